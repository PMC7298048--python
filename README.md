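# pdxtrial

Analysis toolkit for patient-derived xenograft (PDX) preclinical trials in
breast cancer — the "mouse clinical trial" design in which each PDX model is
treated with one animal per drug arm (1×1×1) and drug response is read out
from longitudinal caliper measurements.

The package covers the full chemogenomic analysis around such a trial:

* **Response quantification (mRECIST).** Caliper pairs become volumes via
  *V* = (length × width²)/2; each trajectory is expressed as percent change
  ΔV*ₜ* = 100 · (V*ₜ* − V₀)/V₀. Two statistics summarise it:
  BestResponse = min{ΔV*ₜ* : *t* ≥ 10 d} and
  BestAvgResponse = min{ mean(ΔV₀…ΔV*ₜ*) : *t* ≥ 14 d }.
  The pair maps to CR/PR/SD/PD through strict thresholds
  (CR: BestResponse < −95 and BestAvgResponse < −40; PR: < −50 and < −20;
  SD: < 35 and < 30; else PD).
* **Cohort statistics.** Objective response rates (CR+PR), chemosensitivity
  classification (chemosensitive = ≥ 2 CR/PR across tested agents),
  tumor-volume doubling-free survival (Kaplan–Meier product-limit estimate
  and two-group log-rank test, both implemented from their definitions),
  replicate reproducibility, patient–PDX response concordance
  (both sides collapsed to sensitive = CR/PR vs resistant = SD/PD), and the
  correlation between a patient's prior drug exposure and their PDX's mean
  BestAvgResponse.
* **Expression scoring.** Per-feature IQR outlier scores
  (*x* − Q3)/IQR with outliers called strictly above 1.5; RPPA pathway
  signature scores (sum of positive minus negative regulatory components on
  median-centered log2 values); single-sample gene-set enrichment (ssGSEA);
  per-probe RNA~protein Pearson correlation with Benjamini–Hochberg control.
* **Cohort fidelity.** Engraftment take rate, patient-vs-PDX ER/HER2 and
  intrinsic-subtype concordance, and composition statistics, computed from a
  clinicopathologic annotation table. The development cohort's table
  (37 PDX lines from 36 tumors) ships as a fixture.
* **Actionability.** Table-driven matching of mutations/CNAs and expression
  outliers against a curated actionable-alteration rule snapshot, integrated
  with receptor status, germline BRCA and chemosensitivity into a
  model × feature matrix with per-cell provenance.
* **Synthetic cohorts.** A simulator generates trials with known ground
  truth from a two-compartment growth law
  V(*t*) = V₀·[*f*ᵣ·e^{*g t*} + (1 − *f*ᵣ)·e^{−*k t*}]
  (resistant fraction *f*ᵣ grows at rate *g*, the rest regresses at kill
  rate *k*), plus expression matrices with planted outliers, mutation
  tables, and clinical annotations — so every downstream stage is testable
  without sequencing data.

## Worked example

```python
from pdxtrial import (SimConfig, simulate_cohort, responses_from_measurements,
                      objective_response_rate, exposure_response_correlation)

cohort = simulate_cohort(SimConfig(n_models=30, seed=42))
responses = responses_from_measurements(cohort.measurements)
print(responses.head(3).round(1).to_string(index=False))

for arm, grp in responses.groupby("arm"):
    print(f"{arm:12s} ORR = {objective_response_rate(list(grp['mrecist'])):.1f}%")

counts = cohort.annotations.set_index("model_id")["prior_drug_count"]
r, p = exposure_response_correlation(responses, counts)
print(f"prior-exposure vs mean BestAvgResponse: r = {r:.3f}, p = {p:.2e}")
```

prints

```
model_id         arm  best_response  best_avg_response mrecist  n_days  doubling_time  doubling_event
 SIM000X   cisplatin          -28.6              -23.5      SD    28.0           28.0               1
 SIM000X doxorubicin          -54.3              -41.9      PR    28.0           28.0               1
 SIM000X gemcitabine          -51.2              -39.1      PR    28.0           28.0               1
cisplatin    ORR = 43.3%
doxorubicin  ORR = 43.3%
gemcitabine  ORR = 40.0%
paclitaxel   ORR = 43.3%
untreated    ORR = 0.0%
prior-exposure vs mean BestAvgResponse: r = 0.796, p = 1.42e-07
```

SIM000X regresses partially under doxorubicin and gemcitabine (PR), merely
stabilises under cisplatin (SD), and no untreated tumor responds; across the
cohort, models from more heavily pre-treated patients respond less (positive
r: higher exposure, higher — i.e. worse — BestAvgResponse).

Cohort-fidelity statistics on the bundled annotation table:

```python
from pdxtrial import load_table1, take_rate, receptor_concordance, subtype_concordance
table = load_table1()
take_rate((36, 81))                    # 44.4  (% of engraftment attempts)
receptor_concordance(table, "ER")[0]   # 80.6  (% of 36 tumor-PDX pairs)
subtype_concordance(table)[0]          # 86.7  (% of 30 subtyped pairs)
```

A `pdxtrial` command-line tool exposes the same pipeline
(`simulate`, `respond`, `cohort`, `express`, `fidelity`, `action`);
run `pdxtrial --help`.

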