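# Methods

## Response metrics and mRECIST classification

Tumor volume is the standard ellipsoid approximation V = (length × width²)/2,
with length the larger caliper dimension (swapped pairs are corrected with a
warning rather than rejected; missing measurement days are skipped, never
interpolated). Percent change is ΔVₜ = 100·(Vₜ − V₀)/V₀, so ΔV₀ = 0 exactly
and complete regression is bounded at −100.

Two summary statistics drive classification:

* **BestResponse** — min ΔVₜ over days t ≥ 10. The 10-day window guards
  against calling a response on a transient early dip.
* **BestAvgResponse** — min over days t ≥ 14 of the arithmetic mean of all
  ΔV values from day 0 through t inclusive. The day-0 value (always 0) is
  included in every running mean, i.e. "from t = 0 to t" read literally;
  this makes the statistic slightly conservative (it can never be below the
  deepest single-day regression).

mRECIST categories are assigned first-match with strict inequalities:
CR if BestResponse < −95 and BestAvgResponse < −40; PR if < −50 and < −20;
SD if < 35 and < 30; else PD. Thresholds and windows are arguments
(`MrecistCriteria`, `bar_window`, `br_window`), with the published mouse-trial
convention as defaults. Series are truncated at a 28-day study horizon before
metric computation; animals whose follow-up ends before day 14 have no
defined BestAvgResponse and are excluded with a warning. Doubling-free
survival uses the first measurement day with Vₜ ≥ 2·V₀ (inclusive), censoring
at the last day otherwise.

The classification is monotone: deepening either statistic can only move a
call toward CR along CR < PR < SD < PD (property-tested).

## Cohort statistics

Objective response rate is 100·(#CR + #PR)/n per arm. A model tested with at
least two single agents is **chemosensitive** when ≥ 2 of its calls are CR/PR
and chemoresistant otherwise; models with fewer tested agents are flagged
not-classifiable. The control arm never counts as a tested agent.

Kaplan–Meier and the two-group log-rank test are implemented from their
definitions (product-limit estimator; observed-minus-expected events over
the hypergeometric variance, χ² with 1 df, two-sided). The test suite
cross-checks both against lifelines and against hand computations; no
multiple-testing correction is applied across arms, matching how per-arm
survival comparisons are conventionally reported in this setting.

Patient–PDX concordance collapses both sides to sensitive (CR/PR) vs
resistant (SD/PD); combinations are counted per PDX-model × drug, so two
PDXs from one patient contribute two combinations. Untested combinations
never enter the denominator, and the percent is invariant to row order.
Exposure–response correlation is Pearson's r between a model's prior-drug
count and its mean BestAvgResponse over arms actually tested (untested cells
are never imputed).

## Expression scoring

* **Outlier score**: (x − Q3)/IQR per feature across samples, flagged
  strictly above 1.5. Quartiles use linear interpolation of order statistics
  at h = (n − 1)p + 1 (the numpy default) — fixed and documented because the
  quantile convention changes scores at small n. Scoring is leave-value-in
  (the tested value contributes to its own feature's quartiles). Features
  with zero IQR yield undefined scores and never an outlier call.
* **Signature scores**: sum of positive minus negative regulatory components
  on median-centered log2 values. The score is linear in the matrix, so any
  loading normalisation applied upstream passes through transparently.
  Components absent from a matrix are dropped with a logged count. An RPPA
  sample whose total-protein correction factor falls below 0.5 (configurable)
  is excluded before analysis — extreme loading corrections mark samples
  whose quantification is unreliable (e.g. matrix-protein-rich tumors).
* **ssGSEA**: features ranked by descending expression (ties broken by
  stable input order); the score integrates the difference between the
  weighted cumulative in-set distribution (weights |rank|^α, α = 0.25 by
  default) and the unweighted out-of-set cumulative distribution. Scores are
  unnormalized and therefore only comparable within a fixed feature
  universe; at α = 0 the score of a set and of its complement are exact
  negatives.
* **RNA~protein correlation**: per-probe Pearson over shared samples,
  pairwise-complete on missing values (probes with < 3 complete pairs or
  zero variance are dropped), Benjamini–Hochberg adjustment across probes,
  and the fraction of probes with adjusted p < 0.05.

## Cohort fidelity conventions

Receptor statuses are pathology strings parsed by rule: ER is positive at
any nonzero percent (a "10%" PDX counts positive); HER2 is positive for "+"
or a FISH ratio ≥ 2.0; an annotation like "− (1° +)" (sampled lesion
negative, primary positive) uses the sampled lesion. Denominators are
statistic-specific and encoded explicitly, because they are the only
conventions under which the fixture's published summary percentages are
internally consistent:

* ER/HER2 concordance — per tumor (36 pairs): a tumor with several PDX
  sublines counts once and is concordant only if every subline agrees;
* subtype concordance — per PDX line with a non-N/A patient subtype call
  (30 pairs);
* composition (subtype, TNBC = ER− and HER2−, rare histology = anything but
  IDC-NOS) — over all 37 PDX lines.

Percentages are reported to one decimal, rounding half up. Prior-drug counts
de-duplicate repeated drugs across regimens and ignore the "given > 1 year
before sampling" star.

## Actionability

Matching is exact on (gene, alteration class), plus exact variant string for
hotspot rules; hotspot membership comes from the rule file's variant list and
is never recomputed statistically. Expression/protein rules additionally
require the outlier flag (score strictly > 1.5) and direction agreement.
A gene matching through several sources (e.g. amplified and outlier-high)
keeps one column per source — no precedence or merging. Germline BRCA counts
as actionable for plain pathogenic annotations; "benign" is excluded and VUS
is excluded by default (`include_vus=True` reverses this). Evidence tiers
are carried as opaque labels. The matrix build is deterministic, idempotent
under duplicate matches, and every present cell carries provenance strings
resolving to input records.

## Synthetic cohorts

The simulator emulates the trial design, not tumor biology in detail. Volume
follows a two-compartment law V(t) = V₀·[f_r·e^{gt} + (1 − f_r)·e^{−kt}]:
a resistant fraction f_r grows exponentially at rate g while the sensitive
remainder regresses at kill rate k. This is the minimal form that produces
all four mRECIST classes, including regression followed by regrowth;
untreated arms have k = 0, f_r = 1. Measurement noise is multiplicative
lognormal on volume (unit mean; caliper error scales with size),
back-converted to a caliper pair with aspect ratio 1.0.

Default study conditions: 30 models, four drug arms plus untreated, one
animal per model per arm, measurements on days 0–28 twice weekly, baseline
100 mm³, untreated growth rate U(0.02, 0.09)/d (doubling in ~8–35 d), kill
rate U(0.05, 0.45)/d, 5% measurement CV. The per-model baseline resistant
fraction is right-skewed within [0, 0.6] (Beta(0.7, 1.5)-shaped), because
treatment-naive tumors frequently lack resistant clones — that mass near
zero is what yields complete responses. About 30% of simulated patients are
treatment-naive; the rest carry 1–9 prior drugs, and each prior drug shifts
the expected resistant fraction up by 0.06 (clipped to [0, 1]) — the
simplest monotone mechanism linking prior exposure to PDX chemoresistance.
Simulated drugs are abstract arms; nothing about them predicts any real
agent. Retrospective patient calls equal the latent PDX sensitivity with a
20% flip rate, and 25% of combinations are untested.

Expression matrices are N(0, 1) per feature with +2 mean-shift blocks per
subtype and planted outlier spikes. Spikes are set to Q3 + 2.5–3 × IQR of
their own feature *including the spikes themselves* (a two-pass fixed-point
placement), so every planted spike has a leave-value-in outlier score equal
to the spike magnitude by construction. Protein probes track a transcript
subset with probe-level noise, giving positive RNA~protein correlations.

Randomness: one root seed; model i draws from SeedSequence(seed,
spawn_key=(i,)) and its arm j from (i, j), so enlarging a cohort never
perturbs existing models (tested).

What the simulator does *not* capture: pharmacokinetics, dosing schedules,
immune or stromal compartments, clonal evolution under treatment, realistic
expression covariance, or mutation co-occurrence structure. Tests passing on
simulated cohorts therefore validate the statistical machinery and its
contracts — not biological claims about real PDX data.

## Problem sizes and numerical choices

The test suite and the reproduction script run the simulator at 12–200
models: 200 models (1,000 arms) for mRECIST category recovery and the
exposure–response correlation, 40 for planted-outlier recovery, 30 for the
trial-scale summaries, 13 replicate pairs for reproducibility — sizes chosen
to match the statistics' intended operating range while keeping runs
essentially instant. Oracle comparisons (running-mean enumeration, BH
step-up, ssGSEA cumulative sums, lifelines survival routines) use absolute
tolerances of 1e-9 or tighter, since all paths are closed-form arithmetic.
Ties in ssGSEA rankings break by stable feature order; quantile and rounding
conventions are fixed as described above.

## Known limitations

* The actionability rule snapshot is a small curated subset for
  reproducibility; it is not a clinical knowledge base.
* ssGSEA scores are unnormalized; cross-universe comparisons are
  unsupported.
* The fixture's germline-alteration actionability count depends on an
  explicit VUS/benign inclusion rule (see above); no single published
  summary number is claimed for it.
* Patient-level survival modelling is limited to the generic KM/log-rank
  operations; no Cox regression, no T/C or AUC response metrics.
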