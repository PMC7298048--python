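"""Cohort-level PDX-trial statistics.

Takes the per-model x arm response table produced by :mod:`pdxtrial.response`
and computes the population-level readouts of a mouse clinical trial:
objective response rates, broad chemosensitivity classification (a model is
chemosensitive when it achieves >= 2 objective responses across the agents it
was tested with), tumor-volume doubling-free survival (product-limit estimate
and two-group log-rank test), replicate reproducibility, the patient-vs-PDX
response concordance table, and the correlation between a patient's prior
drug exposure and their PDX's average response.

Survival machinery is implemented directly from the product-limit /
observed-minus-expected definitions so every number is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SurvivalSample",
    "ChemoClass",
    "OBJECTIVE",
    "objective_response_rate",
    "classify_chemosensitivity",
    "chemosensitivity_table",
    "km_estimate",
    "logrank_test",
    "replicate_reproducibility",
    "patient_pdx_concordance",
    "exposure_response_correlation",
]

#: mRECIST categories counting as an objective response
OBJECTIVE = frozenset({"CR", "PR"})

_SENSITIVE_WORDS = {"sensitive", "cr", "pr"}
_RESISTANT_WORDS = {"resistant", "sd", "pd"}


@dataclass(frozen=True)
class SurvivalSample:
    """Right-censored survival data for one group."""

    label: str
    times: tuple[float, ...]
    events: tuple[int, ...]

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.times)
        events = tuple(int(e) for e in self.events)
        if len(times) != len(events):
            raise ValueError("times and events differ in length")
        if any(t < 0 for t in times):
            raise ValueError("times must be non-negative")
        if any(e not in (0, 1) for e in events):
            raise ValueError("events must be 0/1")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "events", events)


@dataclass(frozen=True)
class ChemoClass:
    model_id: str
    n_objective_responses: int
    n_tested: int
    label: str  # "chemosensitive" | "chemoresistant" | "not-classifiable"


def objective_response_rate(calls: Sequence[str]) -> float:
    """Percent of calls that are CR or PR."""
    calls = list(calls)
    if not calls:
        raise ValueError("cannot compute a response rate from zero calls")
    n_obj = sum(1 for c in calls if c in OBJECTIVE)
    return 100.0 * n_obj / len(calls)


def classify_chemosensitivity(
    model_id: str, calls: Sequence[str], min_tested: int = 2
) -> ChemoClass:
    """Chemosensitive iff >= 2 objective responses (CR/PR) across tested arms.

    Models tested with fewer than ``min_tested`` agents are flagged
    not-classifiable rather than forced into either class.
    """
    calls = list(calls)
    n_obj = sum(1 for c in calls if c in OBJECTIVE)
    if len(calls) < min_tested:
        label = "not-classifiable"
    elif n_obj >= 2:
        label = "chemosensitive"
    else:
        label = "chemoresistant"
    return ChemoClass(model_id, n_obj, len(calls), label)


def chemosensitivity_table(
    responses: pd.DataFrame,
    untreated_arm: str = "untreated",
    min_tested: int = 2,
) -> pd.DataFrame:
    """Per-model chemosensitivity from a response table.

    The untreated (control) arm never counts as a tested agent.
    """
    drug = responses[responses["arm"] != untreated_arm]
    rows = []
    for model_id, grp in drug.groupby("model_id", sort=True):
        cc = classify_chemosensitivity(str(model_id), list(grp["mrecist"]), min_tested)
        rows.append(
            {
                "model_id": cc.model_id,
                "n_objective_responses": cc.n_objective_responses,
                "n_tested": cc.n_tested,
                "label": cc.label,
            }
        )
    return pd.DataFrame(
        rows, columns=["model_id", "n_objective_responses", "n_tested", "label"]
    )


def km_estimate(sample: SurvivalSample) -> pd.DataFrame:
    """Kaplan–Meier product-limit estimator.

    Returns a step function as a DataFrame with columns ``time``, ``n_at_risk``,
    ``n_events``, ``survival`` — one row per distinct event time, survival being
    the value just after that time. Censored observations leave the risk set
    without contributing an event factor; with no censoring the estimate equals
    the empirical survivor function.
    """
    if len(sample.times) == 0:
        raise ValueError("empty survival sample")
    times = np.asarray(sample.times)
    events = np.asarray(sample.events)
    rows = []
    surv = 1.0
    for t in np.unique(times[events == 1]):
        n_at_risk = int(np.sum(times >= t))
        d = int(np.sum((times == t) & (events == 1)))
        surv *= 1.0 - d / n_at_risk
        rows.append(
            {"time": float(t), "n_at_risk": n_at_risk, "n_events": d,
             "survival": surv}
        )
    return pd.DataFrame(rows, columns=["time", "n_at_risk", "n_events", "survival"])


def logrank_test(a: SurvivalSample, b: SurvivalSample) -> tuple[float, float]:
    """Two-group log-rank (Mantel–Cox) test.

    At each distinct event time the observed events in group *a* are compared
    with their hypergeometric expectation given the pooled risk set; the
    statistic is (sum O - sum E)^2 / sum Var, referred to chi-square with 1 df.
    Returns ``(chi2, p)``; symmetric in its arguments.
    """
    if len(a.times) == 0 or len(b.times) == 0:
        raise ValueError("both groups must be nonempty")
    ta, ea = np.asarray(a.times), np.asarray(a.events)
    tb, eb = np.asarray(b.times), np.asarray(b.events)
    pooled = np.concatenate([ta[ea == 1], tb[eb == 1]])
    if pooled.size == 0:
        raise ValueError("no events in either group; statistic undefined")
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(pooled):
        n1 = int(np.sum(ta >= t))
        n2 = int(np.sum(tb >= t))
        n = n1 + n2
        d1 = int(np.sum((ta == t) & (ea == 1)))
        d2 = int(np.sum((tb == t) & (eb == 1)))
        d = d1 + d2
        if n < 2 or n1 == 0:
            continue
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    if var == 0.0:
        # identical groups with a shared single event time can land here
        return (0.0, 1.0)
    chi2 = o_minus_e**2 / var
    p = float(stats.chi2.sf(chi2, df=1))
    return (float(chi2), p)


def replicate_reproducibility(
    pairs: Iterable[tuple[float, float]]
) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) between replicate response calls."""
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 replicate pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in a replicate vector")
    r, p = stats.pearsonr(x, y)
    return (float(r), float(p))


def _to_sensitivity(call: str) -> str | None:
    c = str(call).strip().lower()
    if c in _SENSITIVE_WORDS:
        return "sensitive"
    if c in _RESISTANT_WORDS:
        return "resistant"
    return None  # untested / unknown


def patient_pdx_concordance(
    responses: pd.DataFrame,
    patient_responses: pd.DataFrame,
) -> tuple[pd.DataFrame, float]:
    """Concordance of patient vs PDX drug-sensitivity calls.

    ``responses`` carries PDX mRECIST calls (``model_id, arm, mrecist``);
    ``patient_responses`` carries per model x drug patient calls
    (``model_id, drug, response`` with response in CR/PR/SD/PD or
    sensitive/resistant; anything else counts as untested and is skipped).
    Both sides collapse to sensitive (CR/PR) vs resistant (SD/PD); the
    combination is concordant when the labels match. Returns the
    combination-level table and the overall percent concordant.
    """
    pdx_calls = responses.set_index(["model_id", "arm"])["mrecist"]
    rows = []
    for rec in patient_responses.itertuples(index=False):
        patient = _to_sensitivity(rec.response)
        if patient is None:
            continue
        key = (rec.model_id, rec.drug)
        if key not in pdx_calls.index:
            continue
        pdx = _to_sensitivity(pdx_calls.loc[key])
        rows.append(
            {
                "model_id": rec.model_id,
                "drug": rec.drug,
                "patient": patient,
                "pdx": pdx,
                "concordant": patient == pdx,
            }
        )
    table = pd.DataFrame(
        rows, columns=["model_id", "drug", "patient", "pdx", "concordant"]
    )
    if table.empty:
        return (table, float("nan"))
    pct = 100.0 * table["concordant"].mean()
    return (table, float(pct))


def exposure_response_correlation(
    responses: pd.DataFrame,
    prior_drug_counts: Mapping[str, int] | pd.Series,
    untreated_arm: str = "untreated",
) -> tuple[float, float]:
    """Pearson r between prior drug exposure and mean PDX BestAvgResponse.

    The per-model mean is over arms actually tested (control arm excluded);
    untested cells are never imputed.
    """
    counts = pd.Series(prior_drug_counts, dtype=float)
    drug = responses[responses["arm"] != untreated_arm]
    mean_bar = drug.groupby("model_id")["best_avg_response"].mean()
    joined = pd.concat([counts.rename("prior"), mean_bar.rename("bar")], axis=1)
    joined = joined.dropna()
    if len(joined) < 3:
        raise ValueError("need >= 3 models with exposure and response data")
    if joined["prior"].std() == 0 or joined["bar"].std() == 0:
        raise ValueError("zero variance; correlation undefined")
    r, p = stats.pearsonr(joined["prior"], joined["bar"])
    return (float(r), float(p))
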