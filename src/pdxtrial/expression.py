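"""Expression-level scoring: IQR outliers, signatures, ssGSEA, RNA~protein.

Works on features x samples matrices (RNA-seq summaries or RPPA protein
levels). The scientific operations are:

* quartile-based outlier scoring — score(x) = (x - Q3) / IQR per feature, a
  value being called an expression outlier when its score exceeds 1.5;
* pathway signature scores on median-centered log2 values — the sum of a
  signature's positive regulatory components minus its negative ones;
* single-sample gene-set enrichment (ssGSEA) — the integrated difference
  between the weighted in-set and unweighted out-of-set cumulative
  distributions over the sample's expression ranking;
* per-probe RNA~protein Pearson correlation with Benjamini–Hochberg control.

Quartiles use linear interpolation of order statistics at h = (n-1)p + 1
(the numpy default), fixed so scores are reproducible across runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionMatrix",
    "SignatureDef",
    "GeneSet",
    "median_center_log2",
    "outlier_score",
    "call_outliers",
    "signature_score",
    "ssgsea_score",
    "rna_protein_correlation",
    "filter_by_correction_factor",
]

logger = logging.getLogger(__name__)

OUTLIER_THRESHOLD = 1.5


@dataclass
class ExpressionMatrix:
    """Features x samples numeric matrix with platform metadata.

    ``values`` is a DataFrame indexed by feature id with sample-id columns.
    ``is_log2`` declares the scale; linear-scale matrices must be strictly
    positive so they can be logged.
    """

    values: pd.DataFrame
    platform: str = "RNA"  # "RNA" | "RPPA"
    is_log2: bool = True
    feature_annotation: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate feature ids")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class SignatureDef:
    """A pathway signature: positive minus negative regulatory components."""

    name: str
    positive_components: tuple[str, ...]
    negative_components: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        pos = tuple(self.positive_components)
        neg = tuple(self.negative_components)
        if not pos:
            raise ValueError(f"signature {self.name}: no positive components")
        if set(pos) & set(neg):
            raise ValueError(f"signature {self.name}: overlapping components")
        object.__setattr__(self, "positive_components", pos)
        object.__setattr__(self, "negative_components", neg)


@dataclass(frozen=True)
class GeneSet:
    """A plain gene set for enrichment scoring."""

    name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        members = tuple(dict.fromkeys(self.members))  # unique, order kept
        if not members:
            raise ValueError(f"gene set {self.name} is empty")
        object.__setattr__(self, "members", members)


def median_center_log2(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Log2-transform if needed, then center every feature on its median.

    Idempotent on already-centered log2 input. Linear input must be strictly
    positive.
    """
    vals = matrix.values
    if not matrix.is_log2:
        if (vals <= 0).any().any():
            raise ValueError("linear-scale matrix has non-positive values")
        vals = np.log2(vals)
    centered = vals.sub(vals.median(axis=1), axis=0)
    return ExpressionMatrix(
        centered, platform=matrix.platform, is_log2=True,
        feature_annotation=matrix.feature_annotation,
    )


def outlier_score(values_for_feature: Sequence[float], x: float) -> float:
    """(x - Q3) / IQR for one feature's cross-sample distribution.

    Raises on degenerate spread (IQR = 0) — such features can never yield an
    outlier call.
    """
    vals = np.asarray(values_for_feature, dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size < 4:
        raise ValueError("need >= 4 values to estimate quartiles")
    q1, q3 = np.quantile(vals, [0.25, 0.75])
    iqr = q3 - q1
    if iqr == 0:
        raise ValueError("IQR is zero; outlier score undefined")
    return float((x - q3) / iqr)


def call_outliers(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Score every (feature, sample) pair and flag outliers (score > 1.5).

    The tested value is left in when computing its feature's quartiles.
    Features with zero IQR get NaN scores and are never flagged. Returns a
    long table with columns ``feature, sample, score, outlier``.
    """
    vals = matrix.values
    q1 = vals.quantile(0.25, axis=1)
    q3 = vals.quantile(0.75, axis=1)
    iqr = q3 - q1
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = vals.sub(q3, axis=0).div(iqr.replace(0.0, np.nan), axis=0)
    long = scores.stack().rename("score").reset_index()
    long.columns = ["feature", "sample", "score"]
    long["outlier"] = long["score"] > OUTLIER_THRESHOLD
    return long


def signature_score(
    matrix: ExpressionMatrix,
    sig: SignatureDef,
    center: bool = False,
) -> pd.Series:
    """Per-sample signature score: sum(positives) - sum(negatives).

    Expects median-centered log2 values (pass ``center=True`` to apply
    :func:`median_center_log2` first). Components absent from the matrix are
    dropped with a log message; if none remain the score is undefined.
    """
    if center:
        matrix = median_center_log2(matrix)
    vals = matrix.values
    pos = [f for f in sig.positive_components if f in vals.index]
    neg = [f for f in sig.negative_components if f in vals.index]
    n_missing = (
        len(sig.positive_components) + len(sig.negative_components)
        - len(pos) - len(neg)
    )
    if n_missing:
        logger.warning(
            "signature %s: %d component(s) absent from matrix", sig.name, n_missing
        )
    if not pos and not neg:
        raise ValueError(f"signature {sig.name}: no components found in matrix")
    score = vals.loc[pos].sum(axis=0) - vals.loc[neg].sum(axis=0)
    return score.rename(sig.name)


def ssgsea_score(
    sample_values: pd.Series, gene_set: GeneSet, alpha: float = 0.25
) -> float:
    """Single-sample enrichment score for one gene set in one sample.

    Features are ranked by descending expression (ties broken by stable input
    order). Walking down the ranking, the score accumulates the difference
    between the weighted cumulative in-set distribution — weights
    ``|value|**alpha`` with values replaced by their integer ranks — and the
    unweighted cumulative distribution of out-of-set features. ``alpha=0``
    reduces the in-set weights to an ECDF. Scores are unnormalized and only
    comparable within a fixed feature universe.
    """
    members = set(gene_set.members)
    universe = set(sample_values.index)
    if not members & universe:
        raise ValueError(f"gene set {gene_set.name} shares no features with sample")
    if universe <= members:
        raise ValueError("gene set equals the feature universe; no out-of-set mass")
    n = len(sample_values)
    order = np.argsort(-sample_values.to_numpy(), kind="stable")
    ranked_ids = sample_values.index.to_numpy()[order]
    # rank statistic: n for the top feature down to 1 for the bottom
    rank_values = np.arange(n, 0, -1, dtype=float)
    in_set = np.fromiter((f in members for f in ranked_ids), dtype=bool, count=n)
    weights = np.abs(rank_values) ** alpha
    w_in = np.where(in_set, weights, 0.0)
    cum_in = np.cumsum(w_in)
    total_in = cum_in[-1]
    cum_out = np.cumsum(~in_set)
    total_out = cum_out[-1]
    return float(np.sum(cum_in / total_in - cum_out / total_out))


def rna_protein_correlation(
    rna: ExpressionMatrix,
    rppa: ExpressionMatrix,
    probe_map: Mapping[str, str],
) -> tuple[pd.DataFrame, float]:
    """Per-probe Pearson correlation between protein and transcript levels.

    ``probe_map`` links each RPPA probe to one transcript feature id. Pairs are
    computed over samples shared by the two matrices (pairwise-complete over
    missing values; probes with < 3 complete pairs are dropped). P-values get
    Benjamini–Hochberg adjustment across probes. Returns the per-probe table
    and the fraction (in percent) of probes with adjusted p < 0.05.
    """
    shared = [s for s in rppa.sample_ids if s in set(rna.sample_ids)]
    if len(shared) < 3:
        raise ValueError("need >= 3 shared samples")
    rows = []
    for probe, transcript in probe_map.items():
        if probe not in rppa.values.index or transcript not in rna.values.index:
            continue
        x = rppa.values.loc[probe, shared].astype(float)
        y = rna.values.loc[transcript, shared].astype(float)
        ok = x.notna() & y.notna()
        if ok.sum() < 3 or x[ok].std() == 0 or y[ok].std() == 0:
            continue
        r, p = stats.pearsonr(x[ok], y[ok])
        rows.append({"probe": probe, "transcript": transcript,
                     "r": float(r), "p": float(p), "n": int(ok.sum())})
    table = pd.DataFrame(rows, columns=["probe", "transcript", "r", "p", "n"])
    if table.empty:
        return (table.assign(p_adjusted=pd.Series(dtype=float)), float("nan"))
    table["p_adjusted"] = multipletests(table["p"], method="fdr_bh")[1]
    frac = 100.0 * float((table["p_adjusted"] < 0.05).mean())
    return (table, frac)


def filter_by_correction_factor(
    matrix: ExpressionMatrix,
    correction_factors: Mapping[str, float],
    threshold: float = 0.5,
) -> ExpressionMatrix:
    """Drop samples whose total-protein correction factor falls below threshold.

    RPPA quantification divides each sample by a loading correction factor;
    extreme factors (e.g. matrix-protein-rich tumors) flag unreliable samples.
    Samples without a recorded factor are kept.
    """
    keep = [
        s for s in matrix.sample_ids
        if correction_factors.get(s, 1.0) >= threshold
    ]
    dropped = set(matrix.sample_ids) - set(keep)
    if dropped:
        logger.info("correction-factor filter dropped samples: %s", sorted(dropped))
    return ExpressionMatrix(
        matrix.values[keep], platform=matrix.platform, is_log2=matrix.is_log2,
        feature_annotation=matrix.feature_annotation,
    )
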