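"""Patient–PDX fidelity and cohort-composition statistics.

Works on a clinicopathologic annotation table with one row per PDX line
(columns: tumor_id, site, patient_histology, patient_er, patient_her2,
patient_subtype, gbrca, prior_therapy, aln, distant, pdx_id, pdx_histology,
pdx_er, pdx_her2, pdx_subtype). Receptor status strings mirror pathology
reports and are parsed by rule:

* ER — "+" or any nonzero percent ("10%") is positive; "-" is negative.
  Annotations like "- (1° +)" (lesion negative, primary positive) use the
  sampled lesion's status.
* HER2 — "+" is positive; a FISH ratio ("FISH 2.2") is positive when >= 2.0.

Denominators follow the statistic: receptor concordance is per tumor
(multi-subline tumors count once and must agree in every subline), subtype
concordance is per PDX line restricted to pairs with a patient subtype call,
and composition fractions are over PDX lines. Percentages are reported to one
decimal, rounding half up.

The development cohort's printed annotation table ships as a package fixture
(``load_table1``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import pandas as pd

__all__ = [
    "EngraftmentLedger",
    "StatusParseError",
    "load_table1",
    "er_positive",
    "her2_positive",
    "prior_drug_count",
    "take_rate",
    "receptor_concordance",
    "subtype_concordance",
    "composition_stats",
    "flow_table",
]

_MINUS = {"-", "−", "–"}  # ascii hyphen, minus sign, en dash


class StatusParseError(ValueError):
    """A receptor status string could not be interpreted."""


@dataclass(frozen=True)
class EngraftmentLedger:
    n_attempts: int
    n_success: int

    def __post_init__(self) -> None:
        if self.n_success > self.n_attempts or self.n_success < 0:
            raise ValueError("need 0 <= n_success <= n_attempts")


def _round1(x: float) -> float:
    return float(
        Decimal(repr(float(x))).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    )


def load_table1() -> pd.DataFrame:
    """The bundled cohort annotation table (one row per PDX line)."""
    with resources.files("pdxtrial.data").joinpath(
        "table1_annotations.csv"
    ).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, keep_default_na=False)


def _lesion_status(status: str) -> str:
    """Strip a parenthetical primary-status annotation, e.g. '- (1° +)' -> '-'."""
    return re.sub(r"\(.*?\)", "", str(status)).strip()


def er_positive(status: str, row_id: str = "?") -> bool:
    """Binarize an ER status string; any nonzero percent counts as positive."""
    s = _lesion_status(status)
    if s in _MINUS:
        return False
    if s == "+":
        return True
    m = re.fullmatch(r"(\d+(?:\.\d+)?)\s*%", s)
    if m:
        return float(m.group(1)) > 0
    raise StatusParseError(f"{row_id}: cannot parse ER status {status!r}")


def her2_positive(status: str, row_id: str = "?") -> bool:
    """Binarize a HER2 status string; FISH ratios >= 2.0 are amplified."""
    s = _lesion_status(status)
    if s in _MINUS:
        return False
    if s == "+":
        return True
    m = re.fullmatch(r"FISH\s+(\d+(?:\.\d+)?)", s, flags=re.IGNORECASE)
    if m:
        return float(m.group(1)) >= 2.0
    raise StatusParseError(f"{row_id}: cannot parse HER2 status {status!r}")


def prior_drug_count(therapy: str) -> int:
    """Number of distinct drugs in a prior-therapy string.

    'None' or blank means untreated; a trailing '*' (exposure long before
    sampling) is ignored for counting; repeated drugs across regimens count
    once.
    """
    s = str(therapy).strip()
    if not s or s.lower() in {"none", "n/a", "nan"}:
        return 0
    drugs = {tok.strip().rstrip("*").strip() for tok in s.split(",")}
    drugs.discard("")
    return len(drugs)


def take_rate(ledger: EngraftmentLedger | tuple[int, int]) -> float:
    """Percent of engraftment attempts yielding a propagatable xenograft.

    Accepts an :class:`EngraftmentLedger` or a raw ``(n_success, n_attempts)``
    pair; reported to one decimal.
    """
    if isinstance(ledger, tuple):
        ledger = EngraftmentLedger(n_attempts=ledger[1], n_success=ledger[0])
    if ledger.n_attempts == 0:
        raise ValueError("take rate undefined for zero attempts")
    return _round1(100.0 * ledger.n_success / ledger.n_attempts)


def receptor_concordance(
    table: pd.DataFrame, marker: str
) -> tuple[float, list[str]]:
    """Patient vs PDX receptor concordance per tumor.

    ``marker`` is ``"ER"`` or ``"HER2"``. A tumor with several PDX sublines is
    concordant only if every subline matches the patient's binarized status.
    Returns ``(percent, discordant tumor ids)``.
    """
    marker = marker.upper()
    if marker == "ER":
        parse = er_positive
        pt_col, px_col = "patient_er", "pdx_er"
    elif marker == "HER2":
        parse = her2_positive
        pt_col, px_col = "patient_her2", "pdx_her2"
    else:
        raise ValueError(f"unknown marker {marker!r}")
    discordant: list[str] = []
    tumors = table.groupby("tumor_id", sort=True)
    for tumor_id, grp in tumors:
        patient = parse(grp[pt_col].iloc[0], str(tumor_id))
        pdx_vals = [parse(v, str(tumor_id)) for v in grp[px_col]]
        if any(v != patient for v in pdx_vals):
            discordant.append(str(tumor_id))
    n = tumors.ngroups
    pct = _round1(100.0 * (n - len(discordant)) / n)
    return (pct, discordant)


def subtype_concordance(table: pd.DataFrame) -> tuple[float, pd.DataFrame]:
    """Intrinsic-subtype concordance per PDX line.

    Pairs without a patient subtype call (``N/A``) are excluded. Returns the
    percent and a table of switches (pdx_id, patient_subtype, pdx_subtype).
    """
    eligible = table[table["patient_subtype"].astype(str) != "N/A"]
    if eligible.empty:
        return (float("nan"), eligible[["pdx_id"]].assign(
            patient_subtype=pd.Series(dtype=str), pdx_subtype=pd.Series(dtype=str)
        ))
    mismatch = eligible["patient_subtype"] != eligible["pdx_subtype"]
    switches = eligible.loc[
        mismatch, ["pdx_id", "patient_subtype", "pdx_subtype"]
    ].reset_index(drop=True)
    pct = _round1(100.0 * (1.0 - mismatch.mean()))
    return (pct, switches)


def composition_stats(table: pd.DataFrame) -> dict[str, float]:
    """Cohort composition over PDX lines.

    Returns subtype fractions, the triple-negative fraction (PDX ER- and
    HER2-) and the rare-histology fraction (PDX histology other than
    IDC-NOS), all as percents of PDX lines, plus the line count.
    """
    n = len(table)
    out: dict[str, float] = {"n_pdx": float(n)}
    for subtype, cnt in table["pdx_subtype"].value_counts().items():
        out[f"subtype_{subtype}_pct"] = _round1(100.0 * cnt / n)
    er_neg = ~table.apply(
        lambda r: er_positive(r["pdx_er"], r["pdx_id"]), axis=1
    )
    her2_neg = ~table.apply(
        lambda r: her2_positive(r["pdx_her2"], r["pdx_id"]), axis=1
    )
    out["tnbc_pct"] = _round1(100.0 * (er_neg & her2_neg).mean())
    rare = table["pdx_histology"].astype(str) != "IDC-NOS"
    out["rare_histology_pct"] = _round1(100.0 * rare.mean())
    return out


def flow_table(table: pd.DataFrame, field: str) -> pd.DataFrame:
    """Patient-label -> PDX-label transition counts (Sankey-ready).

    ``field`` is one of ``er``, ``her2``, ``histology``, ``subtype``. Receptor
    fields are binarized to '+'/'-'; the others use labels verbatim. One pair
    per PDX line.
    """
    field = field.lower()
    if field == "er":
        pt = table.apply(lambda r: "+" if er_positive(r["patient_er"]) else "-", axis=1)
        px = table.apply(lambda r: "+" if er_positive(r["pdx_er"]) else "-", axis=1)
    elif field == "her2":
        pt = table.apply(lambda r: "+" if her2_positive(r["patient_her2"]) else "-", axis=1)
        px = table.apply(lambda r: "+" if her2_positive(r["pdx_her2"]) else "-", axis=1)
    elif field in {"histology", "subtype"}:
        pt = table[f"patient_{field}"].astype(str)
        px = table[f"pdx_{field}"].astype(str)
    else:
        raise ValueError(f"unknown field {field!r}")
    counts = (
        pd.DataFrame({"patient_label": pt, "pdx_label": px})
        .value_counts()
        .rename("count")
        .reset_index()
        .sort_values(["patient_label", "pdx_label"])
        .reset_index(drop=True)
    )
    return counts
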