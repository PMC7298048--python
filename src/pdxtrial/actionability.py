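"""Multi-omic actionability integration.

Combines genomic alteration calls, expression/protein outliers, clinical
receptor and germline BRCA status, and in vivo chemosensitivity into a
model x actionable-feature presence matrix with a provenance record for
every filled cell.

Matching is table-driven: a rule names a source (genomic / expression /
protein / clinical-receptor), a gene or probe, an alteration class
(hotspot-mutation, truncating, amplification, deletion, outlier-high,
outlier-low, ...) and optionally an exact variant (e.g. PIK3CA H1047R).
Hotspot membership is defined by the rule file's explicit variant lists, not
recomputed. A curated default rule snapshot ships with the package; live
knowledge-base queries are deliberately out of scope so results do not drift
with database versions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = [
    "ActionabilityRule",
    "ALTERATION_CLASSES",
    "load_default_rules",
    "read_rules",
    "match_genomic",
    "match_expression",
    "build_matrix",
]

ALTERATION_CLASSES = frozenset(
    {
        "hotspot-mutation",
        "truncating",
        "amplification",
        "deletion",
        "outlier-high",
        "outlier-low",
        "receptor-positive",
        "germline",
    }
)

_MATCH_COLUMNS = ["model_id", "source", "gene", "alteration_class", "variant", "tier", "provenance"]


@dataclass(frozen=True)
class ActionabilityRule:
    source: str
    gene: str
    alteration_class: str
    variant: str = ""
    tier: str = ""

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValueError("rule gene must be nonempty")
        if self.alteration_class not in ALTERATION_CLASSES:
            raise ValueError(
                f"unknown alteration class {self.alteration_class!r}"
            )

    @property
    def column(self) -> str:
        """Stable matrix-column name for this rule."""
        core = f"{self.source}:{self.gene}:{self.alteration_class}"
        return f"{core}:{self.variant}" if self.variant else core


def read_rules(path) -> list[ActionabilityRule]:
    """Load rules from a TSV with columns source, gene, alteration_class, variant, tier."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return [
        ActionabilityRule(
            source=str(r.source),
            gene=str(r.gene),
            alteration_class=str(r.alteration_class),
            variant=str(getattr(r, "variant", "")),
            tier=str(getattr(r, "tier", "")),
        )
        for r in df.itertuples(index=False)
    ]


def load_default_rules() -> list[ActionabilityRule]:
    """The bundled curated rule snapshot."""
    with resources.files("pdxtrial.data").joinpath(
        "actionability_rules.tsv"
    ).open("r", encoding="utf-8") as fh:
        return read_rules(fh)


def match_genomic(
    mutations: pd.DataFrame, rules: list[ActionabilityRule]
) -> pd.DataFrame:
    """Match mutation/CNA calls against genomic rules.

    ``mutations`` needs columns ``model_id, gene, alteration, class`` (class in
    the same vocabulary as the rules, e.g. hotspot-mutation / truncating /
    amplification / deletion). A variant-specific rule additionally requires an
    exact ``alteration`` string match. Malformed rows are skipped with a
    warning.
    """
    genomic_rules = [r for r in rules if r.source == "genomic"]
    # 'class' is a reserved word that itertuples would mangle
    mutations = mutations.rename(columns={"class": "alteration_class"})
    rows = []
    for rec in mutations.itertuples(index=False):
        gene = str(getattr(rec, "gene", "") or "")
        klass = str(getattr(rec, "alteration_class", "") or "")
        if not gene or not klass or klass == "nan":
            warnings.warn(f"skipping malformed mutation row {rec!r}", stacklevel=2)
            continue
        for rule in genomic_rules:
            if rule.gene != gene or rule.alteration_class != klass:
                continue
            if rule.variant and rule.variant != str(rec.alteration):
                continue
            rows.append(
                {
                    "model_id": rec.model_id,
                    "source": "genomic",
                    "gene": gene,
                    "alteration_class": rule.alteration_class,
                    "variant": rule.variant,
                    "tier": rule.tier,
                    "provenance": f"mutation:{rec.model_id}:{gene}:{rec.alteration}",
                }
            )
    return pd.DataFrame(rows, columns=_MATCH_COLUMNS).drop_duplicates(
        ignore_index=True
    )


def match_expression(
    outliers: pd.DataFrame,
    rules: list[ActionabilityRule],
    source: str = "expression",
) -> pd.DataFrame:
    """Match flagged expression/protein outliers against outlier rules.

    ``outliers`` is the long table from
    :func:`pdxtrial.expression.call_outliers` (columns feature, sample, score,
    outlier), with samples being model ids. Rows whose flag is unset (score
    <= 1.5) never match. A ``direction`` column ('high'/'low') may mark
    low-tail outliers; without one all rows are treated as high.
    """
    src_rules = [r for r in rules if r.source == source]
    direction = (
        outliers["direction"].astype(str)
        if "direction" in outliers.columns
        else pd.Series("high", index=outliers.index)
    )
    flagged = outliers[outliers["outlier"].astype(bool)]
    rows = []
    for idx, rec in flagged.iterrows():
        wanted = f"outlier-{direction.loc[idx]}"
        for rule in src_rules:
            if rule.gene != str(rec["feature"]) or rule.alteration_class != wanted:
                continue
            rows.append(
                {
                    "model_id": rec["sample"],
                    "source": source,
                    "gene": rule.gene,
                    "alteration_class": rule.alteration_class,
                    "variant": "",
                    "tier": rule.tier,
                    "provenance": (
                        f"{source}-outlier:{rec['sample']}:{rec['feature']}"
                        f":score={rec['score']:.3f}"
                    ),
                }
            )
    return pd.DataFrame(rows, columns=_MATCH_COLUMNS).drop_duplicates(
        ignore_index=True
    )


def _gbrca_actionable(status: str, include_vus: bool = False) -> bool:
    s = str(status).strip()
    if not s:
        return False
    lowered = s.lower()
    if "benign" in lowered:
        return False
    if "vus" in lowered:
        return include_vus
    return lowered.startswith("brca")


def build_matrix(
    annotations: pd.DataFrame,
    genomic_matches: pd.DataFrame,
    expression_matches: pd.DataFrame,
    chemo_classes: pd.DataFrame | None = None,
    include_vus: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble the per-model actionability matrix.

    ``annotations`` is the cohort annotation table (one row per PDX line;
    model ids come from ``pdx_id``). Clinical columns (ER+, HER2+, germline
    BRCA) are derived from the annotations; genomic and expression columns
    from the match tables; a chemosensitivity column from the trial
    classification when given. Cells are booleans; a provenance sidecar maps
    every filled cell back to the record that produced it. Construction is
    deterministic and idempotent (duplicate matches collapse).
    """
    from . import fidelity  # receptor parsing rules live with the fidelity stats

    # accept either the cohort-fixture schema (pdx_id/pdx_er/pdx_her2) or the
    # simulator schema (model_id/er_status/her2_status)
    annotations = annotations.rename(
        columns={"model_id": "pdx_id", "er_status": "pdx_er", "her2_status": "pdx_her2"}
    )
    models = [str(m) for m in annotations["pdx_id"]]
    model_set = set(models)
    match_tables = [t for t in (genomic_matches, expression_matches) if not t.empty]
    unknown = sorted(
        {str(m) for t in match_tables for m in t["model_id"]} - model_set
    )
    if unknown:
        raise ValueError(f"matched models absent from annotations: {unknown}")

    columns: list[str] = ["clinical:ER+", "clinical:HER2+", "clinical:gBRCA"]
    cells: dict[tuple[str, str], list[str]] = {}
    for rec in annotations.itertuples(index=False):
        mid = str(rec.pdx_id)
        if fidelity.er_positive(rec.pdx_er, mid):
            cells.setdefault((mid, "clinical:ER+"), []).append(f"annotation:{mid}:ER")
        if fidelity.her2_positive(rec.pdx_her2, mid):
            cells.setdefault((mid, "clinical:HER2+"), []).append(f"annotation:{mid}:HER2")
        if _gbrca_actionable(rec.gbrca, include_vus):
            cells.setdefault((mid, "clinical:gBRCA"), []).append(
                f"annotation:{mid}:gBRCA={rec.gbrca}"
            )

    for table in match_tables:
        for rec in table.itertuples(index=False):
            rule = ActionabilityRule(
                rec.source, rec.gene, rec.alteration_class, rec.variant, rec.tier
            )
            if rule.column not in columns:
                columns.append(rule.column)
            cells.setdefault((str(rec.model_id), rule.column), []).append(
                str(rec.provenance)
            )

    if chemo_classes is not None and not chemo_classes.empty:
        columns.append("trial:chemosensitive")
        for rec in chemo_classes.itertuples(index=False):
            if rec.label == "chemosensitive" and str(rec.model_id) in model_set:
                cells.setdefault(
                    (str(rec.model_id), "trial:chemosensitive"), []
                ).append(f"chemo:{rec.model_id}:{rec.n_objective_responses}CR/PR")

    matrix = pd.DataFrame(False, index=models, columns=columns)
    prov_rows = []
    for (mid, col), provs in sorted(cells.items()):
        matrix.loc[mid, col] = True
        for p in sorted(set(provs)):
            prov_rows.append({"model_id": mid, "column": col, "provenance": p})
    provenance = pd.DataFrame(prov_rows, columns=["model_id", "column", "provenance"])
    matrix.index.name = "model_id"
    return (matrix, provenance)
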