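"""Plain-text readers and writers for the pipeline's table formats."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd

from .expression import ExpressionMatrix, GeneSet, SignatureDef

__all__ = [
    "read_measurements",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_gmt",
    "write_gmt",
    "signatures_from_gmt",
]

MEASUREMENT_COLUMNS = ["model_id", "arm", "animal_id", "day", "length_mm", "width_mm"]


def read_measurements(path) -> pd.DataFrame:
    """Caliper measurement CSV with the canonical column schema."""
    df = pd.read_csv(path)
    missing = set(MEASUREMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"measurements file missing columns {sorted(missing)}")
    return df[MEASUREMENT_COLUMNS]


def read_expression_tsv(
    path, platform: str = "RNA", is_log2: bool = True
) -> ExpressionMatrix:
    """Features-in-rows TSV; first column is the feature id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return ExpressionMatrix(df, platform=platform, is_log2=is_log2)


def write_expression_tsv(matrix: ExpressionMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="feature")


def read_gmt(path) -> dict[str, list[str]]:
    """GMT gene sets: one tab-separated line of NAME, description, members...."""
    sets: dict[str, list[str]] = {}
    text = Path(path).read_text(encoding="utf-8") if not hasattr(path, "read") else path.read()
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, Iterable[str]], path, description: str = "na") -> None:
    lines = [
        "\t".join([name, description, *members]) for name, members in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def gene_sets_from_gmt(path) -> list[GeneSet]:
    return [GeneSet(name, tuple(members)) for name, members in read_gmt(path).items()]


def signatures_from_gmt(path) -> list[SignatureDef]:
    """Signatures encoded as paired GMT entries ``NAME_POS`` / ``NAME_NEG``.

    A ``NAME_NEG`` entry is optional; a ``NAME_NEG`` without its ``NAME_POS``
    partner is an error (a signature needs positive components).
    """
    raw = read_gmt(path)
    names = {n[:-4] for n in raw if n.endswith("_POS")}
    orphans = {n[:-4] for n in raw if n.endswith("_NEG")} - names
    if orphans:
        raise ValueError(f"NAME_NEG entries without NAME_POS: {sorted(orphans)}")
    return [
        SignatureDef(
            name,
            tuple(raw[f"{name}_POS"]),
            tuple(raw.get(f"{name}_NEG", ())),
        )
        for name in sorted(names)
    ]
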