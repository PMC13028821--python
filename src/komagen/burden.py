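"""Per-genome insertion-sequence and prophage-region burden summaries.

Burden is counted from annotation coordinates, not from sequence, so
fragmented or coordinate-only inputs remain summarizable: an element of
1-based inclusive coordinates (start, end) contributes end - start + 1 bp.

Element annotations are long-format rows with columns
``genome, element_type, contig, start, end, label`` where ``element_type``
is ``IS`` for insertion sequences or ``prophage_region`` for predicted
prophage regions/fragments.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .manifest import GenomeManifest

__all__ = [
    "BurdenSummary",
    "LengthDistribution",
    "is_burden",
    "prophage_burden",
    "length_distribution",
    "cross_tool_concordance",
    "load_elements",
]

ELEMENT_COLUMNS = ("genome", "element_type", "contig", "start", "end", "label")

IS_TYPE = "IS"
PROPHAGE_TYPE = "prophage_region"

#: default operational length bins: short < 20 kb, medium 20-50 kb, long >= 50 kb
DEFAULT_BIN_EDGES = (20_000, 50_000)


@dataclass(frozen=True)
class BurdenSummary:
    genome: str
    count: int
    total_length_bp: int
    lengths: tuple[int, ...]


@dataclass(frozen=True)
class LengthDistribution:
    median_bp: float
    iqr: tuple[float, float]
    bin_counts: dict[str, int]  # short / medium / long


def load_elements(path: str | Path) -> pd.DataFrame:
    """Read an element annotation TSV into the long-format table."""
    df = pd.read_csv(path, sep="\t", dtype={"start": int, "end": int})
    missing = [c for c in ELEMENT_COLUMNS if c not in df.columns and c != "label"]
    if missing:
        raise ValueError(f"element table missing column(s): {missing}")
    if "label" not in df.columns:
        df["label"] = pd.NA
    return df[list(ELEMENT_COLUMNS)]


def _lengths(annotations: pd.DataFrame) -> pd.Series:
    lengths = annotations["end"].astype(int) - annotations["start"].astype(int) + 1
    if (lengths <= 0).any():
        bad = annotations.loc[lengths <= 0]
        raise ValueError(
            f"element rows with non-positive length (end < start): "
            f"{bad[['genome', 'contig', 'start', 'end']].to_dict('records')}"
        )
    return lengths


def _burden(
    annotations: pd.DataFrame,
    element_type: str,
    manifest: GenomeManifest | None,
) -> list[BurdenSummary]:
    rows = annotations[annotations["element_type"] == element_type].copy()
    rows["length"] = _lengths(rows) if len(rows) else pd.Series(dtype=int)
    per_genome: dict[str, list[int]] = {}
    for rec in rows.itertuples(index=False):
        per_genome.setdefault(str(rec.genome), []).append(int(rec.length))
    genomes = list(manifest.accessions) if manifest is not None else sorted(per_genome)
    out = []
    for g in genomes:
        lens = tuple(per_genome.get(g, ()))
        out.append(
            BurdenSummary(
                genome=g, count=len(lens), total_length_bp=int(sum(lens)), lengths=lens
            )
        )
    return out


def is_burden(
    annotations: pd.DataFrame, manifest: GenomeManifest | None = None
) -> list[BurdenSummary]:
    """IS burden per genome: element count and cumulative IS sequence length.

    With a manifest, genomes absent from the annotation table are reported
    with count 0 (no annotation is evidence of absence in this summary, not
    missingness).
    """
    return _burden(annotations, IS_TYPE, manifest)


def prophage_burden(
    annotations: pd.DataFrame, manifest: GenomeManifest | None = None
) -> list[BurdenSummary]:
    """Predicted prophage-region burden per genome: region count and total length."""
    return _burden(annotations, PROPHAGE_TYPE, manifest)


def burden_frame(summaries: Sequence[BurdenSummary]) -> pd.DataFrame:
    """Tidy per-genome burden table (genome, count, total_length_bp)."""
    return pd.DataFrame(
        [
            {"genome": s.genome, "count": s.count, "total_length_bp": s.total_length_bp}
            for s in summaries
        ]
    ).set_index("genome")


def length_distribution(
    annotations: pd.DataFrame,
    element_type: str = PROPHAGE_TYPE,
    bin_edges: tuple[int, int] = DEFAULT_BIN_EDGES,
) -> LengthDistribution:
    """Dataset-wide element length distribution with short/medium/long bins.

    Median and quartiles use linear interpolation (the type-7 convention).
    Bins are closed on the left: short [0, lo), medium [lo, hi), long [hi, inf).
    """
    rows = annotations[annotations["element_type"] == element_type]
    if rows.empty:
        raise ValueError(f"no {element_type} rows to summarize")
    lens = _lengths(rows).to_numpy(dtype=float)
    lo, hi = bin_edges
    q1, med, q3 = np.percentile(lens, [25, 50, 75])  # default = linear (type 7)
    return LengthDistribution(
        median_bp=float(med),
        iqr=(float(q1), float(q3)),
        bin_counts={
            "short": int((lens < lo).sum()),
            "medium": int(((lens >= lo) & (lens < hi)).sum()),
            "long": int((lens >= hi).sum()),
        },
    )


def cross_tool_concordance(
    burden_a: Sequence[BurdenSummary], burden_b: Sequence[BurdenSummary]
) -> tuple[float, int]:
    """Rank agreement (Spearman rho) of per-genome burden totals from two tools.

    Returns (rho, n) over the genomes shared by both summaries; fewer than
    three shared genomes is an error.
    """
    from .pangenome import spearman

    a = {s.genome: s.total_length_bp for s in burden_a}
    b = {s.genome: s.total_length_bp for s in burden_b}
    shared = sorted(set(a) & set(b))
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared genomes, got {len(shared)}")
    x = [a[g] for g in shared]
    y = [b[g] for g in shared]
    rho, _ = spearman(x, y)
    return rho, len(shared)
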