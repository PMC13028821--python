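"""Genome manifest loading, curation, and summary statistics.

A *manifest* is the frozen table of genome assemblies a comparative study
operates on: one row per assembly with its RefSeq accession, species and
strain labels, assembly size, isolation source, and a flag marking
clonal/derivative assemblies that must be excluded from mobilome
conservation analyses (near-identical genomes inflate sharing signals).

The package bundles the curated *Komagataeibacter* reference manifest used
throughout the examples: 18 nonredundant complete genomes plus the four
clonal/derivative assemblies flagged for exclusion.  Assembly sizes for the
four excluded rows are not part of the curated record and are stored as 0;
the size invariant (``size_bp > 0``) applies to included records only.
"""

from __future__ import annotations

import re
import warnings
from collections import Counter
from dataclasses import dataclass, replace
from decimal import Decimal, ROUND_HALF_UP
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import pandas as pd

__all__ = [
    "GenomeRecord",
    "GenomeManifest",
    "ManifestSummary",
    "ManifestSchemaError",
    "ManifestValidationError",
    "load_manifest",
    "apply_exclusions",
    "summarize_manifest",
    "reference_manifest",
    "reference_exclusions",
]

REQUIRED_COLUMNS = ("accession", "species", "strain", "size_bp", "source", "excluded_clonal")

#: RefSeq/GenBank assembly accession shape, e.g. GCF_000182745.2
_ACCESSION_RE = re.compile(r"GC[AF]_\d+\.\d+")

_TRUE = {"true", "t", "1", "yes", "y"}
_FALSE = {"false", "f", "0", "no", "n"}


class ManifestSchemaError(ValueError):
    """The manifest file does not have the expected columns."""


class ManifestValidationError(ValueError):
    """The manifest content violates an invariant (e.g. duplicate accession)."""


@dataclass(frozen=True)
class GenomeRecord:
    accession: str
    species: str
    strain: str
    size_bp: int
    source: Optional[str]
    excluded_clonal: bool


@dataclass(frozen=True)
class GenomeManifest:
    records: tuple[GenomeRecord, ...]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[GenomeRecord]:
        return iter(self.records)

    @property
    def accessions(self) -> tuple[str, ...]:
        return tuple(r.accession for r in self.records)

    @property
    def species_of(self) -> dict[str, str]:
        """Accession -> species label map."""
        return {r.accession: r.species for r in self.records}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "accession": r.accession,
                    "species": r.species,
                    "strain": r.strain,
                    "size_bp": r.size_bp,
                    "source": r.source,
                    "excluded_clonal": r.excluded_clonal,
                }
                for r in self.records
            ],
            columns=list(REQUIRED_COLUMNS),
        )


@dataclass(frozen=True)
class ManifestSummary:
    n_genomes: int
    n_species: int
    n_singleton_species: int
    size_median_mb: float
    size_min_mb: float
    size_max_mb: float


def _parse_bool(value: str, accession: str) -> bool:
    v = str(value).strip().lower()
    if v in _TRUE:
        return True
    if v in _FALSE:
        return False
    raise ManifestValidationError(
        f"unparseable excluded_clonal value {value!r} for accession {accession}"
    )


def load_manifest(path: str | Path, provenance: str | None = None) -> GenomeManifest:
    """Load and validate a genome manifest TSV.

    Required columns: accession, species, strain, size_bp, source,
    excluded_clonal.  Missing values (empty fields or the literal ``NA``) in
    the ``source`` column are preserved as ``None``, never as empty strings.

    Raises
    ------
    ManifestSchemaError
        If a required column is missing (the error names the column).
    ManifestValidationError
        On duplicate accessions, non-positive sizes for included records,
        or unparseable fields.
    """
    path = Path(path)
    df = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, na_values=["NA", ""]
    )
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ManifestSchemaError(f"manifest is missing required column: {col!r}")

    records: list[GenomeRecord] = []
    for row in df.itertuples(index=False):
        acc = str(row.accession)
        try:
            size_bp = int(row.size_bp)
        except (TypeError, ValueError):
            raise ManifestValidationError(
                f"unparseable size_bp {row.size_bp!r} for accession {acc}"
            ) from None
        if size_bp < 0:
            raise ManifestValidationError(f"negative size_bp for accession {acc}")
        excluded = _parse_bool(row.excluded_clonal, acc)
        if size_bp == 0 and not excluded:
            raise ManifestValidationError(
                f"included record {acc} must have size_bp > 0"
            )
        source = None if pd.isna(row.source) else str(row.source)
        records.append(
            GenomeRecord(
                accession=acc,
                species=str(row.species),
                strain=str(row.strain),
                size_bp=size_bp,
                source=source,
                excluded_clonal=excluded,
            )
        )

    seen = Counter(r.accession for r in records)
    dupes = sorted(a for a, n in seen.items() if n > 1)
    if dupes:
        raise ManifestValidationError(f"duplicate accession(s) in manifest: {dupes}")

    return GenomeManifest(records=tuple(records), provenance=provenance or str(path))


def apply_exclusions(
    manifest: GenomeManifest, exclusions: Iterable[str]
) -> GenomeManifest:
    """Return a new manifest without the excluded accessions.

    The input manifest is untouched.  Every exclusion must look like an
    assembly accession (``GCF_*``/``GCA_*``); exclusions not present in the
    manifest are permitted but emit a warning.  Applying the same exclusion
    list twice is a no-op the second time (idempotent).
    """
    exclusions = list(exclusions)
    for acc in exclusions:
        if not _ACCESSION_RE.fullmatch(acc):
            raise ManifestValidationError(
                f"exclusion {acc!r} is not a valid assembly accession"
            )
    present = set(manifest.accessions)
    unknown = sorted(set(exclusions) - present)
    if unknown:
        warnings.warn(
            f"exclusion accessions not present in manifest: {unknown}", stacklevel=2
        )
    drop = set(exclusions)
    kept = tuple(r for r in manifest.records if r.accession not in drop)
    return replace(manifest, records=kept)


def _round_mb(size_bp: float) -> float:
    """bp -> Mb rounded half-up to 2 decimals (3,755,000 -> 3.76)."""
    mb = Decimal(repr(size_bp)) / Decimal(1_000_000)
    return float(mb.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def summarize_manifest(manifest: GenomeManifest) -> ManifestSummary:
    """Dataset-level summary: counts and genome-size range in Mb.

    The median for an even number of genomes is the arithmetic mean of the
    two central values; species are counted on the species label verbatim
    (no taxonomy resolution); a singleton species is one represented by a
    single genome in the manifest.
    """
    if len(manifest) == 0:
        raise ManifestValidationError("cannot summarize empty manifest")
    sizes = sorted(r.size_bp for r in manifest.records)
    n = len(sizes)
    if n % 2 == 1:
        median = float(sizes[n // 2])
    else:
        median = (sizes[n // 2 - 1] + sizes[n // 2]) / 2.0
    species_counts = Counter(r.species for r in manifest.records)
    return ManifestSummary(
        n_genomes=n,
        n_species=len(species_counts),
        n_singleton_species=sum(1 for c in species_counts.values() if c == 1),
        size_median_mb=_round_mb(median),
        size_min_mb=_round_mb(sizes[0]),
        size_max_mb=_round_mb(sizes[-1]),
    )


def reference_manifest() -> GenomeManifest:
    """The bundled curated *Komagataeibacter* manifest (22 assemblies)."""
    with resources.as_file(
        resources.files("komagen.data") / "komagataeibacter_manifest.tsv"
    ) as p:
        return load_manifest(p, provenance="bundled Komagataeibacter reference manifest")


def reference_exclusions() -> list[str]:
    """Accessions of the four clonal/derivative assemblies to exclude."""
    text = (resources.files("komagen.data") / "clonal_exclusions.txt").read_text()
    return [line.strip() for line in text.splitlines() if line.strip()]
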