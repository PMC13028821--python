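"""Cellulose-locus (bcs) anchoring, c-di-GMP neighborhood signals, and PCA.

Bacterial cellulose synthesis in acetic acid bacteria is encoded by bcs
operons (bcsA catalytic subunit, bcsB, bcsC/bcsD export-assembly, bcsZ
endoglucanase, bcsQ accessory) and regulated by c-di-GMP, whose levels are
set by GGDEF-domain diguanylate cyclases and EAL-domain phosphodiesterases.
Because genomes frequently carry multiple bcs copies on multiple replicons,
cross-genome comparison is standardized on a per-genome *anchor contig*: the
contig on which bcsA and bcsZ co-localize.  Local regulatory context is then
summarized as GGDEF/EAL gene counts within 50 kb of the anchored bcs span,
and per-target protein similarity is measured alignment-free against a
medoid reference (amino-acid 5-mer Jaccard).  The per-genome features are
z-scored and projected by PCA.

Genomes whose bcsA and bcsZ never co-localize do not qualify for anchor-
based summaries; they stay in the feature matrix with presence-based
features and zero-imputed window features, flagged as non-qualifying.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TargetRule",
    "TargetHit",
    "AnchorSelection",
    "WindowSignals",
    "RichnessFeatureMatrix",
    "PcaProjection",
    "DEFAULT_TARGETS",
    "BCS_TARGETS",
    "find_targets",
    "select_anchor",
    "window_signals",
    "medoid_similarity",
    "build_feature_matrix",
    "pca_project",
    "features_from_gff",
]

#: bcs structural/accessory targets considered for anchoring and presence flags
BCS_TARGETS = ("bcsA", "bcsB", "bcsC", "bcsD", "bcsZ", "bcsQ")

FEATURE_COLUMNS = ("genome", "contig", "start", "end", "strand", "gene", "product", "domains")


@dataclass(frozen=True)
class TargetRule:
    """Matching rules mapping an annotated CDS onto a named target.

    A CDS matches if its gene name is a known synonym, any keyword occurs in
    the (case-folded) product string, or any domain label is attached.
    """

    gene_names: tuple[str, ...] = ()
    product_keywords: tuple[str, ...] = ()
    domain_labels: tuple[str, ...] = ()

    def matches(self, gene: str, product: str, domains: frozenset[str]) -> bool:
        if gene and gene.lower() in {g.lower() for g in self.gene_names}:
            return True
        prod = product.casefold()
        if any(kw.casefold() in prod for kw in self.product_keywords if kw):
            return True
        dl = {d.upper() for d in domains}
        return any(lbl.upper() in dl for lbl in self.domain_labels)


DEFAULT_TARGETS: dict[str, TargetRule] = {
    "bcsA": TargetRule(("bcsA", "acsA"), ("cellulose synthase catalytic",)),
    "bcsB": TargetRule(("bcsB", "acsB"), ("cellulose synthase regulatory", "cyclic di-GMP-binding regulatory")),
    "bcsC": TargetRule(("bcsC", "acsC"), ("cellulose synthase operon protein C", "cellulose synthase subunit C")),
    "bcsD": TargetRule(("bcsD", "acsD"), ("cellulose synthase operon protein D",)),
    "bcsZ": TargetRule(("bcsZ",), ("endoglucanase", "endo-1,4-beta-glucanase")),
    "bcsQ": TargetRule(("bcsQ",), ("cellulose synthesis protein BcsQ",)),
    "GGDEF": TargetRule((), ("diguanylate cyclase",), ("GGDEF",)),
    "EAL": TargetRule((), ("c-di-GMP phosphodiesterase",), ("EAL",)),
}


@dataclass(frozen=True)
class TargetHit:
    genome: str
    target: str
    contig: str
    start: int  # 1-based inclusive
    end: int
    strand: str = "+"
    protein: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"hit start > end ({self.start} > {self.end}) on {self.contig}"
            )


@dataclass(frozen=True)
class AnchorSelection:
    genome: str
    qualifies: bool
    anchor_contig: str | None
    anchor_span: tuple[int, int] | None
    bcsQ_on_anchor: bool
    bcsA_copy_count: int
    bcsA_dispersed: bool
    targets_on_anchor: tuple[str, ...] = ()


@dataclass(frozen=True)
class WindowSignals:
    ggdef_present: bool
    eal_present: bool
    ggdef_count: int
    eal_count: int


@dataclass(frozen=True)
class RichnessFeatureMatrix:
    raw: pd.DataFrame  # genomes x features, pre-scaling
    scaled: pd.DataFrame  # z-scored, constant columns dropped
    means: pd.Series
    sds: pd.Series
    dropped_constant: tuple[str, ...]
    non_qualifying: tuple[str, ...] = ()


@dataclass(frozen=True)
class PcaProjection:
    scores: pd.DataFrame  # genomes x PCs
    loadings: pd.DataFrame  # features x PCs
    variance_explained: tuple[float, ...]


def _parse_domains(value) -> frozenset[str]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return frozenset()
    if isinstance(value, str):
        return frozenset(d.strip() for d in value.split(",") if d.strip())
    return frozenset(str(d) for d in value)


def find_targets(
    features: pd.DataFrame, target_defs: Mapping[str, TargetRule] | None = None
) -> list[TargetHit]:
    """Scan an annotated CDS table for the named targets.

    ``features`` columns: genome, contig, start, end, strand, gene, product,
    domains (comma-separated string or iterable); an optional ``protein``
    column carries the translated sequence.  A CDS with both GGDEF and EAL
    domains yields one hit under each target.
    """
    rules = dict(DEFAULT_TARGETS if target_defs is None else target_defs)
    hits: list[TargetHit] = []
    if features.empty:
        return hits
    has_protein = "protein" in features.columns
    for row in features.itertuples(index=False):
        gene = "" if pd.isna(getattr(row, "gene", "")) else str(getattr(row, "gene", ""))
        product = "" if pd.isna(getattr(row, "product", "")) else str(getattr(row, "product", ""))
        domains = _parse_domains(getattr(row, "domains", None))
        protein = getattr(row, "protein", None) if has_protein else None
        if isinstance(protein, float) and np.isnan(protein):
            protein = None
        for name, rule in rules.items():
            if rule.matches(gene, product, domains):
                hits.append(
                    TargetHit(
                        genome=str(row.genome),
                        target=name,
                        contig=str(row.contig),
                        start=int(row.start),
                        end=int(row.end),
                        strand=str(getattr(row, "strand", "+")),
                        protein=protein,
                    )
                )
    return hits


def select_anchor(
    hits: Sequence[TargetHit],
    genome: str | None = None,
    contig_lengths: Mapping[str, int] | None = None,
) -> AnchorSelection:
    """Pick the per-genome anchor contig where bcsA and bcsZ co-localize.

    If several contigs qualify, the one carrying the most distinct bcs
    targets wins; ties fall to the longer contig (when lengths are known)
    and then to the lexicographically smallest contig ID.  Non-qualifying
    genomes are flagged, never an error.
    """
    genomes = {h.genome for h in hits}
    if len(genomes) > 1:
        raise ValueError(f"hits span multiple genomes: {sorted(genomes)}")
    if genome is None:
        if not genomes:
            raise ValueError("no hits and no genome label given")
        genome = next(iter(genomes))

    bcs_hits = [h for h in hits if h.target in BCS_TARGETS]
    by_contig: dict[str, list[TargetHit]] = {}
    for h in bcs_hits:
        by_contig.setdefault(h.contig, []).append(h)

    bcsa_contigs = {h.contig for h in bcs_hits if h.target == "bcsA"}
    bcsA_copy_count = sum(1 for h in bcs_hits if h.target == "bcsA")
    bcsA_dispersed = len(bcsa_contigs) > 1

    qualifying = [
        c
        for c, hs in by_contig.items()
        if {"bcsA", "bcsZ"} <= {h.target for h in hs}
    ]
    if not qualifying:
        return AnchorSelection(
            genome=genome,
            qualifies=False,
            anchor_contig=None,
            anchor_span=None,
            bcsQ_on_anchor=False,
            bcsA_copy_count=bcsA_copy_count,
            bcsA_dispersed=bcsA_dispersed,
        )

    def rank(contig: str):
        n_targets = len({h.target for h in by_contig[contig]})
        length = (contig_lengths or {}).get(contig, 0)
        return (-n_targets, -length, contig)

    anchor = min(qualifying, key=rank)
    anchor_hits = by_contig[anchor]
    span = (min(h.start for h in anchor_hits), max(h.end for h in anchor_hits))
    targets_on_anchor = tuple(sorted({h.target for h in anchor_hits}))
    return AnchorSelection(
        genome=genome,
        qualifies=True,
        anchor_contig=anchor,
        anchor_span=span,
        bcsQ_on_anchor="bcsQ" in targets_on_anchor,
        bcsA_copy_count=bcsA_copy_count,
        bcsA_dispersed=bcsA_dispersed,
        targets_on_anchor=targets_on_anchor,
    )


def window_signals(
    hits: Sequence[TargetHit],
    anchor: AnchorSelection,
    window_bp: int = 50_000,
    contig_lengths: Mapping[str, int] | None = None,
) -> WindowSignals:
    """GGDEF/EAL gene counts within ``window_bp`` of the anchored bcs span.

    A domain gene counts if its CDS interval intersects (closed intervals)
    the span extended by ``window_bp`` on both sides, clipped to the contig,
    considering the anchor contig only.  Calling this on a non-qualifying
    anchor is an error.
    """
    if not anchor.qualifies:
        raise ValueError(f"genome {anchor.genome} has no qualifying anchor contig")
    assert anchor.anchor_span is not None and anchor.anchor_contig is not None
    lo = max(1, anchor.anchor_span[0] - window_bp)
    hi = anchor.anchor_span[1] + window_bp
    clen = (contig_lengths or {}).get(anchor.anchor_contig)
    if clen is not None:
        hi = min(hi, clen)
    counts = {"GGDEF": 0, "EAL": 0}
    for h in hits:
        if h.target in counts and h.contig == anchor.anchor_contig:
            if h.start <= hi and h.end >= lo:
                counts[h.target] += 1
    return WindowSignals(
        ggdef_present=counts["GGDEF"] > 0,
        eal_present=counts["EAL"] > 0,
        ggdef_count=counts["GGDEF"],
        eal_count=counts["EAL"],
    )


def _kmer_set(seq: str, k: int = 5) -> frozenset[str]:
    if len(seq) < k:
        return frozenset((seq,)) if seq else frozenset()
    return frozenset(seq[i : i + k] for i in range(len(seq) - k + 1))


def _kmer_jaccard_dist(a: frozenset, b: frozenset) -> float:
    if not a and not b:
        return 0.0
    return 1.0 - len(a & b) / len(a | b)


def medoid_similarity(
    protein_seqs: Mapping[str, Mapping[str, str]], k: int = 5
) -> dict[str, dict[str, float]]:
    """Per-target, per-genome similarity to the target's medoid sequence.

    Pairwise distance between two protein sequences is 1 minus the Jaccard
    of their amino-acid k-mer sets; the medoid minimizes the summed distance
    to all carriers (ties break to the lexicographically smallest genome).
    The feature is 1 minus the distance to the medoid, so the medoid itself
    scores 1.0.  Targets carried by fewer than two genomes are skipped;
    genomes lacking a target are imputed 0 downstream.
    """
    out: dict[str, dict[str, float]] = {}
    for target, seqs in protein_seqs.items():
        carriers = sorted(g for g, s in seqs.items() if s)
        if len(carriers) < 2:
            continue
        kmers = {g: _kmer_set(seqs[g], k) for g in carriers}
        summed = {
            g: sum(_kmer_jaccard_dist(kmers[g], kmers[h]) for h in carriers if h != g)
            for g in carriers
        }
        medoid = min(carriers, key=lambda g: (summed[g], g))
        out[target] = {
            g: 1.0 - _kmer_jaccard_dist(kmers[g], kmers[medoid]) for g in carriers
        }
    return out


def build_feature_matrix(
    anchors: Sequence[AnchorSelection],
    windows: Mapping[str, WindowSignals],
    similarities: Mapping[str, Mapping[str, float]] | None = None,
) -> RichnessFeatureMatrix:
    """Assemble and z-score the per-genome richness feature matrix.

    Features: bcsA copy count, bcsA dispersal flag, on-anchor presence flags
    for bcsB/C/D/Z/Q, GGDEF/EAL presence flags and counts within the 50-kb
    window, and per-target medoid similarities.  Non-qualifying genomes get
    zero-imputed anchor/window features and are listed in
    ``non_qualifying``.  Constant columns are dropped before scaling and
    recorded.
    """
    if len(anchors) < 2:
        raise ValueError("need at least 2 genomes to build a feature matrix")
    rows = {}
    non_qualifying = []
    for a in anchors:
        feats: dict[str, float] = {
            "bcsA_copy_count": float(a.bcsA_copy_count),
            "bcsA_dispersed": float(a.bcsA_dispersed),
        }
        for t in ("bcsB", "bcsC", "bcsD", "bcsZ", "bcsQ"):
            feats[f"{t}_on_anchor"] = float(t in a.targets_on_anchor)
        w = windows.get(a.genome)
        if a.qualifies and w is not None:
            feats.update(
                ggdef_present=float(w.ggdef_present),
                eal_present=float(w.eal_present),
                ggdef_count=float(w.ggdef_count),
                eal_count=float(w.eal_count),
            )
        else:
            feats.update(ggdef_present=0.0, eal_present=0.0, ggdef_count=0.0, eal_count=0.0)
        if not a.qualifies:
            non_qualifying.append(a.genome)
        rows[a.genome] = feats
    raw = pd.DataFrame.from_dict(rows, orient="index").sort_index(axis=1)
    raw.index.name = "genome"
    for target, sims in (similarities or {}).items():
        col = f"sim_{target}"
        raw[col] = [float(sims.get(g, 0.0)) for g in raw.index]
    if raw.isna().any().any():
        raise ValueError("feature matrix contains NA after imputation")

    sds = raw.std(ddof=1)
    constant = tuple(sds.index[sds == 0.0])
    kept = raw.drop(columns=list(constant))
    means = kept.mean()
    kept_sds = kept.std(ddof=1)
    scaled = (kept - means) / kept_sds
    return RichnessFeatureMatrix(
        raw=raw,
        scaled=scaled,
        means=means,
        sds=kept_sds,
        dropped_constant=constant,
        non_qualifying=tuple(non_qualifying),
    )


def pca_project(m: RichnessFeatureMatrix, n_components: int = 2) -> PcaProjection:
    """PCA of the scaled feature matrix via covariance eigendecomposition.

    Components are ordered by decreasing eigenvalue; each loading vector's
    sign is fixed so its largest-magnitude entry is positive.  Variance
    fractions are relative to the total variance of the scaled matrix.
    """
    x = m.scaled.to_numpy(dtype=float)
    if x.shape[1] < 1 or np.allclose(x, x[0:1, :]):
        raise ValueError("no variance to project")
    cov = np.cov(x, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    nc = min(n_components, x.shape[1])
    vecs = eigvecs[:, :nc]
    for c in range(nc):
        jmax = int(np.argmax(np.abs(vecs[:, c])))
        if vecs[jmax, c] < 0:
            vecs[:, c] = -vecs[:, c]
    scores = x @ vecs
    total = eigvals.sum()
    frac = tuple(float(v / total) for v in eigvals[:nc]) if total > 0 else (0.0,) * nc
    pcs = [f"PC{i + 1}" for i in range(nc)]
    return PcaProjection(
        scores=pd.DataFrame(scores, index=m.scaled.index, columns=pcs),
        loadings=pd.DataFrame(vecs, index=m.scaled.columns, columns=pcs),
        variance_explained=frac,
    )


def features_from_gff(path: str | Path, genome: str) -> pd.DataFrame:
    """Read CDS rows of a GFF3 file into the annotated feature table.

    Recognized attributes: ``gene``, ``product``, ``domain`` (repeatable or
    comma-separated), ``translation`` (protein sequence).
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    rows = []
    for feat in db.features_of_type("CDS"):
        domains = feat.attributes.get("domain", [])
        flat: list[str] = []
        for d in domains:
            flat.extend(x.strip() for x in str(d).split(",") if x.strip())
        translation = feat.attributes.get("translation", [None])[0]
        rows.append(
            {
                "genome": genome,
                "contig": feat.seqid,
                "start": int(feat.start),
                "end": int(feat.end),
                "strand": feat.strand or "+",
                "gene": feat.attributes.get("gene", [""])[0],
                "product": feat.attributes.get("product", [""])[0],
                "domains": ",".join(flat),
                "protein": translation,
            }
        )
    return pd.DataFrame(rows, columns=list(FEATURE_COLUMNS) + ["protein"])
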