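"""Plasmid homology clustering, conservation classification, and validation.

Plasmids are clustered into homology groups as the connected components of
the graph whose edges join plasmid pairs with Mash distance at or below a
threshold (single linkage; default 0.10).  Single linkage deliberately lets
a tight conserved backbone and loosely attached mosaic members fall into the
same group, which is the structure the within-cluster dispersion summary is
designed to expose.

Within each cluster the all-by-all Mash distances are summarized as median,
minimum, and maximum, and the median drives a three-way conservation call:

    median < 0.02          -> highly_conserved   (shared backbone)
    0.02 <= median <= 0.05 -> moderately_conserved
    median > 0.05          -> mosaic_like        (module-driven sharing)

Size-1 components are retained and labelled ``singleton`` (no pairs exist).

Plasmid IDs follow the catalog convention ``<host accession>|<plasmid name>``
so that the genome-by-cluster presence matrix and species spans can be built
directly against a genome manifest.
"""

from __future__ import annotations

import re
import statistics
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .manifest import GenomeManifest
from .sketch import DistanceMatrix

__all__ = [
    "PlasmidCluster",
    "PlasmidClusterSet",
    "ClusterDispersion",
    "PresenceMatrix",
    "ConcordanceSummary",
    "cluster_plasmids",
    "dispersion_stats",
    "classify_conservation",
    "presence_matrix",
    "product_concordance",
    "ingest_mobility_table",
    "host_of",
]

HIGHLY_CONSERVED = "highly_conserved"
MODERATELY_CONSERVED = "moderately_conserved"
MOSAIC_LIKE = "mosaic_like"
SINGLETON = "singleton"

MOBILITY_CATEGORIES = ("conjugative", "mobilizable", "non-mobilizable", "unknown")


def host_of(plasmid_id: str) -> str:
    """Host genome accession from a ``<accession>|<plasmid>`` catalog ID."""
    return plasmid_id.split("|", 1)[0]


@dataclass(frozen=True)
class PlasmidCluster:
    cluster_id: int
    members: tuple[str, ...]

    @property
    def is_singleton(self) -> bool:
        return len(self.members) == 1

    def hosts(self, hosts: Mapping[str, str] | None = None) -> tuple[str, ...]:
        if hosts is None:
            return tuple(host_of(m) for m in self.members)
        return tuple(hosts[m] for m in self.members)


@dataclass(frozen=True)
class PlasmidClusterSet:
    clusters: tuple[PlasmidCluster, ...]
    threshold_used: float

    @property
    def multi_member(self) -> tuple[PlasmidCluster, ...]:
        return tuple(c for c in self.clusters if not c.is_singleton)

    @property
    def n_clustered_plasmids(self) -> int:
        """Plasmids in multi-member clusters (singletons not counted)."""
        return sum(len(c.members) for c in self.multi_member)

    def __getitem__(self, cluster_id: int) -> PlasmidCluster:
        for c in self.clusters:
            if c.cluster_id == cluster_id:
                return c
        raise KeyError(cluster_id)


@dataclass(frozen=True)
class ClusterDispersion:
    cluster_id: int
    n_pairs: int
    median_d: float | None
    min_d: float | None
    max_d: float | None
    category: str


@dataclass(frozen=True)
class PresenceMatrix:
    matrix: pd.DataFrame  # genomes x cluster_ids, 0/1
    species: pd.Series  # species label per genome
    species_span: pd.Series  # per cluster: distinct host species labels

    @property
    def cluster_counts(self) -> pd.Series:
        """Per-genome number of clusters represented (row sums)."""
        return self.matrix.sum(axis=1)


@dataclass(frozen=True)
class ConcordanceSummary:
    cluster_id: int
    pairwise_jaccard: tuple[float, ...]
    median_jaccard: float


def cluster_plasmids(dm: DistanceMatrix, threshold: float = 0.10) -> PlasmidClusterSet:
    """Single-linkage homology clusters at a Mash distance threshold.

    Components of size 1 are retained as singletons.  Cluster IDs are dense
    from 1, ordered by descending size then by the lexicographically smallest
    member, so "Cluster 1" is always the largest group.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    g = nx.Graph()
    g.add_nodes_from(dm.labels)
    n = len(dm.labels)
    for i in range(n):
        for j in range(i + 1, n):
            if dm.d[i, j] <= threshold:
                g.add_edge(dm.labels[i], dm.labels[j])
    comps = [tuple(sorted(c)) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    clusters = tuple(
        PlasmidCluster(cluster_id=i + 1, members=c) for i, c in enumerate(comps)
    )
    return PlasmidClusterSet(clusters=clusters, threshold_used=threshold)


def classify_conservation(median_d: float) -> str:
    """Three-way conservation call from a within-cluster median Mash distance."""
    if not (0.0 <= median_d <= 1.0):
        raise ValueError(f"median distance must be in [0, 1], got {median_d}")
    if median_d < 0.02:
        return HIGHLY_CONSERVED
    if median_d <= 0.05:
        return MODERATELY_CONSERVED
    return MOSAIC_LIKE


def dispersion_stats(cluster: PlasmidCluster, dm: DistanceMatrix) -> ClusterDispersion:
    """Median/min/max over the n(n-1)/2 within-cluster Mash distances."""
    missing = [m for m in cluster.members if m not in dm.labels]
    if missing:
        raise ValueError(f"cluster members missing from distance matrix: {missing}")
    if cluster.is_singleton:
        return ClusterDispersion(cluster.cluster_id, 0, None, None, None, SINGLETON)
    pairs = [
        dm.get(a, b)
        for idx, a in enumerate(cluster.members)
        for b in cluster.members[idx + 1 :]
    ]
    med = statistics.median(pairs)
    return ClusterDispersion(
        cluster_id=cluster.cluster_id,
        n_pairs=len(pairs),
        median_d=med,
        min_d=min(pairs),
        max_d=max(pairs),
        category=classify_conservation(med),
    )


def presence_matrix(
    clusters: PlasmidClusterSet,
    manifest: GenomeManifest,
    hosts: Mapping[str, str] | None = None,
    include_singletons: bool = False,
) -> PresenceMatrix:
    """Binary genome-by-cluster presence matrix with per-cluster species spans.

    Hosts default to the ``<accession>|<plasmid>`` ID convention.  Every host
    accession must appear in the manifest (orphans are an error).  Singleton
    clusters are excluded from the matrix columns unless requested.
    """
    species = manifest.species_of
    use = clusters.clusters if include_singletons else clusters.multi_member
    genomes = list(manifest.accessions)
    mat = pd.DataFrame(
        0, index=pd.Index(genomes, name="genome"),
        columns=pd.Index([c.cluster_id for c in use], name="cluster_id"),
        dtype=int,
    )
    span: dict[int, int] = {}
    for c in use:
        c_hosts = c.hosts(hosts)
        orphans = sorted(set(c_hosts) - set(genomes))
        if orphans:
            raise ValueError(
                f"cluster {c.cluster_id} has host accession(s) not in manifest: {orphans}"
            )
        for h in c_hosts:
            mat.loc[h, c.cluster_id] = 1
        span[c.cluster_id] = len({species[h] for h in c_hosts})
    return PresenceMatrix(
        matrix=mat,
        species=pd.Series(species, name="species").reindex(genomes),
        species_span=pd.Series(span, name="species_span", dtype=int),
    )


def _normalize_product(product: str) -> str:
    p = re.sub(r"\s+", " ", product.casefold().strip())
    return p.rstrip(".,;:")


def _jaccard(a: set, b: set) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def product_concordance(
    cluster: PlasmidCluster, products: Mapping[str, Iterable[str]]
) -> ConcordanceSummary:
    """Pairwise Jaccard overlap of normalized CDS product sets within a cluster.

    Product strings are case-folded, whitespace-collapsed, and stripped of
    trailing punctuation before comparison; Jaccard of two empty sets is 1.
    """
    missing = [m for m in cluster.members if m not in products]
    if missing:
        raise ValueError(f"product sets missing for cluster members: {missing}")
    sets = {
        m: {_normalize_product(p) for p in products[m]} for m in cluster.members
    }
    vals = tuple(
        _jaccard(sets[a], sets[b])
        for idx, a in enumerate(cluster.members)
        for b in cluster.members[idx + 1 :]
    )
    if not vals:
        raise ValueError("concordance undefined for a singleton cluster")
    return ConcordanceSummary(
        cluster_id=cluster.cluster_id,
        pairwise_jaccard=vals,
        median_jaccard=statistics.median(vals),
    )


def ingest_mobility_table(path: str | Path) -> pd.DataFrame:
    """Per-genome plasmid mobility counts from a mobility-typing TSV.

    Expects columns ``plasmid_id``, ``host_accession``, ``predicted_mobility``
    and ``relaxase_type``.  Mobility labels are matched case-insensitively to
    conjugative / mobilizable / non-mobilizable / unknown; unrecognized
    labels are bucketed as unknown with a warning.  Returns a DataFrame
    indexed by genome with one integer column per mobility category plus a
    ``relaxase_types`` column (sorted, comma-joined distinct detected types).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, na_values=["NA", ""])
    required = ("plasmid_id", "host_accession", "predicted_mobility", "relaxase_type")
    for col in required:
        if col not in df.columns:
            raise ValueError(f"mobility table is missing required column: {col!r}")
    rows: dict[str, dict] = {}
    for rec in df.itertuples(index=False):
        genome = rec.host_accession
        entry = rows.setdefault(
            genome, {c: 0 for c in MOBILITY_CATEGORIES} | {"_relaxases": set()}
        )
        label = str(rec.predicted_mobility).strip().lower().replace("_", "-")
        if label not in MOBILITY_CATEGORIES:
            warnings.warn(
                f"unrecognized mobility label {rec.predicted_mobility!r}; "
                "bucketed as unknown",
                stacklevel=2,
            )
            label = "unknown"
        entry[label] += 1
        if not pd.isna(rec.relaxase_type) and str(rec.relaxase_type) != "-":
            entry["_relaxases"].add(str(rec.relaxase_type))
    out = pd.DataFrame.from_dict(rows, orient="index")
    if out.empty:
        out = pd.DataFrame(columns=list(MOBILITY_CATEGORIES) + ["relaxase_types"])
        out.index.name = "genome"
        return out
    out["relaxase_types"] = out.pop("_relaxases").map(lambda s: ",".join(sorted(s)))
    out.index.name = "genome"
    return out[list(MOBILITY_CATEGORIES) + ["relaxase_types"]]
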