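"""Pangenome composition metrics and cross-module correlation linkage.

Composition partitions gene clusters by prevalence: *core* clusters occur in
every genome, *singletons* in exactly one, *accessory* in between.  Per
genome, counts are restricted to the clusters that genome carries, and
fractions divide by the genome's total cluster count.

Linkage evaluates all unordered pairs of per-genome variables (composition
metrics, plasmid cluster counts, IS burden, richness PC scores) with
tie-corrected Spearman correlations.  Two-sided p values come from exact
permutation enumeration for n <= 9 and the t approximation otherwise, and
the Benjamini-Hochberg step-up adjustment converts each analysis family's
p values to q values.
"""

from __future__ import annotations

import math
import warnings
from itertools import combinations, permutations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "load_membership",
    "composition_metrics",
    "spearman",
    "bh_adjust",
    "linkage_analysis",
    "assemble_features",
]

EXACT_PERMUTATION_MAX_N = 9


def load_membership(path: str | Path) -> pd.DataFrame:
    """Load a gene-cluster membership TSV into a cluster x genome 0/1 matrix.

    Accepts either a wide matrix (first column ``cluster_id``, one column
    per genome) or a long table with columns cluster_id, genome, present.
    """
    df = pd.read_csv(path, sep="\t")
    if {"cluster_id", "genome", "present"} <= set(df.columns):
        wide = df.pivot_table(
            index="cluster_id", columns="genome", values="present", fill_value=0
        )
        return (wide > 0).astype(int)
    if "cluster_id" not in df.columns:
        raise ValueError("membership table missing 'cluster_id' column")
    wide = df.set_index("cluster_id")
    return (wide > 0).astype(int)


def composition_metrics(membership: pd.DataFrame) -> pd.DataFrame:
    """Per-genome core/accessory/singleton partition of carried gene clusters.

    ``membership`` is a cluster x genome 0/1 incidence matrix.  Returns a
    genome-indexed frame with total/core/accessory/singleton cluster counts
    and accessory/singleton fractions of the per-genome total.
    """
    m = (membership > 0).astype(int)
    if m.shape[1] < 2:
        raise ValueError("composition requires >= 2 genomes (core undefined)")
    if (m.sum(axis=1) == 0).any():
        raise ValueError("membership table has cluster(s) present in no genome")
    prevalence = m.sum(axis=1)
    n_genomes = m.shape[1]
    is_core = prevalence == n_genomes
    is_singleton = prevalence == 1
    is_accessory = ~(is_core | is_singleton)
    rows = {}
    for g in m.columns:
        carried = m[g] > 0
        total = int(carried.sum())
        core = int((carried & is_core).sum())
        singleton = int((carried & is_singleton).sum())
        accessory = int((carried & is_accessory).sum())
        rows[g] = {
            "total_clusters": total,
            "core_clusters": core,
            "accessory_clusters": accessory,
            "singleton_clusters": singleton,
            "accessory_fraction": accessory / total if total else 0.0,
            "singleton_fraction": singleton / total if total else 0.0,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "genome"
    return out


def _rank(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt((xc * xc).sum() * (yc * yc).sum())
    return float((xc * yc).sum() / denom)


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Tie-corrected Spearman correlation with a two-sided p value.

    rho is the Pearson correlation of mid-ranks (average ranks for ties).
    For n <= 9 the p value is the exact two-sided permutation probability
    P(|rho_perm| >= |rho_obs|) over all n! pairings; for larger n the usual
    t approximation with n - 2 degrees of freedom is used.  A zero-variance
    input leaves rho undefined and raises ``ValueError``.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = xv.size
    if n < 3:
        raise ValueError("need n >= 3 observations")
    if not (np.isfinite(xv).all() and np.isfinite(yv).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise ValueError("zero-variance input: Spearman rho undefined")
    rx, ry = _rank(xv), _rank(yv)
    rho = _pearson(rx, ry)
    if n <= EXACT_PERMUTATION_MAX_N:
        target = abs(rho) - 1e-12
        hits = 0
        total = 0
        for perm in permutations(range(n)):
            total += 1
            if abs(_pearson(rx, ry[list(perm)])) >= target:
                hits += 1
        p = hits / total
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = 2.0 * float(sps.t.sf(abs(t), df=n - 2))
    return rho, min(p, 1.0)


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up q values, in the input order.

    q(i) = min over j >= i of m * p(j) / j after ascending sort, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q.tolist()


def assemble_features(*frames: pd.DataFrame | pd.Series) -> pd.DataFrame:
    """Outer-join per-genome feature tables on the genome index."""
    parts = [f.to_frame() if isinstance(f, pd.Series) else f for f in frames]
    return pd.concat(parts, axis=1, join="outer")


def linkage_analysis(features: pd.DataFrame) -> pd.DataFrame:
    """Spearman + BH over all unordered pairs of per-genome variables.

    NA handling is pairwise-complete: each pair uses the genomes where both
    variables are observed, and its n is reported.  Pairs with fewer than 3
    complete observations or a zero-variance member are dropped with a
    warning.  BH is applied across all retained pairs of this call (one
    family); run subsets (e.g. plasmid-bearing genomes only) as separate
    calls to give them their own correction family.

    Returns a frame with columns var_a, var_b, rho, p, q, n.
    """
    cols = list(features.columns)
    records = []
    for a, b in combinations(cols, 2):
        sub = features[[a, b]].dropna()
        if len(sub) < 3:
            warnings.warn(f"pair ({a}, {b}) dropped: <3 complete observations", stacklevel=2)
            continue
        try:
            rho, p = spearman(sub[a].to_numpy(), sub[b].to_numpy())
        except ValueError as e:
            warnings.warn(f"pair ({a}, {b}) dropped: {e}", stacklevel=2)
            continue
        records.append({"var_a": a, "var_b": b, "rho": rho, "p": p, "n": len(sub)})
    out = pd.DataFrame(records, columns=["var_a", "var_b", "rho", "p", "n"])
    if len(out):
        out["q"] = bh_adjust(out["p"].tolist())
    else:
        out["q"] = []
    return out[["var_a", "var_b", "rho", "p", "q", "n"]]
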