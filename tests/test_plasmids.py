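from __future__ import annotations

import numpy as np
import pytest

from _oracles import connected_components
from komagen.manifest import GenomeManifest, GenomeRecord
from komagen.plasmids import (
    HIGHLY_CONSERVED,
    MODERATELY_CONSERVED,
    MOSAIC_LIKE,
    SINGLETON,
    PlasmidCluster,
    classify_conservation,
    cluster_plasmids,
    dispersion_stats,
    ingest_mobility_table,
    presence_matrix,
    product_concordance,
)
from komagen.sketch import DistanceMatrix


def dm_from(labels, pairs):
    """Distance matrix with given off-diagonal distances, default 1.0."""
    n = len(labels)
    d = np.ones((n, n)) - np.eye(n)
    for (a, b), v in pairs.items():
        i, j = labels.index(a), labels.index(b)
        d[i, j] = d[j, i] = v
    return DistanceMatrix(tuple(labels), d)


def random_dm(rng, n):
    d = rng.uniform(0, 1, size=(n, n))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(tuple(f"p{i:02d}" for i in range(n)), d)


class TestClustering:
    def test_all_far_apart_gives_only_singletons(self):
        dm = dm_from(["a", "b", "c"], {})
        cs = cluster_plasmids(dm, 0.1)
        assert all(c.is_singleton for c in cs.clusters)
        assert cs.n_clustered_plasmids == 0

    def test_transitive_single_linkage(self):
        """a-b and b-c below threshold chain a,b,c even though d(a,c) is large."""
        dm = dm_from(
            ["a", "b", "c"], {("a", "b"): 0.05, ("b", "c"): 0.05, ("a", "c"): 0.30}
        )
        cs = cluster_plasmids(dm, 0.1)
        assert cs.clusters[0].members == ("a", "b", "c")

    def test_cluster_ids_dense_and_size_ordered(self, rng):
        dm = random_dm(rng, 12)
        cs = cluster_plasmids(dm, 0.4)
        ids = [c.cluster_id for c in cs.clusters]
        assert ids == list(range(1, len(ids) + 1))
        sizes = [len(c.members) for c in cs.clusters]
        assert sizes == sorted(sizes, reverse=True)

    def test_matches_bruteforce_components(self, rng):
        """Single-linkage clusters equal union-find components on random instances."""
        for _ in range(30):
            n = int(rng.integers(3, 12))
            dm = random_dm(rng, n)
            thr = float(rng.uniform(0.05, 0.9))
            cs = cluster_plasmids(dm, thr)
            edges = {
                (dm.labels[i], dm.labels[j])
                for i in range(n)
                for j in range(i + 1, n)
                if dm.d[i, j] <= thr
            }
            expected = connected_components(list(dm.labels), edges)
            assert [c.members for c in cs.clusters] == expected

    def test_threshold_monotonicity(self, rng):
        """Raising the threshold never increases the number of components."""
        dm = random_dm(rng, 15)
        counts = [
            len(cluster_plasmids(dm, t).clusters) for t in (0.1, 0.3, 0.5, 0.7, 0.9)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_label_permutation_invariance(self, rng):
        dm = random_dm(rng, 8)
        perm = rng.permutation(8)
        dm2 = DistanceMatrix(
            tuple(dm.labels[i] for i in perm), dm.d[np.ix_(perm, perm)]
        )
        a = cluster_plasmids(dm, 0.35)
        b = cluster_plasmids(dm2, 0.35)
        assert [c.members for c in a.clusters] == [c.members for c in b.clusters]

    def test_threshold_bounds(self, rng):
        dm = random_dm(rng, 4)
        with pytest.raises(ValueError):
            cluster_plasmids(dm, 0.0)


class TestDispersion:
    def test_size_two_cluster_single_pair(self):
        dm = dm_from(["a", "b"], {("a", "b"): 0.004})
        d = dispersion_stats(PlasmidCluster(1, ("a", "b")), dm)
        assert d.n_pairs == 1
        assert d.median_d == d.min_d == d.max_d == 0.004
        assert d.category == HIGHLY_CONSERVED

    def test_size_seven_cluster_has_21_pairs(self, rng):
        labels = [f"p{i}" for i in range(7)]
        d = rng.uniform(0.001, 0.01, size=(7, 7))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        disp = dispersion_stats(
            PlasmidCluster(1, tuple(labels)), DistanceMatrix(tuple(labels), d)
        )
        assert disp.n_pairs == 21

    def test_size_three_cluster_stats(self):
        dm = dm_from(
            ["a", "b", "c"], {("a", "b"): 0.01, ("a", "c"): 0.02, ("b", "c"): 0.06}
        )
        d = dispersion_stats(PlasmidCluster(1, ("a", "b", "c")), dm)
        assert (d.median_d, d.min_d, d.max_d) == (0.02, 0.01, 0.06)

    def test_singleton_category(self):
        dm = dm_from(["a", "b"], {})
        d = dispersion_stats(PlasmidCluster(2, ("a",)), dm)
        assert d.category == SINGLETON
        assert d.n_pairs == 0

    def test_member_missing_from_matrix(self):
        dm = dm_from(["a", "b"], {})
        with pytest.raises(ValueError, match="missing"):
            dispersion_stats(PlasmidCluster(1, ("a", "z")), dm)


@pytest.mark.parametrize(
    "median_d,expected",
    [
        (0.001, HIGHLY_CONSERVED),
        (0.0199, HIGHLY_CONSERVED),
        (0.02, MODERATELY_CONSERVED),  # boundary: closed interval
        (0.035, MODERATELY_CONSERVED),
        (0.05, MODERATELY_CONSERVED),  # boundary: closed interval
        (0.052, MOSAIC_LIKE),
    ],
)
def test_conservation_classification(median_d, expected):
    assert classify_conservation(median_d) == expected


def tiny_manifest(accs_species):
    return GenomeManifest(
        tuple(
            GenomeRecord(a, sp, f"s{i}", 1_000_000, None, False)
            for i, (a, sp) in enumerate(accs_species)
        )
    )


class TestPresenceMatrix:
    def test_species_span(self):
        mani = tiny_manifest(
            [(f"GCF_00000000{i}.1", f"sp{i}") for i in range(1, 7)]
        )
        members = tuple(f"GCF_00000000{i}.1|p1" for i in range(1, 7))
        cs_clusters = (PlasmidCluster(1, members),)
        from komagen.plasmids import PlasmidClusterSet

        pm = presence_matrix(PlasmidClusterSet(cs_clusters, 0.1), mani)
        assert pm.species_span[1] == 6
        assert pm.matrix[1].sum() == 6

    def test_single_species_span(self):
        mani = tiny_manifest([("GCF_000000001.1", "sp"), ("GCF_000000002.1", "sp")])
        from komagen.plasmids import PlasmidClusterSet

        cs = PlasmidClusterSet(
            (PlasmidCluster(1, ("GCF_000000001.1|a", "GCF_000000002.1|b")),), 0.1
        )
        pm = presence_matrix(cs, mani)
        assert pm.species_span[1] == 1

    def test_no_multi_member_clusters_gives_all_zero(self):
        mani = tiny_manifest([("GCF_000000001.1", "sp")])
        from komagen.plasmids import PlasmidClusterSet

        cs = PlasmidClusterSet((PlasmidCluster(1, ("GCF_000000001.1|a",)),), 0.1)
        pm = presence_matrix(cs, mani)
        assert pm.matrix.shape == (1, 0)
        assert pm.matrix.to_numpy().sum() == 0

    def test_orphan_host_rejected(self):
        mani = tiny_manifest([("GCF_000000001.1", "sp")])
        from komagen.plasmids import PlasmidClusterSet

        cs = PlasmidClusterSet(
            (PlasmidCluster(1, ("GCF_000000001.1|a", "GCF_000000009.1|b")),), 0.1
        )
        with pytest.raises(ValueError, match="not in manifest"):
            presence_matrix(cs, mani)


class TestProductConcordance:
    def test_identical_sets(self):
        c = PlasmidCluster(1, ("x", "y"))
        s = product_concordance(c, {"x": ["repA", "mobC"], "y": ["repA", "mobC"]})
        assert s.pairwise_jaccard == (1.0,)
        assert s.median_jaccard == 1.0

    def test_disjoint_nonempty_sets(self):
        c = PlasmidCluster(1, ("x", "y"))
        s = product_concordance(c, {"x": ["repA"], "y": ["mobC"]})
        assert s.pairwise_jaccard == (0.0,)

    def test_partial_overlap_half(self):
        c = PlasmidCluster(1, ("x", "y"))
        s = product_concordance(c, {"x": ["a", "b", "c"], "y": ["b", "c", "d"]})
        assert s.pairwise_jaccard == (0.5,)

    def test_normalization_folds_case_and_whitespace(self):
        c = PlasmidCluster(1, ("x", "y"))
        s = product_concordance(
            c, {"x": ["Replication  Protein A."], "y": ["replication protein a"]}
        )
        assert s.median_jaccard == 1.0

    def test_both_empty_sets_jaccard_one(self):
        c = PlasmidCluster(1, ("x", "y"))
        assert product_concordance(c, {"x": [], "y": []}).median_jaccard == 1.0

    def test_missing_member_listed(self):
        c = PlasmidCluster(1, ("x", "y"))
        with pytest.raises(ValueError, match="y"):
            product_concordance(c, {"x": ["a"]})


class TestMobilityIngestion:
    def write(self, tmp_path, rows):
        p = tmp_path / "mobility.tsv"
        header = "plasmid_id\thost_accession\tpredicted_mobility\trelaxase_type\n"
        p.write_text(header + "".join("\t".join(r) + "\n" for r in rows))
        return p

    def test_counts_per_genome(self, tmp_path):
        rows = [
            ("p1", "G1", "conjugative", "MOBQ"),
            ("p2", "G1", "conjugative", "MOBF"),
            ("p3", "G1", "conjugative", "MOBP"),
            ("p4", "G2", "mobilizable", "MOBQ"),
        ]
        out = ingest_mobility_table(self.write(tmp_path, rows))
        assert out.loc["G1", "conjugative"] == 3
        assert out.loc["G2", "mobilizable"] == 1
        assert out.loc["G1", "relaxase_types"] == "MOBF,MOBP,MOBQ"

    def test_mixed_case_label_normalized(self, tmp_path):
        out = ingest_mobility_table(
            self.write(tmp_path, [("p1", "G1", "Conjugative", "MOBQ")])
        )
        assert out.loc["G1", "conjugative"] == 1

    def test_unrecognized_label_bucketed_unknown_with_warning(self, tmp_path):
        p = self.write(tmp_path, [("p1", "G1", "weird-label", "-")])
        with pytest.warns(UserWarning, match="unrecognized"):
            out = ingest_mobility_table(p)
        assert out.loc["G1", "unknown"] == 1

    def test_empty_table(self, tmp_path):
        out = ingest_mobility_table(self.write(tmp_path, []))
        assert out.empty
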