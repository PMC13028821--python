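from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from komagen.richness import (
    AnchorSelection,
    TargetHit,
    build_feature_matrix,
    features_from_gff,
    find_targets,
    medoid_similarity,
    pca_project,
    select_anchor,
    window_signals,
)

COLS = ["genome", "contig", "start", "end", "strand", "gene", "product", "domains"]


def feat(genome="G1", contig="c1", start=100, end=200, gene="", product="", domains=""):
    return dict(
        genome=genome, contig=contig, start=start, end=end, strand="+",
        gene=gene, product=product, domains=domains,
    )


def hit(target, contig="c1", start=100, end=200, genome="G1"):
    return TargetHit(genome=genome, target=target, contig=contig, start=start, end=end)


class TestFindTargets:
    def test_gene_name_match(self):
        df = pd.DataFrame([feat(gene="bcsA")], columns=COLS)
        hits = find_targets(df)
        assert [h.target for h in hits] == ["bcsA"]

    def test_product_keyword_match(self):
        df = pd.DataFrame(
            [feat(product="Cellulose synthase catalytic subunit [UDP-forming]")],
            columns=COLS,
        )
        assert [h.target for h in find_targets(df)] == ["bcsA"]

    def test_dual_domain_protein_hits_both_targets(self):
        df = pd.DataFrame([feat(domains="GGDEF,EAL")], columns=COLS)
        targets = sorted(h.target for h in find_targets(df))
        assert targets == ["EAL", "GGDEF"]

    def test_empty_table(self):
        assert find_targets(pd.DataFrame(columns=COLS)) == []


class TestSelectAnchor:
    def test_colocalized_pair_qualifies(self):
        hits = [hit("bcsA", start=100, end=200), hit("bcsZ", start=500, end=700)]
        a = select_anchor(hits)
        assert a.qualifies and a.anchor_contig == "c1"
        assert a.anchor_span == (100, 700)

    def test_split_contigs_do_not_qualify(self):
        hits = [hit("bcsA", contig="c1"), hit("bcsZ", contig="c2")]
        a = select_anchor(hits)
        assert not a.qualifies
        assert a.anchor_contig is None and a.anchor_span is None

    def test_bcsq_selected_from_anchor_contig(self):
        hits = [hit("bcsA"), hit("bcsZ"), hit("bcsQ", start=900, end=1000)]
        a = select_anchor(hits)
        assert a.bcsQ_on_anchor
        assert a.anchor_span == (100, 1000)

    def test_copy_count_and_dispersal(self):
        hits = [
            hit("bcsA", contig="c1", start=100, end=200),
            hit("bcsA", contig="c1", start=5000, end=5100),
            hit("bcsA", contig="c2"),
            hit("bcsZ", contig="c1", start=900, end=1000),
        ]
        a = select_anchor(hits)
        assert a.bcsA_copy_count == 3
        assert a.bcsA_dispersed
        assert a.qualifies and a.anchor_contig == "c1"

    def test_tie_break_more_targets_then_length_then_lexicographic(self):
        both = lambda c: [hit("bcsA", contig=c), hit("bcsZ", contig=c)]
        # c2 carries an extra target -> wins on target count
        hits = both("c1") + both("c2") + [hit("bcsB", contig="c2")]
        assert select_anchor(hits).anchor_contig == "c2"
        # equal targets -> longer contig wins
        hits = both("c1") + both("c2")
        a = select_anchor(hits, contig_lengths={"c1": 1000, "c2": 5000})
        assert a.anchor_contig == "c2"
        # equal targets, equal length -> lexicographic smallest
        a = select_anchor(hits, contig_lengths={"c1": 1000, "c2": 1000})
        assert a.anchor_contig == "c1"

    def test_order_invariance(self):
        hits = [
            hit("bcsA"), hit("bcsZ", start=300, end=400),
            hit("bcsB", contig="c2"), hit("bcsQ", start=600, end=700),
        ]
        expected = select_anchor(hits)
        for perm in itertools.permutations(hits):
            assert select_anchor(list(perm)) == expected

    def test_hits_from_multiple_genomes_rejected(self):
        with pytest.raises(ValueError, match="multiple genomes"):
            select_anchor([hit("bcsA", genome="G1"), hit("bcsZ", genome="G2")])


class TestWindowSignals:
    def anchor(self):
        return select_anchor(
            [hit("bcsA", start=100_000, end=102_000), hit("bcsZ", start=105_000, end=106_000)]
        )

    def test_domain_gene_inside_window(self):
        hits = [hit("GGDEF", start=116_000, end=117_000)]  # 10 kb downstream
        w = window_signals(hits, self.anchor())
        assert w.ggdef_present and w.ggdef_count == 1
        assert not w.eal_present

    def test_domain_gene_outside_window(self):
        hits = [hit("GGDEF", start=166_001, end=167_000)]  # 60 kb downstream
        w = window_signals(hits, self.anchor())
        assert not w.ggdef_present and not w.eal_present

    def test_straddling_window_edge_by_one_bp_counts(self):
        # window end = span_end + 50000 = 156000; gene starts exactly there
        hits = [hit("EAL", start=156_000, end=157_500)]
        w = window_signals(hits, self.anchor())
        assert w.eal_present
        # one bp further and it no longer intersects
        hits = [hit("EAL", start=156_001, end=157_500)]
        assert not window_signals(hits, self.anchor()).eal_present

    def test_other_contig_not_counted(self):
        hits = [hit("GGDEF", contig="c9", start=116_000, end=117_000)]
        assert not window_signals(hits, self.anchor()).ggdef_present

    def test_monotone_in_window_size(self):
        hits = [
            hit("GGDEF", start=116_000, end=117_000),
            hit("GGDEF", start=200_000, end=201_000),
            hit("EAL", start=400_000, end=401_000),
        ]
        counts = [
            window_signals(hits, self.anchor(), window_bp=w).ggdef_count
            for w in (1_000, 20_000, 100_000, 500_000)
        ]
        assert counts == sorted(counts)

    def test_non_qualifying_anchor_errors(self):
        a = select_anchor([hit("bcsA", contig="c1"), hit("bcsZ", contig="c2")])
        with pytest.raises(ValueError, match="no qualifying anchor"):
            window_signals([], a)


class TestMedoidSimilarity:
    def test_identical_sequences_similarity_one(self):
        seqs = {"bcsA": {"G1": "MKKLLA" * 10, "G2": "MKKLLA" * 10, "G3": "MKKLLA" * 10}}
        sims = medoid_similarity(seqs)
        assert all(v == 1.0 for v in sims["bcsA"].values())

    def test_medoid_matches_bruteforce(self, rng):
        """Medoid = argmin of summed pairwise 5-mer Jaccard distances."""
        aas = "ACDEFGHIKLMNPQRSTVWY"
        seqs = {
            f"G{i}": "".join(rng.choice(list(aas), size=60)) for i in range(5)
        }
        sims = medoid_similarity({"t": seqs})["t"]

        def kset(s):
            return {s[i : i + 5] for i in range(len(s) - 4)}

        def dist(a, b):
            ka, kb = kset(a), kset(b)
            return 1 - len(ka & kb) / len(ka | kb)

        summed = {
            g: sum(dist(seqs[g], seqs[h]) for h in seqs if h != g) for g in seqs
        }
        medoid = min(sorted(seqs), key=lambda g: summed[g])
        assert sims[medoid] == 1.0
        for g in seqs:
            assert sims[g] == pytest.approx(1 - dist(seqs[g], seqs[medoid]))

    def test_single_carrier_target_skipped(self):
        assert medoid_similarity({"t": {"G1": "MKLV" * 20}}) == {}


def make_anchors(n, qualify_all=True):
    anchors = []
    for i in range(n):
        anchors.append(
            AnchorSelection(
                genome=f"G{i}",
                qualifies=qualify_all or i > 0,
                anchor_contig="c1",
                anchor_span=(100, 1000),
                bcsQ_on_anchor=i % 2 == 0,
                bcsA_copy_count=1 + i % 3,
                bcsA_dispersed=i % 2 == 1,
                targets_on_anchor=("bcsA", "bcsZ") + (("bcsQ",) if i % 2 == 0 else ()),
            )
        )
    return anchors


class TestFeatureMatrixAndPca:
    def test_identical_feature_genomes_get_identical_rows(self):
        a = make_anchors(1)[0]
        anchors = [
            AnchorSelection("G1", True, "c1", (1, 10), True, 2, False, ("bcsA", "bcsZ")),
            AnchorSelection("G2", True, "c1", (1, 10), True, 2, False, ("bcsA", "bcsZ")),
            AnchorSelection("G3", True, "c1", (1, 10), False, 1, True, ("bcsA", "bcsZ")),
        ]
        fm = build_feature_matrix(anchors, {})
        assert (fm.raw.loc["G1"] == fm.raw.loc["G2"]).all()

    def test_constant_columns_dropped_and_recorded(self):
        fm = build_feature_matrix(make_anchors(4), {})
        assert set(fm.dropped_constant) > set()
        assert not set(fm.dropped_constant) & set(fm.scaled.columns)

    def test_scaled_moments(self):
        fm = build_feature_matrix(make_anchors(6), {})
        assert np.allclose(fm.scaled.mean(), 0.0, atol=1e-12)
        assert np.allclose(fm.scaled.std(ddof=1), 1.0, atol=1e-12)

    def test_missing_similarity_imputed_zero(self):
        fm = build_feature_matrix(
            make_anchors(3), {}, {"bcsA": {"G0": 1.0, "G1": 0.9}}
        )
        assert fm.raw.loc["G2", "sim_bcsA"] == 0.0

    def test_fewer_than_two_genomes_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            build_feature_matrix(make_anchors(1), {})

    def test_all_identical_rows_error(self):
        anchors = [
            AnchorSelection(f"G{i}", True, "c1", (1, 10), True, 2, False, ("bcsA", "bcsZ"))
            for i in range(3)
        ]
        fm = build_feature_matrix(anchors, {})
        with pytest.raises(ValueError, match="no variance"):
            pca_project(fm)

    def test_two_distinct_rows_rank_one(self):
        fm = build_feature_matrix(make_anchors(2), {})
        proj = pca_project(fm, 2)
        assert proj.variance_explained[0] == pytest.approx(1.0)

    def test_scores_match_svd_oracle(self, rng):
        """Eigendecomposition PCA agrees with an SVD oracle to 1e-8."""
        sims = {
            t: {f"G{i}": float(rng.uniform(0.3, 1.0)) for i in range(6)}
            for t in ("bcsA", "bcsB", "bcsZ")
        }
        fm = build_feature_matrix(make_anchors(6), {}, sims)
        proj = pca_project(fm, 2)
        x = fm.scaled.to_numpy()
        xc = x - x.mean(axis=0)
        u, sv, vt = np.linalg.svd(xc, full_matrices=False)
        for c in range(2):
            v = vt[c]
            if v[np.argmax(np.abs(v))] < 0:
                v = -v
            assert np.allclose(proj.loadings.iloc[:, c], v, atol=1e-8)
            assert np.allclose(proj.scores.iloc[:, c], x @ v, atol=1e-8)
            ev = sv[c] ** 2 / (x.shape[0] - 1)
            total = (sv**2).sum() / (x.shape[0] - 1)
            assert proj.variance_explained[c] == pytest.approx(ev / total, abs=1e-8)

    def test_row_order_invariance(self):
        anchors = make_anchors(6)
        p1 = pca_project(build_feature_matrix(anchors, {}), 2)
        p2 = pca_project(build_feature_matrix(anchors[::-1], {}), 2)
        s1 = p1.scores.sort_index()
        s2 = p2.scores.sort_index()
        assert np.allclose(s1.to_numpy(), s2.to_numpy(), atol=1e-10)


class TestGffRoundTrip:
    def test_features_from_gff(self, tmp_path, genome_set):
        acc = genome_set.manifest.accessions[0]
        genome_set._write_gff(tmp_path / "g.gff3", acc)
        df = features_from_gff(tmp_path / "g.gff3", acc)
        direct = genome_set.features[genome_set.features["genome"] == acc]
        assert len(df) == len(direct)
        hits_file = {(h.target, h.contig, h.start) for h in find_targets(df)}
        hits_mem = {(h.target, h.contig, h.start) for h in find_targets(direct)}
        assert hits_file == hits_mem
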