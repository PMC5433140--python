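"""Enrichment, distances, ROC, expression patterns and profile correlation."""

import numpy as np
import pytest
from scipy import stats

from chromnmf import (
    ExpressionTable,
    FeatureSet,
    anchor_distance_distribution,
    contingency_enrichment,
    expression_pattern,
    mean_overlap_and_coverage,
    profile_correlation,
    roc_recovery,
)
from test_profiles import track_from_labels


def feature(intervals, name="f", strands=None):
    c, s, e = zip(*intervals)
    return FeatureSet(
        name=name,
        chroms=np.array(c, dtype=object),
        starts=np.array(s, dtype=np.int64),
        ends=np.array(e, dtype=np.int64),
        strands=None if strands is None else np.array(strands, dtype=object),
    )


class TestContingencyEnrichment:
    def test_direct_arithmetic(self):
        # 100 bins of profile 0 (30 overlapping), 1000 other bins (100 overlap)
        labels = [0] * 100 + [1] * 1000
        t = track_from_labels(labels)
        hits = list(range(30)) + list(range(100, 200))
        feat = feature([("c1", i * 200, i * 200 + 200) for i in hits])
        res = contingency_enrichment(t, feat)
        r0 = res[0]
        assert (r0.a, r0.b, r0.c, r0.d) == (30, 70, 100, 900)
        assert r0.ratio == pytest.approx((30 * 900) / (70 * 100))

    def test_whole_genome_feature_inf_sentinel(self):
        t = track_from_labels([0] * 10 + [1] * 10)
        feat = feature([("c1", 0, 4000)])
        res = contingency_enrichment(t, feat)
        assert np.isinf(res[0].ratio)

    def test_empty_feature_nan(self):
        t = track_from_labels([0, 1])
        feat = feature([("c2", 0, 100)])  # different chromosome: no overlap
        res = contingency_enrichment(t, feat)
        assert np.isnan(res[0].ratio)

    def test_fisher_p_matches_hypergeometric_enumeration(self):
        """One-tail Fisher p equals the brute-force hypergeometric tail."""
        rng = np.random.default_rng(0)
        for _ in range(25):
            a, b, c, d = rng.integers(0, 12, size=4)
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
            N, K, n = a + b + c + d, a + c, a + b
            lo, hi = max(0, n + K - N), min(n, K)
            tail = sum(
                stats.hypergeom.pmf(x, N, K, n) for x in range(a, hi + 1)
            )
            assert p == pytest.approx(tail, rel=1e-9, abs=1e-12)

    def test_ratio_matches_independent_recount(self, rng):
        labels = rng.integers(0, 3, 400)
        t = track_from_labels(labels)
        ivs = sorted(rng.choice(400, 50, replace=False))
        feat = feature([("c1", int(i) * 200 + 50, int(i) * 200 + 120) for i in ivs])
        res = contingency_enrichment(t, feat)
        hit = np.zeros(400, dtype=bool)
        hit[list(ivs)] = True
        for r in res:
            u = r.profile
            a = int((hit & (labels == u)).sum())
            b = int((~hit & (labels == u)).sum())
            c = int((hit & (labels != u)).sum())
            d = int((~hit & (labels != u)).sum())
            assert (r.a, r.b, r.c, r.d) == (a, b, c, d)
            if b * c:
                assert r.ratio == pytest.approx(a * d / (b * c))


class TestAnchorDistances:
    def test_plus_strand_distance_sign(self):
        t = track_from_labels([0])
        # bin [0,200), midpoint 100; anchor at 10,000 on + strand
        t.bin_starts[:] = 9900 + 100
        t.bin_ends[:] = t.bin_starts + 200
        anchors = feature([("c1", 10000, 10001)], strands=["+"])
        hists = anchor_distance_distribution(t, anchors, window_bp=1000, hist_bin_bp=200)
        edges, counts = hists[0]
        centers = (edges[:-1] + edges[1:]) / 2
        assert counts.sum() == 1
        assert centers[counts.argmax()] == pytest.approx(100, abs=100)

    def test_bin_on_anchor_zero_distance(self):
        t = track_from_labels([0])
        anchors = feature([("c1", 100, 101)], strands=["+"])
        hists = anchor_distance_distribution(t, anchors, window_bp=1000, hist_bin_bp=200)
        edges, counts = hists[0]
        centers = (edges[:-1] + edges[1:]) / 2
        assert abs(centers[counts.argmax()]) <= 100

    def test_minus_strand_flips_sign(self):
        t = track_from_labels([0])
        t.bin_starts[:] = 10000
        t.bin_ends[:] = 10200  # midpoint 10100, 100 bp right of anchor
        anchors = feature([("c1", 9000, 10000)], strands=["-"])
        hists = anchor_distance_distribution(t, anchors, window_bp=1000, hist_bin_bp=200)
        edges, counts = hists[0]
        centers = (edges[:-1] + edges[1:]) / 2
        assert centers[counts.argmax()] < 0  # right of a minus anchor = upstream

    def test_total_mass_equals_assigned_bins_in_window(self, rng):
        labels = rng.integers(0, 2, 50)
        t = track_from_labels(labels)
        anchors = feature([("c1", 5000, 5001)])
        hists = anchor_distance_distribution(t, anchors, window_bp=20000, hist_bin_bp=200)
        total = sum(h[1].sum() for h in hists.values())
        assert total == 50


class TestRocRecovery:
    def test_perfect_separation_auc_one(self):
        scores = np.array([5.0, 4.0, 1.0, 0.5])
        pos = np.array([True, True, False, False])
        *_, auc = roc_recovery(scores, pos)
        assert auc == 1.0

    def test_hand_enumerated_staircase(self):
        scores = np.array([4.0, 3.0, 2.0, 1.0])
        pos = np.array([True, True, False, False])
        fpr, tpr, thr, auc = roc_recovery(scores, pos)
        assert auc == 1.0
        assert np.allclose(tpr[:3], [0, 0.5, 1.0])
        assert np.allclose(fpr[:3], [0, 0, 0])

    def test_permuted_scores_auc_half(self, rng):
        scores = rng.random(4000)
        pos = rng.random(4000) < 0.3
        *_, auc = roc_recovery(scores, pos)
        assert abs(auc - 0.5) < 0.05

    def test_auc_equals_mann_whitney(self, rng):
        for _ in range(5):
            scores = rng.normal(size=300) + np.repeat([0.0, 0.7], [200, 100])
            pos = np.repeat([False, True], [200, 100])
            *_, auc = roc_recovery(scores, pos)
            u = stats.mannwhitneyu(scores[pos], scores[~pos], alternative="two-sided")
            assert auc == pytest.approx(u.statistic / (200 * 100), abs=1e-9)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_recovery(np.ones(5), np.ones(5, dtype=bool))


class TestExpressionPattern:
    def build_track_and_genes(self, rng, n_bins=6000, n_genes=400):
        labels = rng.integers(0, 3, n_bins)
        track = track_from_labels(labels)
        # plant profile 0 at the TSS of high-expression genes
        rho = rng.uniform(0, 1, n_genes)
        p0_bins = np.where(labels == 0)[0]
        other = np.where(labels != 0)[0]
        on0 = rng.random(n_genes) < (0.1 + 0.8 * rho)
        gbin = np.where(on0, rng.choice(p0_bins, n_genes), rng.choice(other, n_genes))
        expr = ExpressionTable(
            gene_ids=np.array([f"g{i}" for i in range(n_genes)], dtype=object),
            chroms=np.full(n_genes, "c1", dtype=object),
            tss=gbin * 200 + 100,
            strands=np.array(rng.choice(["+", "-"], n_genes), dtype=object),
            rpkm=np.exp(2 * rho),
        )
        return track, expr

    def test_planted_monotone_trend_recovered(self, rng):
        track, expr = self.build_track_and_genes(rng)
        res = expression_pattern(track, expr, window=(-200, 200), percentile_step=10,
                                 n_permutations=5, seed=0)
        pos0 = np.where(res.positions == 0)[0][0]
        freq = res.observed[0][:, pos0]
        rho = stats.spearmanr(np.arange(len(freq)), freq).statistic
        assert rho > 0.8
        # logFC positive in the top stratum at the TSS
        assert res.logfc[0][-1, pos0] > 0

    def test_uniform_track_near_zero_logfc(self, rng):
        labels = rng.integers(0, 3, 6000)
        track = track_from_labels(labels)
        genes = rng.choice(6000, 300, replace=False)
        expr = ExpressionTable(
            gene_ids=np.array([f"g{i}" for i in range(300)], dtype=object),
            chroms=np.full(300, "c1", dtype=object),
            tss=genes * 200 + 100,
            strands=np.full(300, "+", dtype=object),
            rpkm=rng.lognormal(1, 1, 300),
        )
        res = expression_pattern(track, expr, window=(-400, 400), percentile_step=25,
                                 n_permutations=20, seed=1)
        vals = np.concatenate([v[np.isfinite(v)] for v in res.logfc.values()])
        assert abs(vals.mean()) < 0.1

    def test_identical_rpkm_single_stratum(self, rng):
        track = track_from_labels(rng.integers(0, 2, 1000))
        expr = ExpressionTable(
            gene_ids=np.array(["a", "b", "c"], dtype=object),
            chroms=np.full(3, "c1", dtype=object),
            tss=np.array([1000, 5000, 9000]),
            strands=np.full(3, "+", dtype=object),
            rpkm=np.array([2.0, 2.0, 2.0]),
        )
        res = expression_pattern(track, expr, window=(-200, 200), n_permutations=2, seed=0)
        assert res.observed[0].shape[0] == 1


class TestOverlapCoverage:
    def test_perfect_profile(self):
        t = track_from_labels([0] * 10 + [1] * 10)
        feat = feature([("c1", i * 200, i * 200 + 200) for i in range(10)])
        ov, cov = mean_overlap_and_coverage(t, feat, [0])
        assert ov == 100.0 and cov == 100.0

    def test_disjoint_profile(self):
        t = track_from_labels([0] * 10 + [1] * 10)
        feat = feature([("c1", i * 200, i * 200 + 200) for i in range(10)])
        ov, cov = mean_overlap_and_coverage(t, feat, [1])
        assert ov == 0.0 and cov == 0.0

    def test_mean_over_profiles(self):
        labels = [0] * 10 + [1] * 10
        t = track_from_labels(labels)
        # profile 0: 2/10 bins overlap; profile 1: 4/10
        hits = [0, 1, 10, 11, 12, 13]
        feat = feature([("c1", i * 200, i * 200 + 200) for i in hits])
        ov, _ = mean_overlap_and_coverage(t, feat, [0, 1])
        assert ov == pytest.approx(100 * (0.2 + 0.4) / 2)

    def test_empty_set_rejected(self):
        t = track_from_labels([0, 1])
        feat = feature([("c1", 0, 100)])
        with pytest.raises(ValueError):
            mean_overlap_and_coverage(t, feat, [])


class TestProfileCorrelation:
    def test_self_correlation_diagonal_one(self, rng):
        H = rng.random((4, 13))
        corr, pairs = profile_correlation(H, H)
        assert np.allclose(np.diag(corr), 1.0)
        assert all(i == j and r == pytest.approx(1.0) for i, j, r in pairs)

    def test_scale_invariance(self, rng):
        H = rng.random((3, 10))
        corr, pairs = profile_correlation(H, 2.0 * H)
        assert all(r == pytest.approx(1.0) for _, _, r in pairs)

    def test_one_hot_profiles_nonpositive_off_diagonal(self):
        H = np.eye(4)
        corr, _ = profile_correlation(H, H)
        off = corr[~np.eye(4, dtype=bool)]
        assert np.all(off <= 0)

    def test_zero_variance_profile_nan(self, rng):
        A = rng.random((2, 6))
        B = np.vstack([np.ones(6), rng.random(6)])
        corr, _ = profile_correlation(A, B)
        assert np.isnan(corr[:, 0]).all()
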