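"""Insulation scoring, boundary calling, and cross-sample statistics."""

import numpy as np
import pytest

from capchic import (
    BinTable,
    Boundary,
    BoundarySet,
    GenomicInterval,
    boundary_candidates,
    call_robust_boundaries,
    compare_boundary_sets,
    insulation_ks,
    insulation_pca,
    insulation_profile,
    insulation_spearman,
)
from capchic.insulation import InsulationProfile, _plateau_minima
from conftest import as_balanced, random_symmetric_matrix


def brute_force_insulation(m, w, max_missing=0.5):
    """Direct diamond-window summation, independent of the implementation."""
    n = m.shape[0]
    raw = np.full(n, np.nan)
    for i in range(w, n - w):
        cells = [m[a, b] for a in range(i - w, i) for b in range(i + 1, i + w + 1)]
        cells = np.array(cells)
        if np.isnan(cells).sum() > max_missing * cells.size:
            continue
        raw[i] = np.nanmean(cells)
    score = np.log2(raw / np.nanmean(raw))
    return raw, score


def profile_from_scores(scores, resolution=5_000):
    n = len(scores)
    bt = BinTable(resolution, [GenomicInterval("chrT", 0, n * resolution)])
    return InsulationProfile(bt, 2, [np.asarray(scores, dtype=float)], [np.asarray(scores, dtype=float)])


class TestInsulationProfile:
    def test_uniform_matrix_scores_zero(self):
        prof = insulation_profile(as_balanced(np.full((12, 12), 2.0)), 2)
        inner = prof.scores[0][2:-2]
        np.testing.assert_allclose(inner, 0.0, atol=1e-12)

    def test_edge_bins_missing(self):
        prof = insulation_profile(as_balanced(np.full((10, 10), 1.0)), 3)
        s = prof.scores[0]
        assert np.isnan(s[:3]).all() and np.isnan(s[-3:]).all()
        assert np.isfinite(s[3:-3]).all()

    @pytest.mark.parametrize("w", [1, 2, 3])
    def test_matches_brute_force(self, w, rng):
        m = random_symmetric_matrix(12, rng)
        prof = insulation_profile(as_balanced(m), w)
        raw_bf, score_bf = brute_force_insulation(m, w)
        np.testing.assert_allclose(prof.raw[0], raw_bf, atol=1e-13, equal_nan=True)
        np.testing.assert_allclose(prof.scores[0], score_bf, atol=1e-13, equal_nan=True)

    def test_window_too_large_raises(self):
        with pytest.raises(ValueError, match="window"):
            insulation_profile(as_balanced(np.ones((4, 4))), 4)

    def test_missing_fraction_rule(self):
        m = np.full((12, 12), 1.0)
        m[4, :] = np.nan
        m[:, 4] = np.nan
        bal = as_balanced(m)
        bal.valid[0][4] = False
        prof = insulation_profile(bal, 2, max_missing_fraction=0.2)
        # bins 5 and 3 have half their window rows missing (2/4 cells) > 0.2
        assert np.isnan(prof.scores[0][3]) and np.isnan(prof.scores[0][5])
        prof2 = insulation_profile(bal, 2, max_missing_fraction=0.5)
        assert np.isfinite(prof2.scores[0][3]) and np.isfinite(prof2.scores[0][5])


class TestBoundaryCandidates:
    def test_monotone_profile_no_candidates(self):
        prof = profile_from_scores(np.linspace(0, 1, 10))
        assert boundary_candidates(prof) == []

    def test_single_dip_scores_one(self):
        prof = profile_from_scores([0, 0, 0, -1, 0, 0, 0])
        cands = boundary_candidates(prof)
        assert len(cands) == 1
        bin_idx, score = cands[0]
        assert bin_idx == 3
        assert score == pytest.approx(1.0)

    def test_plateau_leftmost(self):
        assert _plateau_minima(np.array([0.0, -1, -1, 0])) == [1]

    def test_plateau_candidate_requires_flanks(self):
        prof = profile_from_scores([0, 0, 0, -1, -1, 0, 0, 0])
        cands = boundary_candidates(prof)
        assert [b for b, _ in cands] == [3]

    def test_min_flank_rule_two_sided(self):
        # asymmetric dip: left flank mean 0, right flank mean 0.6
        prof = profile_from_scores([0, 0, 0, -1, 0.6, 0.6, 0.6])
        (bin_idx, score), = boundary_candidates(prof)
        assert score == pytest.approx(1.0)  # min of the two flank means - (-1)

    def test_missing_flank_skipped(self):
        scores = [0, 0, 0, -1, 0, np.nan, 0]
        prof = profile_from_scores(scores)
        assert boundary_candidates(prof) == []


class TestRobustBoundaries:
    BT = BinTable(5_000, [GenomicInterval("chrT", 0, 600_000)])

    def test_single_window_support_dropped(self):
        cands = {3: [(40, 0.5)], 5: [], 7: []}
        bset = call_robust_boundaries(cands, self.BT)
        assert len(bset) == 0

    def test_merge_adjacent_and_average(self):
        cands = {3: [(40, 0.2)], 5: [(41, 0.4)]}
        bset = call_robust_boundaries(cands, self.BT)
        assert len(bset) == 1
        b = bset.boundaries[0]
        assert b.score == pytest.approx(0.3)
        assert (b.interval.start, b.interval.end) == (40 * 5_000, 42 * 5_000)
        assert b.supporting_windows == {3, 5}

    def test_below_threshold_excluded_from_mean(self):
        cands = {3: [(40, 0.05)], 5: [(40, 0.4)], 7: [(41, 0.2)]}
        bset = call_robust_boundaries(cands, self.BT)
        assert bset.boundaries[0].score == pytest.approx(0.3)

    def test_empty_candidates(self):
        assert len(call_robust_boundaries({}, self.BT)) == 0

    def test_merge_gap_controls_clustering(self):
        cands = {3: [(40, 0.2), (42, 0.2)], 5: [(40, 0.2), (42, 0.2)]}
        # bins 2 apart stay separate at gap 1, merge at gap 2
        assert len(call_robust_boundaries(cands, self.BT, merge_gap_bins=1)) == 2
        assert len(call_robust_boundaries(cands, self.BT, merge_gap_bins=2)) == 1

    def test_planted_borders_recovered_noise_free(self):
        from capchic import kr_balance
        from capchic.simulate import boundary_study_config, expected_matrix

        cfg = boundary_study_config(seed=0)
        expected, truth = expected_matrix(cfg)
        bal = kr_balance(expected, min_coverage_fraction=0)
        cands = {
            w: boundary_candidates(insulation_profile(bal, w))
            for w in (3, 5, 7, 10, 15)
        }
        bset = call_robust_boundaries(cands, bal.bin_table)
        assert len(bset) == 3
        res = cfg.resolution
        for called, true_bin in zip(bset.boundaries, truth.boundary_bins[0]):
            called_bins = range(called.interval.start // res, called.interval.end // res)
            assert any(abs(cb - true_bin) <= 1 for cb in called_bins)


def _bset(intervals, cell_type="x"):
    return BoundarySet(
        cell_type, [Boundary(GenomicInterval(*iv), 0.5) for iv in intervals], 5_000
    )


class TestCompareBoundarySets:
    def test_identical_sets(self):
        a = _bset([("c", 10, 20), ("c", 50, 60)])
        assert compare_boundary_sets(a, a)["jaccard"] == 1.0

    def test_disjoint_sets(self):
        a = _bset([("c", 10, 20)])
        b = _bset([("c", 50, 60)])
        assert compare_boundary_sets(a, b)["jaccard"] == 0.0

    def test_partial_overlap_third(self):
        a = _bset([("c", 10, 20), ("c", 50, 60)])
        b = _bset([("c", 50, 60), ("c", 90, 100)])
        result = compare_boundary_sets(a, b)
        assert result["jaccard"] == pytest.approx(1 / 3)
        assert result["n_matched"] == 1
        assert result["n_a_only"] == 1 and result["n_b_only"] == 1

    def test_symmetry(self, rng):
        a = _bset([("c", int(s), int(s) + 10) for s in rng.integers(0, 500, 5) * 10])
        b = _bset([("c", int(s), int(s) + 10) for s in rng.integers(0, 500, 4) * 10])
        ra = compare_boundary_sets(a, b)
        rb = compare_boundary_sets(b, a)
        assert ra["jaccard"] == rb["jaccard"]
        assert 0.0 <= ra["jaccard"] <= 1.0

    def test_slack_extension_matches_near_miss(self):
        a = _bset([("c", 10_000, 15_000)])
        b = _bset([("c", 20_000, 25_000)])
        assert compare_boundary_sets(a, b, slack_bins=0)["jaccard"] == 0.0
        assert compare_boundary_sets(a, b, slack_bins=1)["jaccard"] == 1.0

    def test_no_double_counting(self):
        # one wide boundary in a overlapping two in b counts once
        a = _bset([("c", 10, 100)])
        b = _bset([("c", 20, 30), ("c", 60, 70)])
        result = compare_boundary_sets(a, b)
        assert result["n_matched"] == 1
        assert result["jaccard"] == pytest.approx(1 / 2)


class TestKS:
    def test_identical_samples(self):
        r = insulation_ks([1, 2, 3, 4], [1, 2, 3, 4])
        assert r["D"] == 0.0
        assert r["p"] == pytest.approx(1.0)

    def test_disjoint_supports(self):
        assert insulation_ks([0, 1, 2], [10, 11, 12])["D"] == 1.0

    def test_matches_ecdf_oracle(self):
        a = [0.1, 0.5, 0.9, 1.2, 1.5, 2.0, 2.2, 3.0]
        b = [0.3, 0.7, 1.0, 1.1, 1.9, 2.5, 2.8, 3.5]
        grid = np.sort(np.concatenate([a, b]))
        ecdf_a = np.searchsorted(np.sort(a), grid, side="right") / len(a)
        ecdf_b = np.searchsorted(np.sort(b), grid, side="right") / len(b)
        d_oracle = np.abs(ecdf_a - ecdf_b).max()
        assert insulation_ks(a, b)["D"] == pytest.approx(d_oracle)

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            insulation_ks([], [1, 2, 3])

    def test_nan_dropped(self):
        r = insulation_ks([1, 2, 3, np.nan], [1, 2, 3])
        assert r["D"] == 0.0


class TestSpearman:
    def test_identity(self):
        assert insulation_spearman([1, 2, 3, 4], [1, 2, 3, 4])["rho"] == 1.0

    def test_hand_computed(self):
        # d = (2, -1, -1), sum d^2 = 6 -> rho = 1 - 6*6 / (3*8) = -0.5
        assert insulation_spearman([1, 2, 3], [3, 1, 2])["rho"] == pytest.approx(-0.5)

    def test_reversal(self):
        assert insulation_spearman([1, 2, 3], [3, 2, 1])["rho"] == -1.0

    def test_constant_flagged(self):
        r = insulation_spearman([1, 1, 1], [1, 2, 3])
        assert r["constant"] and np.isnan(r["rho"])

    def test_too_few_pairs_raises(self):
        with pytest.raises(ValueError):
            insulation_spearman([1, np.nan, 3], [1, 2, 3])


class TestPCA:
    def test_identical_replicates_coincide(self):
        X = np.array([[1.0, 2, 3, 4], [1, 2, 3, 4], [5, 5, 5, 5]])
        coords = insulation_pca(X)["coordinates"]
        np.testing.assert_allclose(coords[0], coords[1], atol=1e-12)

    def test_rank_one_variation(self):
        base = np.array([1.0, 2, 3, 4, 5, 6])
        X = np.stack([base, base + 1, base + 2, base - 1])
        r = insulation_pca(X)
        assert r["variance_fractions"][0] == pytest.approx(1.0)

    def test_matches_eigendecomposition_oracle(self, rng):
        X = rng.normal(size=(4, 6))
        r = insulation_pca(X)
        Xc = X - X.mean(axis=0)
        evals, evecs = np.linalg.eigh(Xc.T @ Xc)
        order = np.argsort(evals)[::-1]
        for k in range(2):
            oracle = Xc @ evecs[:, order[k]]
            got = r["coordinates"][:, k]
            assert np.allclose(got, oracle, atol=1e-9) or np.allclose(
                got, -oracle, atol=1e-9
            )

    def test_replicate_order_invariance_up_to_sign(self, rng):
        X = rng.normal(size=(5, 8))
        perm = [3, 1, 4, 0, 2]
        a = insulation_pca(X)["coordinates"]
        b = insulation_pca(X[perm])["coordinates"]
        for k in range(2):
            assert np.allclose(a[perm, k], b[:, k], atol=1e-9) or np.allclose(
                a[perm, k], -b[:, k], atol=1e-9
            )

    def test_missing_bins_dropped_listwise(self):
        X = np.array([[1.0, np.nan, 3, 4], [2, 5, 3, 4], [0, 1, 3, 4]])
        assert insulation_pca(X)["n_bins"] == 3

    def test_too_few_replicates_raises(self):
        with pytest.raises(ValueError):
            insulation_pca(np.ones((2, 5)))
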