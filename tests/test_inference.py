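"""Rank-shuffling null, p-values, the doubling correction, and the J heuristic."""

import numpy as np
import pytest

from peakclust import (FixtureSpec, HeuristicCurve, NullDistribution, PeakList,
                       ScanResult, ScanRow, build_null, corrected_alpha,
                       fit_ellipsoid, heuristic_J, make_fixture,
                       min_radii_by_subgroup, p_value, permute_ranks, scan_m,
                       select_reported, smallest_clusters, top_m)


class TestPermuteRanks:
    def test_single_peak_list_unchanged(self, rng):
        pl = PeakList("a", [[1.0, 2.0, 3.0]], [4.0])
        out = permute_ranks([pl], rng)[0]
        assert list(out.ranks) == [1]
        np.testing.assert_allclose(out.locations_mm, pl.locations_mm)

    def test_locations_and_pairing_never_move(self, rng, planted_peaklists):
        out = permute_ranks(planted_peaklists, rng)
        for a, b in zip(planted_peaklists, out):
            np.testing.assert_allclose(a.locations_mm, b.locations_mm)
            np.testing.assert_allclose(a.values, b.values)
            assert sorted(b.ranks) == list(range(1, len(b) + 1))

    def test_top_m_after_shuffle_is_uniform_subset(self, rng):
        # each of P peaks should reach the top m with frequency ~ m/P
        P, m, reps = 8, 3, 4000
        pl = PeakList("a", np.arange(P * 3, dtype=float).reshape(P, 3),
                      np.arange(P, 0, -1, dtype=float))
        counts = np.zeros(P)
        for _ in range(reps):
            shuffled = permute_ranks([pl], rng)[0]
            chosen = top_m(shuffled, m).locations_mm[:, 0]
            counts[(chosen / 3).astype(int)] += 1
        freq = counts / reps
        expect = m / P
        sd = np.sqrt(expect * (1 - expect) / reps)
        assert np.all(np.abs(freq - expect) < 5 * sd)


class TestPValue:
    def make_null(self, radii, n=8, K=None):
        radii = np.asarray(radii, dtype=float)
        return NullDistribution(m=5, k_permutations=K or radii.size,
                                radii={n: radii})

    def test_smaller_than_all_nulls_gives_add_one_minimum(self):
        null = self.make_null(np.linspace(10, 60, 500))
        assert p_value(5.0, null, 8) == pytest.approx(1 / 501)

    def test_larger_than_all_nulls_gives_one(self):
        null = self.make_null(np.linspace(10, 60, 500))
        assert p_value(100.0, null, 8) == 1.0

    def test_counting_matches_direct_oracle(self, rng):
        radii = rng.gamma(5.0, 4.0, size=500)
        null = self.make_null(radii)
        obs = float(np.percentile(radii, 5))
        expect = (1 + int(np.sum(radii <= obs))) / 501
        assert p_value(obs, null, 8) == pytest.approx(expect)
        assert expect == pytest.approx(0.05, abs=0.01)

    def test_monotone_in_observed_radius(self, rng):
        null = self.make_null(rng.gamma(5.0, 4.0, size=300))
        ps = [p_value(r, null, 8) for r in np.linspace(0, 80, 40)]
        assert all(a <= b for a, b in zip(ps, ps[1:]))

    def test_unachieved_permutations_count_as_larger(self):
        # only 100 of 500 permutations achieved this subgroup size
        null = self.make_null(np.full(100, 5.0), K=500)
        assert p_value(10.0, null, 8) == pytest.approx(101 / 501)

    def test_missing_subgroup_raises(self):
        null = self.make_null([1.0, 2.0])
        with pytest.raises(KeyError):
            p_value(3.0, null, 5)

    def test_accepts_ellipsoid(self):
        e = fit_ellipsoid([("a", [0, 0, 0]), ("b", [2, 0, 0]), ("c", [0, 2, 0])])
        null = self.make_null(np.linspace(10, 60, 99), n=3)
        assert p_value(e, null) == pytest.approx(1 / 100)


class TestCorrectedAlpha:
    def test_printed_value_for_m_2_to_40(self):
        assert corrected_alpha(0.05, 2, 40) == pytest.approx(0.0094, abs=5e-5)

    def test_single_m_no_correction(self):
        assert corrected_alpha(0.05, 2, 2) == 0.05

    def test_m_2_to_30(self):
        assert corrected_alpha(0.05, 2, 30) == pytest.approx(
            0.05 / (1 + np.log2(15)), rel=1e-12)

    @pytest.mark.parametrize("c", [2, 3, 7])
    def test_invariant_under_range_scaling(self, c):
        assert corrected_alpha(0.05, 2, 40) == pytest.approx(
            corrected_alpha(0.05, 2 * c, 40 * c), rel=1e-12)

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            corrected_alpha(0.05, 0, 10)
        with pytest.raises(ValueError):
            corrected_alpha(0.05, 10, 2)


class TestBuildNull:
    def test_series_bounded_by_k_and_nonnegative(self, planted_peaklists):
        null = build_null(planted_peaklists, m=3, n_min=5, k_permutations=40,
                          seed=0, restarts=2)
        assert null.radii
        for radii in null.radii.values():
            assert radii.size <= 40
            assert np.all(radii >= 0)

    def test_fast_path_matches_public_permutation_route(self, planted_peaklists):
        # same chance process via permute_ranks -> top_m -> engine
        K = 120
        rng = np.random.default_rng(77)
        slow = []
        for _ in range(K):
            perm = permute_ranks(planted_peaklists, rng)
            best = min_radii_by_subgroup([top_m(pl, 3) for pl in perm], 3, 8,
                                         restarts=2, seed=rng)
            if 8 in best:
                slow.append(best[8])
        fast = build_null(planted_peaklists, 3, 8, K, seed=13, restarts=2)
        a, b = np.asarray(slow), fast.radii[8]
        # identical chance distribution: compare medians within MC error
        assert abs(np.median(a) - np.median(b)) < 0.25 * np.std(a)


def test_scan_m_detects_planted_cluster(planted_peaklists):
    scan = scan_m(planted_peaklists, m_start=2, m_end=4, n_min=8,
                  k_permutations=99, seed=1, restarts=3)
    assert scan.threshold == pytest.approx(0.05 / 2.0)
    sig = scan.significant_rows()
    assert sig, "tight planted cluster should be significant"
    for row in sig:
        assert row.p_raw < scan.threshold
        assert row.p_corrected >= row.p_raw
        # the planted centre is at (52, -29, 13)
        assert np.linalg.norm(row.ellipsoid.center_mm - [52, -29, 13]) < 15


def test_power_exceeds_false_positive_rate_with_partial_participation():
    # planted cluster (jitter 5 mm) in 8 of 10 participants: detection
    # probability at alpha=0.05 must clearly exceed the nominal rate
    detections = 0
    reps = 25
    for rep in range(reps):
        pls = make_fixture(FixtureSpec(n_participants=10,
                                       peaks_per_participant=15,
                                       jitter_sd_mm=5.0, participation=0.8,
                                       seed=300 + rep))
        rng = np.random.default_rng(900 + rep)
        cs = smallest_clusters(pls, m=3, n_min=8, iterations=15, restarts=2,
                               seed=rng)
        null = build_null(pls, 3, 8, k_permutations=100, seed=rng,
                          iterations=15, restarts=2)
        if any(n in null.radii and p_value(cs[n], null) < 0.05
               for n in cs.subgroup_sizes()):
            detections += 1
    assert detections / reps > 0.5  # far above the 0.05 false-positive rate


def test_select_reported_prefers_largest_n_then_smallest_radius():
    def row(m, n, center, radius, p=0.001):
        e = fit_ellipsoid([(str(i), np.asarray(center) + [0.01 * i, 0, 0])
                           for i in range(n)])
        e.radii_mm = np.array([radius, 0.0, 0.0])
        return ScanRow(m, n, e, 1.0, p, p * 2, True)

    rows = [row(2, 5, [0, 0, 0], 12.0), row(3, 7, [2, 0, 0], 20.0),
            row(4, 7, [1, 1, 0], 9.0), row(5, 6, [100, 100, 100], 4.0)]
    scan = ScanResult(rows, (2, 5))
    rep = select_reported(scan, link_mm=15.0)
    assert len(rep) == 2
    near = [r for r in rep if np.linalg.norm(r.ellipsoid.center_mm) < 50][0]
    assert near.n_participants == 7
    assert near.ellipsoid.major_radius_mm == pytest.approx(9.0)


class TestHeuristicJ:
    def test_zero_radius_curve_minimised_at_m_start(self):
        ms = np.arange(2, 31)
        curve = HeuristicCurve(ms, {5: np.zeros(ms.size)})
        out = heuristic_J(curve)
        np.testing.assert_allclose(out[5]["J"], ms)
        assert out[5]["m_opt"] == 2

    def test_interior_minimum_at_synthetic_knee(self):
        # R(M) = 200/M gives J = sqrt(M^2 + (200/M)^2), minimal at sqrt(200)
        ms = np.arange(2, 31)
        curve = HeuristicCurve(ms, {7: 200.0 / ms})
        expect = ms[np.argmin(np.sqrt(ms ** 2 + (200.0 / ms) ** 2))]
        out = heuristic_J(curve)
        assert out[7]["m_opt"] == expect == 14

    def test_strictly_increasing_where_r_constant(self):
        ms = np.arange(2, 21)
        curve = HeuristicCurve(ms, {5: np.full(ms.size, 30.0)})
        j = heuristic_J(curve)[5]["J"]
        assert np.all(np.diff(j) > 0)

    def test_axis_scaling_changes_optimum(self):
        ms = np.arange(2, 31)
        curve = HeuristicCurve(ms, {5: 200.0 / ms})
        default = heuristic_J(curve)[5]["m_opt"]
        heavy_m = heuristic_J(curve, m_scale=4.0)[5]["m_opt"]
        assert heavy_m <= default
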