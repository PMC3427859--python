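"""Permutation null, FDR surface fit, extrapolation and replicate consensus."""

import math

import numpy as np
import pandas as pd
import pytest

from damidephys.core import Peak, RatioTrack
from damidephys.fdr_model import (FDRModel, assign_fdr, build_null_grid,
                                  consensus_across_replicates, count_runs_grid,
                                  fdr_table, fit_exponential_decay, randomize_arm)
from oracles import expected_run_count_dp


def track(values, rep="rep1", arm="2L"):
    return RatioTrack(rep, arm, np.asarray(values, float))


class TestRandomize:
    def test_single_probe_unchanged(self):
        out = randomize_arm(track([3.7]), 0)
        assert out.values.tolist() == [3.7]

    def test_multiset_conserved(self):
        rng = np.random.default_rng(5)
        values = rng.normal(size=500)
        out = randomize_arm(track(values), 1)
        np.testing.assert_array_equal(np.sort(out.values), np.sort(values))

    def test_positions_visited_uniformly(self):
        """Over many permutations each value reaches each position with
        frequency ~ 1/n (chi-square style bound on the max deviation)."""
        n, n_perm = 10, 4000
        values = np.arange(n, dtype=float)
        counts = np.zeros((n, n))  # value index x position
        rng = np.random.default_rng(17)
        for _ in range(n_perm):
            out = randomize_arm(track(values), rng)
            for pos, val in enumerate(out.values):
                counts[int(val), pos] += 1
        freq = counts / n_perm
        se = math.sqrt((1 / n) * (1 - 1 / n) / n_perm)
        assert np.abs(freq - 1 / n).max() < 5 * se


class TestNullGrid:
    def test_sub_threshold_track_gives_zero_null(self):
        grid = build_null_grid(track(np.full(100, 0.05)),
                               heights=np.array([0.1, 0.5]),
                               widths=np.array([2, 4]), iterations=5, seed=0)
        assert not grid.mean_null_count.any()
        assert not grid.observed_count.any()

    def test_grid_monotone_non_increasing_in_height_and_width(self):
        rng = np.random.default_rng(3)
        grid = build_null_grid(track(rng.normal(0.5, 0.5, size=400)),
                               heights=np.array([0.2, 0.5, 0.8]),
                               widths=np.array([2, 4, 6]), iterations=10, seed=1)
        for mat in (grid.mean_null_count, grid.observed_count):
            assert np.all(np.diff(mat, axis=0) <= 0)
            assert np.all(np.diff(mat, axis=1) <= 0)

    def test_mean_null_counts_match_dp_expectation(self):
        """On i.i.d. tracks a permutation draw is again i.i.d., so mean null
        run counts must agree with the exact DP expectation within
        Monte-Carlo error (3 SE over many tracks x 20 iterations)."""
        n, n_tracks = 30, 300
        heights = np.array([0.2, 0.8])
        widths = np.array([2, 3])
        rng = np.random.default_rng(29)
        per_track = np.empty((n_tracks, len(heights), len(widths)))
        for t in range(n_tracks):
            g = build_null_grid(track(rng.normal(size=n)), heights, widths,
                                iterations=20, seed=int(rng.integers(2 ** 31)))
            per_track[t] = g.mean_null_count
        mc_mean = per_track.mean(axis=0)
        mc_se = per_track.std(axis=0, ddof=1) / math.sqrt(n_tracks)
        from scipy.stats import norm
        for i, h in enumerate(heights):
            for j, w in enumerate(widths):
                exact = expected_run_count_dp(n, float(norm.sf(h)), int(w))
                assert abs(mc_mean[i, j] - exact) < 3 * mc_se[i, j]

    def test_count_grid_agrees_with_observed_peaks(self):
        v = np.zeros(50)
        v[5:15] = 1.5   # one 10-run
        v[30:36] = 0.6  # one 6-run at lower height
        counts = count_runs_grid(v, np.array([0.5, 1.0]), np.array([6, 8, 12]))
        np.testing.assert_array_equal(counts, [[2, 1, 0], [1, 1, 0]])


class TestFdrTable:
    def test_ratio_cap_and_usability(self):
        from damidephys.fdr_model import NullPeakGrid
        grid = NullPeakGrid(arm_id="2L", replicate_id="r1",
                            heights=np.array([0.1, 0.2]), widths=np.array([6]),
                            iterations=20,
                            mean_null_count=np.array([[2.0], [5.0]]),
                            observed_count=np.array([[100], [3]]))
        table = fdr_table(grid)
        assert table.loc[0, "fdr"] == pytest.approx(0.02)
        assert table.loc[1, "fdr"] == 1.0  # capped
        assert table["usable"].all()

    def test_zero_observed_and_zero_null_marked_unusable(self):
        from damidephys.fdr_model import NullPeakGrid
        grid = NullPeakGrid(arm_id="2L", replicate_id="r1",
                            heights=np.array([0.1]), widths=np.array([6, 8]),
                            iterations=20,
                            mean_null_count=np.array([[0.0, 2.0]]),
                            observed_count=np.array([[10, 0]]))
        table = fdr_table(grid)
        assert not table["usable"].any()
        assert np.isnan(table.loc[1, "fdr"])

    def test_pure_null_track_has_fdr_near_one(self):
        """When the observed track is itself exchangeable noise, observed
        and null counts estimate the same quantity: FDR ~ 1."""
        rng = np.random.default_rng(77)
        fdrs = []
        for _ in range(20):
            g = build_null_grid(track(rng.normal(size=3000)),
                                heights=np.array([0.3]), widths=np.array([3]),
                                iterations=20, seed=int(rng.integers(2 ** 31)))
            fdrs.append(fdr_table(g)["fdr"].iloc[0])
        assert np.mean(fdrs) == pytest.approx(1.0, abs=0.1)


class TestExponentialDecayFit:
    @staticmethod
    def synthetic_table(a, b, c, noise_frac=0.0, rng=None):
        rows = []
        for h in np.arange(0.1, 1.25 + 1e-9, 0.05):
            for w in range(6, 16):
                fdr = math.exp(a + b * h + c * w)
                if noise_frac and rng is not None:
                    fdr *= math.exp(rng.normal(0.0, noise_frac))
                rows.append({"height": h, "width": w, "fdr": fdr,
                             "observed_count": 10, "mean_null_count": fdr * 10,
                             "usable": True})
        return pd.DataFrame(rows)

    def test_exact_recovery_noise_free(self):
        table = self.synthetic_table(1.0, -3.0, -0.2)
        m = fit_exponential_decay(table)
        assert (m.a, m.b, m.c) == (pytest.approx(1.0, abs=1e-6),
                                   pytest.approx(-3.0, abs=1e-6),
                                   pytest.approx(-0.2, abs=1e-6))
        assert m.resid_rms < 1e-9

    def test_recovery_under_multiplicative_noise(self):
        rng = np.random.default_rng(10)
        errs = []
        for _ in range(100):
            table = self.synthetic_table(1.0, -3.0, -0.2, noise_frac=0.05, rng=rng)
            m = fit_exponential_decay(table)
            errs.append(max(abs(m.a - 1.0) / 1.0, abs(m.b + 3.0) / 3.0,
                            abs(m.c + 0.2) / 0.2))
            assert m.b < 0 and m.c < 0
        assert np.mean(errs) < 0.05

    def test_too_few_usable_cells_raises(self):
        table = self.synthetic_table(1.0, -3.0, -0.2).iloc[:5]
        with pytest.raises(ValueError, match="denser grid|degenerate"):
            fit_exponential_decay(table)


class TestAssignFdr:
    def model(self, a=0.0, b=-2.0, c=-0.1):
        return FDRModel("2L", "r1", a, b, c, n_cells=240, resid_rms=0.0)

    def peak(self, h, w):
        return Peak("2L", "r1", 0, w - 1, 0, w * 55, height_log2=h)

    def test_plug_in_arithmetic(self):
        p = assign_fdr(self.peak(1.0, 10), self.model())
        assert p.fdr == pytest.approx(math.exp(-3.0))

    def test_huge_peak_fdr_tends_to_zero_never_negative(self):
        p = assign_fdr(self.peak(50.0, 500), self.model())
        assert 0.0 <= p.fdr < 1e-30

    def test_cap_at_one(self):
        p = assign_fdr(self.peak(0.01, 1), self.model(a=5.0))
        assert p.fdr == 1.0

    def test_monotone_in_height_at_fixed_width(self):
        fdrs = [assign_fdr(self.peak(h, 10), self.model()).fdr
                for h in np.linspace(0.5, 3.0, 7)]
        assert all(x >= y for x, y in zip(fdrs, fdrs[1:]))


class TestConsensus:
    def peak(self, rep, start, end, fdr, arm="2L"):
        return Peak(arm, rep, 0, 1, start, end, height_log2=1.5, fdr=fdr)

    def test_worst_member_fdr_is_kept(self):
        by_rep = {r: [self.peak(r, 100, 800, f)]
                  for r, f in zip(("r1", "r2", "r3"), (1e-4, 5e-4, 2e-3))}
        (cons,) = consensus_across_replicates(by_rep)
        assert cons.fdr == pytest.approx(2e-3)
        assert (cons.start_bp, cons.end_bp) == (100, 800)

    def test_peak_in_two_of_three_replicates_discarded(self):
        by_rep = {"r1": [self.peak("r1", 100, 800, 1e-4)],
                  "r2": [self.peak("r2", 150, 900, 1e-4)],
                  "r3": []}
        assert consensus_across_replicates(by_rep) == []

    def test_two_of_three_rule_as_config(self):
        by_rep = {"r1": [self.peak("r1", 100, 800, 1e-4)],
                  "r2": [self.peak("r2", 150, 900, 3e-4)],
                  "r3": []}
        (cons,) = consensus_across_replicates(by_rep, n_required=2)
        assert (cons.start_bp, cons.end_bp, cons.fdr) == (100, 900, 3e-4)

    def test_union_interval_spans_members(self):
        by_rep = {"r1": [self.peak("r1", 100, 800, 1e-4)],
                  "r2": [self.peak("r2", 700, 1200, 1e-4)],
                  "r3": [self.peak("r3", 50, 750, 1e-4)]}
        (cons,) = consensus_across_replicates(by_rep)
        assert (cons.start_bp, cons.end_bp) == (50, 1200)

    def test_bookended_intervals_do_not_overlap(self):
        by_rep = {"r1": [self.peak("r1", 100, 800, 1e-4)],
                  "r2": [self.peak("r2", 800, 900, 1e-4)],
                  "r3": [self.peak("r3", 100, 800, 1e-4)]}
        assert consensus_across_replicates(by_rep) == []

    def test_missing_fdr_rejected(self):
        by_rep = {"r1": [Peak("2L", "r1", 0, 1, 0, 100, 1.5)]}
        with pytest.raises(ValueError, match="FDR"):
            consensus_across_replicates(by_rep)
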