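"""Occupancy tracks, metagene profiles, phasing and shift statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nurfscape import nucleosomes as nuc
from nurfscape.io import CoverageTrack


def midpoint_bed(positions):
    return pd.DataFrame(
        {
            "chrom": "chr",
            "start": positions,
            "end": np.asarray(positions) + 1,
            "name": "m",
            "score": 0,
            "strand": "+",
        }
    )


class TestOccupancyTrack:
    def test_zero_smoothing_is_raw_histogram(self):
        track = nuc.occupancy_track(midpoint_bed([10, 10, 50]), 100, smooth_sd=0)
        assert track.values[10] == 2
        assert track.values[50] == 1
        assert track.total() == 3

    def test_single_midpoint_unimodal_unit_mass(self):
        track = nuc.occupancy_track(midpoint_bed([500]), 1000, smooth_sd=20)
        assert track.total() == pytest.approx(1.0, abs=1e-9)
        peak = int(np.argmax(track.values)) + track.start
        assert peak == 500
        # symmetric around the midpoint
        v = track.values
        i = np.argmax(v)
        np.testing.assert_allclose(v[i - 50 : i], v[i + 50 : i : -1], rtol=1e-9)

    def test_two_midpoints_resolvable(self):
        track = nuc.occupancy_track(midpoint_bed([400, 580]), 1000, smooth_sd=20)
        from scipy.signal import find_peaks

        peaks, _ = find_peaks(track.values, prominence=0.001)
        coords = peaks + track.start
        assert len(coords) == 2
        assert abs((coords[1] - coords[0]) - 180) <= 2

    @given(st.floats(min_value=0.0, max_value=60.0), st.integers(min_value=1, max_value=50))
    @settings(derandomize=True, max_examples=25, deadline=None)
    def test_mass_conservation_property(self, sd, n):
        rng = np.random.default_rng(n)
        pos = rng.integers(0, 300, size=n)
        track = nuc.occupancy_track(midpoint_bed(pos), 300, smooth_sd=sd)
        assert track.total() == pytest.approx(n, rel=1e-9)


class TestAveragedProfile:
    def test_constant_track_gives_flat_profile(self):
        track = CoverageTrack("chr", 0, np.full(2000, 3.0))
        anchors = pd.DataFrame({"pos": [600, 900], "strand": ["+", "+"]})
        offsets, prof = nuc.averaged_profile(track, anchors, 100, 450)
        np.testing.assert_allclose(prof, 3.0)
        assert offsets[0] == -100 and offsets[-1] == 450

    def test_single_anchor_equals_its_row(self):
        vals = np.random.default_rng(0).uniform(size=2000)
        track = CoverageTrack("chr", 0, vals)
        anchors = pd.DataFrame({"pos": [700], "strand": ["+"]})
        _, prof = nuc.averaged_profile(track, anchors, 100, 450)
        np.testing.assert_array_equal(prof, vals[600:1151])

    def test_minus_strand_profile_is_mirrored(self):
        vals = np.zeros(2000)
        vals[1000 + 135] = 5.0  # feature 135 bp right of a plus-strand anchor
        track = CoverageTrack("chr", 0, vals)
        plus = pd.DataFrame({"pos": [1000], "strand": ["+"]})
        _, p_plus = nuc.averaged_profile(track, plus, 100, 450)
        vals2 = np.zeros(2000)
        vals2[1000 - 135] = 5.0  # same feature, gene on the minus strand
        track2 = CoverageTrack("chr", 0, vals2)
        minus = pd.DataFrame({"pos": [1000], "strand": ["-"]})
        _, p_minus = nuc.averaged_profile(track2, minus, 100, 450)
        np.testing.assert_array_equal(p_plus, p_minus)

    def test_out_of_bounds_anchor_skipped_with_warning(self):
        track = CoverageTrack("chr", 0, np.ones(600))
        anchors = pd.DataFrame({"pos": [50, 300], "strand": ["+", "+"]})
        with pytest.warns(UserWarning, match="skipped"):
            _, prof = nuc.averaged_profile(track, anchors, 100, 200)
        np.testing.assert_allclose(prof, 1.0)


class TestPhasedCount:
    @staticmethod
    def synthetic_profile(n_peaks, dropped=None, repeat=180, first=135):
        offsets = np.arange(-100, 1500)
        prof = np.zeros_like(offsets, dtype=float)
        for k in range(n_peaks):
            if dropped and (k + 1) in dropped:
                amp = 0.05
            else:
                amp = 1.0
            center = first + k * repeat
            prof += amp * np.exp(-0.5 * ((offsets - center) / 25) ** 2)
        return offsets, prof

    def test_seven_equal_peaks(self):
        offsets, prof = self.synthetic_profile(7)
        assert nuc.count_phased_nucleosomes(offsets, prof) == 7

    def test_flat_profile(self):
        offsets = np.arange(-100, 1500)
        assert nuc.count_phased_nucleosomes(offsets, np.ones_like(offsets, float)) == 0

    def test_stops_at_first_failure(self):
        offsets, prof = self.synthetic_profile(7, dropped={4})
        assert nuc.count_phased_nucleosomes(offsets, prof) == 3


class TestSlidingShift:
    def test_identical_tracks_give_zero(self):
        vals = np.random.default_rng(1).poisson(5, size=2000).astype(float)
        track = CoverageTrack("chr", 0, vals)
        shift = nuc.sliding_shift(track, track)
        np.testing.assert_array_equal(shift.log2fc, 0.0)

    def test_doubled_window_without_normalization(self):
        wt = np.ones(1000)
        mut = np.ones(1000)
        mut[500:550] = 2.0
        shift = nuc.sliding_shift(
            CoverageTrack("chr", 0, wt),
            CoverageTrack("chr", 0, mut),
            pseudocount=1e-9,
            normalize=False,
            raw=True,
        )
        idx = np.flatnonzero(shift.starts == 500)[0]
        assert shift.log2fc[idx] == pytest.approx(1.0, abs=1e-6)

    def test_antisymmetry_under_genotype_swap(self):
        rng = np.random.default_rng(2)
        a = CoverageTrack("chr", 0, rng.poisson(10, 3000).astype(float))
        b = CoverageTrack("chr", 0, rng.poisson(10, 3000).astype(float))
        fwd = nuc.sliding_shift(a, b)
        rev = nuc.sliding_shift(b, a)
        np.testing.assert_allclose(fwd.log2fc, -rev.log2fc, atol=1e-9)

    def test_refuses_unnormalized_without_raw(self):
        track = CoverageTrack("chr", 0, np.ones(200))
        with pytest.raises(ValueError, match="raw"):
            nuc.sliding_shift(track, track, normalize=False)


class TestShiftDisplacement:
    def test_identical_profiles(self):
        prof = np.exp(-0.5 * ((np.arange(400) - 200) / 30.0) ** 2)
        assert nuc.shift_displacement(prof, prof) == 0.0

    def test_constructed_translation(self):
        x = np.arange(600)
        wt = np.exp(-0.5 * ((x - 300) / 30.0) ** 2)
        mut = np.exp(-0.5 * ((x - 270) / 30.0) ** 2)  # 30 bp toward the TSS
        assert nuc.shift_displacement(wt, mut, max_lag=60) == -30.0

    def test_zero_variance_undefined(self):
        assert np.isnan(nuc.shift_displacement(np.ones(100), np.ones(100)))


class TestQuintiles:
    def test_ten_distinct_sites(self):
        sites = pd.DataFrame({"pos": np.arange(10), "signal": np.arange(10, 0, -1.0)})
        labels = nuc.quintile_rank(sites)
        assert list(labels) == [1, 1, 2, 2, 3, 3, 4, 4, 5, 5]

    def test_remainder_rule_for_5456_sites(self):
        rng = np.random.default_rng(3)
        sites = pd.DataFrame({"pos": np.arange(5456), "signal": rng.uniform(size=5456)})
        labels = nuc.quintile_rank(sites)
        counts = pd.Series(labels).value_counts().sort_index()
        assert list(counts) == [1092, 1091, 1091, 1091, 1091]

    def test_all_equal_signals_coordinate_stable(self):
        sites = pd.DataFrame({"pos": np.arange(10), "signal": np.ones(10)})
        labels = nuc.quintile_rank(sites)
        assert list(labels) == [1, 1, 2, 2, 3, 3, 4, 4, 5, 5]
        counts = pd.Series(labels).value_counts()
        assert set(counts) == {2}

    def test_too_few_sites_rejected(self):
        with pytest.raises(ValueError):
            nuc.quintile_rank(pd.DataFrame({"pos": [1], "signal": [1.0]}))


class TestKmeansRows:
    def test_separated_groups_exact_partition(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 0.1, size=(20, 30))
        b = rng.normal(10, 0.1, size=(20, 30))
        matrix = np.vstack([a, b])
        labels, order = nuc.kmeans_rows(matrix, k=2, seed=0)
        assert len(set(labels[:20])) == 1
        assert len(set(labels[20:])) == 1
        assert labels[0] != labels[20]
        assert len(order) == 40

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(5)
        matrix = rng.uniform(size=(50, 20))
        l1, o1 = nuc.kmeans_rows(matrix, k=3, seed=11)
        l2, o2 = nuc.kmeans_rows(matrix, k=3, seed=11)
        np.testing.assert_array_equal(l1, l2)
        np.testing.assert_array_equal(o1, o2)

    def test_k_bounds(self):
        with pytest.raises(ValueError):
            nuc.kmeans_rows(np.ones((10, 5)), k=1)
        with pytest.raises(ValueError):
            nuc.kmeans_rows(np.ones((2, 5)), k=3)


class TestSignalCorrelation:
    def test_self_correlation(self):
        vals = np.random.default_rng(6).uniform(size=5000)
        track = CoverageTrack("chr", 0, vals)
        assert nuc.signal_correlation(track, track) == pytest.approx(1.0)

    def test_anticorrelated_pattern(self):
        vals = np.random.default_rng(7).uniform(1, 2, size=5000)
        a = CoverageTrack("chr", 0, vals)
        b = CoverageTrack("chr", 0, vals.max() + 0.5 - vals)
        assert nuc.signal_correlation(a, b) == pytest.approx(-1.0)

    def test_constant_track_undefined(self):
        a = CoverageTrack("chr", 0, np.ones(5000))
        b = CoverageTrack("chr", 0, np.random.default_rng(8).uniform(size=5000))
        assert np.isnan(nuc.signal_correlation(a, b))
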