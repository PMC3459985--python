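"""Size-class filtering, dyad mapping, binning and smoothing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dyadmap import (
    BinnedTrack, bin_dyads, dyad_positions, isize_spectrum, map_particles,
    size_class_filter, smooth3,
)
from dyadmap.particles import local_maxima

from conftest import make_pairs


class TestIsizeSpectrum:
    def test_exact_counts(self):
        pairs = make_pairs(["chrI"] * 3, [0, 10, 20], [150, 150, 300])
        assert isize_spectrum(pairs) == {150: 2, 300: 1}

    def test_empty(self):
        assert isize_spectrum(make_pairs([], [], [])) == {}


class TestSizeClassFilter:
    def test_mononucleosome_window_is_120_to_180_inclusive(self):
        # 150 bp +/- 20% keeps [120, 180]; bounds inclusive
        pairs = make_pairs(["chrI"] * 4, [0] * 4, [119, 120, 150, 180])
        kept = size_class_filter(pairs, 150, 0.2)
        assert sorted(kept["isize"]) == [120, 150, 180]

    def test_enumerated_grid_keeps_61_of_100_to_200(self):
        isizes = list(range(100, 201))
        kept = size_class_filter(make_pairs(["chrI"] * len(isizes), [0] * len(isizes), isizes))
        # brute-force enumeration of the inclusive acceptance interval
        expected = sum(1 for s in isizes if 120 <= s <= 180)
        assert expected == 61 and len(kept) == 61

    def test_empty_input(self):
        assert len(size_class_filter(make_pairs([], [], []))) == 0

    def test_matches_bruteforce_on_random_pairs(self, rng):
        isizes = rng.integers(50, 600, size=20_000)
        pairs = make_pairs(["chrI"] * len(isizes), np.zeros(len(isizes)), isizes)
        kept = size_class_filter(pairs, 150, 0.2)
        brute = [s for s in isizes if 150 * 0.8 <= s <= 150 * 1.2]
        assert sorted(kept["isize"]) == sorted(brute)

    @given(st.lists(st.integers(1, 1000), max_size=50))
    @settings(derandomize=True, deadline=None)
    def test_idempotent(self, isizes):
        pairs = make_pairs(["chrI"] * len(isizes), [0] * len(isizes), isizes)
        once = size_class_filter(pairs)
        twice = size_class_filter(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_rejects_bad_parameters(self):
        pairs = make_pairs(["chrI"], [0], [150])
        with pytest.raises(ValueError):
            size_class_filter(pairs, target=0)
        with pytest.raises(ValueError):
            size_class_filter(pairs, window_fraction=1.5)


class TestDyadPositions:
    @pytest.mark.parametrize(
        "left5,isize,expected", [(1000, 150, 1075), (0, 151, 75), (7, 2, 8)]
    )
    def test_floor_of_half_isize(self, left5, isize, expected):
        pos = dyad_positions(make_pairs(["chrI"], [left5], [isize]))
        assert pos["position"].iloc[0] == expected

    def test_recovers_truth_without_noise(self):
        """Zero jitter + mono-only class: dyad multiset equals truth dyads."""
        from dyadmap import SimConfig, make_genome, simulate_mnase_pairs

        cfg = SimConfig(
            seed=3, dyad_jitter=0, isize_sd=0.0,
            isize_class_weights=(1.0, 0.0, 0.0),
        )
        b = make_genome(cfg)
        pairs = simulate_mnase_pairs(b, "wt")
        got = set(dyad_positions(pairs)["position"])
        truth = set(b.truth.dyads["wt"]["position"])
        assert got <= truth  # every mapped dyad sits exactly on a truth dyad
        # and nearly all truth dyads are seen (ends of chromosomes may clip)
        assert len(got) >= 0.99 * len(truth)


class TestBinDyads:
    def test_single_bin(self):
        pos = pd.DataFrame({"chrom": ["chrI"] * 3, "position": [0, 7, 14]})
        track = bin_dyads(pos, 15)
        assert track.values["chrI"][0] == 3

    def test_floor_rule(self):
        pos = pd.DataFrame({"chrom": ["chrI"], "position": [1075]})
        track = bin_dyads(pos, 15)
        assert track.values["chrI"][71] == 1 and len(track.values["chrI"]) == 72

    @given(st.lists(st.integers(0, 5000), max_size=200))
    @settings(derandomize=True, deadline=None)
    def test_conserves_total_count(self, positions):
        pos = pd.DataFrame({"chrom": ["chrI"] * len(positions), "position": positions})
        track = bin_dyads(pos, 15)
        assert track.total() == len(positions)

    def test_out_of_range_counted_in_terminal_bin(self):
        pos = pd.DataFrame({"chrom": ["chrI"], "position": [999]})
        track = bin_dyads(pos, 15, chrom_lengths={"chrI": 150})
        assert track.values["chrI"][-1] == 1 and track.clipped == 1


class TestSmooth3:
    def test_constant_track_is_fixed_point(self):
        t = BinnedTrack(15, {"chrI": np.array([2.0, 2, 2, 2])})
        assert np.allclose(smooth3(t).values["chrI"], 2.0)

    def test_edge_shrink_rule(self):
        t = BinnedTrack(15, {"chrI": np.array([0.0, 3.0, 0.0])})
        assert np.allclose(smooth3(t).values["chrI"], [1.5, 1.0, 1.5])

    def test_mass_conserved_with_zero_padding(self, rng):
        v = rng.poisson(5, size=50).astype(float)
        padded = np.concatenate([[0, 0], v, [0, 0]])
        t = BinnedTrack(15, {"chrI": padded})
        assert smooth3(t).values["chrI"].sum() == pytest.approx(padded.sum())

    def test_equals_direct_rule_on_random_tracks(self, rng):
        for _ in range(200):
            v = rng.random(rng.integers(3, 40))
            got = smooth3(BinnedTrack(10, {"c": v})).values["c"]
            # independent direct evaluation of the 3-bin moving average
            exp = np.array(
                [
                    np.mean(v[max(i - 1, 0):i + 2])
                    for i in range(len(v))
                ]
            )
            np.testing.assert_allclose(got, exp, atol=1e-12)


class TestMapParticles:
    def test_empty_input_gives_zero_track(self):
        track = map_particles(make_pairs([], [], []), chrom_lengths={"chrI": 300})
        assert track.total() == 0

    def test_compositional_identity(self, wt_pairs, bundle):
        direct = map_particles(wt_pairs, chrom_lengths=bundle.chrom_lengths)
        composed = smooth3(
            bin_dyads(
                dyad_positions(size_class_filter(wt_pairs, 150, 0.2)),
                15, bundle.chrom_lengths,
            )
        )
        for c in direct.values:
            np.testing.assert_allclose(direct.values[c], composed.values[c])

    def test_linear_before_smoothing(self, rng):
        a = make_pairs(["chrI"] * 50, rng.integers(0, 3000, 50), rng.integers(120, 180, 50))
        b = make_pairs(["chrI"] * 30, rng.integers(0, 3000, 30), rng.integers(120, 180, 30))
        both = pd.concat([a, b], ignore_index=True)
        cl = {"chrI": 4000}
        ta = map_particles(a, chrom_lengths=cl, smooth=False)
        tb = map_particles(b, chrom_lengths=cl, smooth=False)
        tab = map_particles(both, chrom_lengths=cl, smooth=False)
        np.testing.assert_allclose(tab.values["chrI"], ta.values["chrI"] + tb.values["chrI"])

    def test_dinucleosome_class_peaks_at_linker_midpoints(self):
        """The 300 bp class maps di-nucleosome centres between adjacent dyads."""
        from dyadmap import SimConfig, make_genome, simulate_mnase_pairs
        from dyadmap.particles import call_peaks

        cfg = SimConfig(seed=11, dyad_jitter=0, isize_sd=5.0)
        b = make_genome(cfg)
        pairs = simulate_mnase_pairs(b, "wt")
        track = map_particles(pairs, target=300, chrom_lengths=b.chrom_lengths)
        peaks = call_peaks(track)
        truth = b.truth.dyads["wt"]
        hits = total = 0
        for chrom, sub in truth.groupby("chrom"):
            pos = np.sort(sub["position"].to_numpy())
            mids = (pos[:-1] + pos[1:]) // 2
            # only midpoints of adjacent dyads (regular spacing)
            mids = mids[np.diff(pos) <= 2 * cfg.nucleosome_spacing]
            ppos = np.sort(peaks.loc[peaks.chrom == chrom, "position"].to_numpy())
            for m in mids:
                total += 1
                i = np.searchsorted(ppos, m)
                near = [ppos[j] for j in (i - 1, i) if 0 <= j < len(ppos)]
                if near and min(abs(p - m) for p in near) <= 22.5:
                    hits += 1
        assert hits / total > 0.9


class TestLocalMaxima:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([0, 1, 0, 2, 0], [1, 3]),
            ([1, 1, 1], [0]),  # whole-array plateau -> leftmost bin
            ([0, 2, 2, 0], [1]),  # plateau -> leftmost bin
            ([3, 0, 0], [0]),  # array end counts as lower
            ([0], []),
        ],
    )
    def test_plateau_and_tie_rules(self, values, expected):
        assert local_maxima(np.array(values, dtype=float)).tolist() == expected
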