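"""Anchored and scaled average-gene profiles and ratio curves."""

import numpy as np
import pandas as pd
import pytest

from dyadmap import (
    BinnedTrack, GeneModel, anchored_profile, moving_average_ratio,
    normalize_occupancy, scaled_profile,
)
from dyadmap.metagene import gene_matrix, probe_offsets, scaled_gene_vector


def gene(gid, strand, start, end, chrom="chrI", u5=None, u3=None):
    return GeneModel(gid, chrom, strand, start, end, utr5_len=u5, utr3_len=u3)


def base_track(values_per_base, bw=1):
    return BinnedTrack(bw, {"chrI": np.asarray(values_per_base, dtype=float)})


class TestAnchoredProfile:
    def test_indicator_bin_at_tss(self):
        v = np.zeros(400)
        g = gene("g", "+", 5000, 8000)
        track = BinnedTrack(25, {"chrI": v})
        track.values["chrI"][5000 // 25] = 1.0
        prof = anchored_profile(track, [g], upstream=1000, downstream=2000, probe=25)
        at0 = prof.loc[prof.offset == 0, "mean"].iloc[0]
        assert at0 == 1.0
        assert prof.loc[prof.offset != 0, "mean"].abs().sum() == 0.0

    def test_strand_flip_invariance_exact(self, rng):
        Lg = 10_000
        bw = 10
        v = rng.random(Lg // bw)
        g = gene("g", "+", 4000, 6000, u5=40, u3=60)
        fwd = BinnedTrack(bw, {"chrI": v})
        rev = BinnedTrack(bw, {"chrI": v[::-1].copy()})
        gm = GeneModel("g", "chrI", "-", Lg - 6000, Lg - 4000, utr5_len=40, utr3_len=60)
        for anchor in ("tss5", "tts3"):
            a = gene_matrix(fwd, [g], anchor, 1000, 2000, 25)
            b = gene_matrix(rev, [gm], anchor, 1000, 2000, 25)
            np.testing.assert_allclose(a, b, atol=1e-12)

    def test_planted_signal_localised_downstream(self, rng):
        v = rng.random(1000) * 0.1
        g = gene("g", "+", 10_000, 14_000)
        track = BinnedTrack(25, {"chrI": v})
        lo, hi = (10_000 + 200) // 25, (10_000 + 400) // 25
        track.values["chrI"][lo:hi] += 5.0
        prof = anchored_profile(track, [g], upstream=1000, downstream=2000, probe=25)
        best = prof.loc[prof["mean"].idxmax(), "offset"]
        assert 200 <= best <= 400

    def test_equals_bruteforce_per_gene_loop(self, rng):
        """Oracle: expand bins to base resolution and average per probe."""
        bw, probe, up, down = 10, 25, 200, 400
        n_bins = 3000
        v = rng.random(n_bins)
        track = BinnedTrack(bw, {"chrI": v})
        per_base = np.repeat(v, bw)
        genes = []
        for i in range(200):
            strand = "+" if rng.random() < 0.5 else "-"
            start = int(rng.integers(0, n_bins * bw - 2000))
            genes.append(gene(f"g{i}", strand, start, start + int(rng.integers(500, 1500))))
        mat = gene_matrix(track, genes, "tss5", up, down, probe)
        offsets = probe_offsets(up, down, probe)
        for gi, g in enumerate(genes):
            a = g.tss
            for j, o in enumerate(offsets):
                if g.strand == "+":
                    s, e = a + o, a + o + probe
                else:
                    s, e = a - o - probe, a - o
                if s < 0 or e > len(per_base):
                    assert np.isnan(mat[gi, j])
                else:
                    assert abs(per_base[s:e].mean() - mat[gi, j]) <= 1e-9

    def test_out_of_range_offsets_excluded_from_mean(self):
        v = np.ones(40)
        g = gene("g", "+", 100, 600)  # upstream window exceeds chromosome start
        prof = anchored_profile(BinnedTrack(25, {"chrI": v}), [g],
                                upstream=1000, downstream=500, probe=25)
        sub = prof[prof.offset < -100]
        assert (sub["n"] == 0).all()
        assert (prof.loc[prof.offset >= 100, "n"] == 1).all()

    def test_strata_sizes_sum_to_gene_count(self, rng):
        v = rng.random(4000)
        genes = []
        for i in range(30):
            g = gene(f"g{i}", "+", 10_000 + i * 800, 10_000 + i * 800 + 500)
            g.expression_category = ["low", "medium", "high"][i % 3]
            genes.append(g)
        track = BinnedTrack(25, {"chrI": v})
        prof = anchored_profile(track, genes, upstream=100, downstream=100, probe=25)
        per_offset = prof.groupby("offset")["n"].sum()
        assert (per_offset == 30).all()


class TestScaledProfile:
    def test_constant_track_gives_constant_profile(self):
        track = BinnedTrack(25, {"chrI": np.full(2000, 3.0)})
        genes = [gene("a", "+", 10_000, 14_000), gene("b", "-", 20_000, 26_000)]
        prof = scaled_profile(track, genes)
        assert np.allclose(prof["mean"], 3.0)

    def test_body_resampling_identity_when_lengths_match(self, rng):
        bw, body_bins = 25, 40
        v = rng.random(400)
        track = BinnedTrack(bw, {"chrI": v})
        g = gene("g", "+", 2000, 2000 + body_bins * bw)
        vec = scaled_gene_vector(track, g, body_bins=body_bins, flank=100, flank_fragment=25)
        body = vec[4:44]
        np.testing.assert_allclose(body, v[80:120])

    def test_shape_preserved_across_gene_lengths(self, rng):
        """Two genes with the same relative signal shape resample alike."""
        bw = 10
        n = 10_000
        track_values = np.zeros(n)
        # gene A: length 400 starting 20000; gene B: length 4000 starting 50000
        a0, alen, b0, blen = 20_000, 400, 50_000, 4000
        x = np.linspace(0, 1, alen // bw, endpoint=False)
        shape = np.sin(2 * np.pi * x) + 2
        track_values[a0 // bw:(a0 + alen) // bw] = shape
        xb = np.linspace(0, 1, blen // bw, endpoint=False)
        track_values[b0 // bw:(b0 + blen) // bw] = np.sin(2 * np.pi * xb) + 2
        track = BinnedTrack(bw, {"chrI": track_values})
        va = scaled_gene_vector(track, gene("a", "+", a0, a0 + alen), flank=100)
        vb = scaled_gene_vector(track, gene("b", "+", b0, b0 + blen), flank=100)
        # point-sampled vs window-averaged sine differ by O(pi/40)
        np.testing.assert_allclose(va[4:44], vb[4:44], atol=0.1)

    def test_short_genes_excluded(self):
        track = BinnedTrack(25, {"chrI": np.ones(100)})
        prof = scaled_profile(track, [gene("tiny", "+", 100, 120)], body_bins=40)
        assert len(prof) == 0


class TestNormalizeOccupancy:
    def test_direct_example(self):
        np.testing.assert_allclose(normalize_occupancy([2, 4, 6]), [0.5, 1.0, 1.5])

    def test_idempotent(self, rng):
        x = normalize_occupancy(rng.random(50) + 0.1)
        np.testing.assert_allclose(normalize_occupancy(x), x)

    def test_output_mean_is_one(self, rng):
        out = normalize_occupancy(rng.random(1000) + 0.01)
        assert abs(out.mean() - 1.0) < 1e-12

    def test_zero_mean_errors(self):
        with pytest.raises(ValueError):
            normalize_occupancy(np.zeros(5))


class TestMovingAverageRatio:
    def test_flat_when_all_ratios_one(self):
        idx = [f"g{i}" for i in range(200)]
        expr = pd.Series(np.linspace(1, 100, 200), index=idx)
        curve = moving_average_ratio(expr, expr, window=150)
        assert np.allclose(curve["mean_ratio"], 1.0)

    def test_window_count(self, rng):
        idx = [f"g{i}" for i in range(300)]
        wt = pd.Series(rng.random(300) * 10, index=idx)
        mut = pd.Series(rng.random(300) * 10, index=idx)
        curve = moving_average_ratio(wt, mut, window=150, step=1)
        assert len(curve) == 151

    def test_full_window_equals_global_mean_ratio(self, rng):
        idx = [f"g{i}" for i in range(80)]
        wt = pd.Series(rng.random(80) * 10 + 1, index=idx)
        mut = pd.Series(rng.random(80) * 10 + 1, index=idx)
        curve = moving_average_ratio(wt, mut, window=80)
        expected = ((mut + 1) / (wt + 1)).mean()
        assert len(curve) == 1
        assert curve["mean_ratio"].iloc[0] == pytest.approx(expected)

    def test_low_expression_boost_elevates_low_end(self):
        """Weakly expressed genes with inflated mutant ratios lift the curve
        at the low-expression end while mid/high expression stays near 1."""
        from dyadmap import SimConfig, make_genome, simulate_expression

        cfg = SimConfig(seed=5, n_chromosomes=6, n_genes_per_chrom=25,
                        de_fraction=0.0, low_expression_ratio_boost=1.0)
        b = make_genome(cfg)
        table = simulate_expression(b)
        wt = pd.Series(table.wt_count.values, index=table.gene_id, dtype=float)
        mut = pd.Series(table.mut_count.values, index=table.gene_id, dtype=float)
        curve = moving_average_ratio(wt, mut, window=50)
        low_end = curve["mean_ratio"].iloc[0]
        high_end = curve["mean_ratio"].iloc[-1]
        assert low_end > 1.3
        assert abs(high_end - 1.0) < 0.15
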