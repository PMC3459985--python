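"""Average-gene (metagene) profiles: anchored, scaled, and expression ratio.

Profiles average a binned signal across many genes after aligning them on
a common anchor (transcript start or termination site) or rescaling gene
bodies to a fixed number of bins.  All extraction is strand-aware: minus-
strand genes are read 5'->3', i.e. their windows are mirrored.  Per-offset
95% confidence intervals use the normal approximation (mean +/- 1.96 SE).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .model import BinnedTrack, GeneModel

logger = logging.getLogger(__name__)

Z95 = 1.96


def _integral(values: np.ndarray) -> np.ndarray:
    # cumulative integral of the bin step function at bin boundaries
    return np.concatenate([[0.0], np.cumsum(values)])


def _interval_means(
    values: np.ndarray, bin_width: int, starts: np.ndarray, ends: np.ndarray
) -> np.ndarray:
    """Overlap-weighted mean of a binned step function over [start, end).

    Intervals reaching outside the chromosome are returned as ``nan``
    (missing), matching the out-of-range policy for terminal genes.
    """
    n = len(values)
    total = n * bin_width
    F = _integral(values) * bin_width

    def point(x):
        x = np.clip(x, 0, total)
        i = np.minimum((x // bin_width).astype(np.int64), n - 1)
        return F[i] + values[i] * (x - i * bin_width)

    s = np.asarray(starts, dtype=float)
    e = np.asarray(ends, dtype=float)
    with np.errstate(invalid="ignore"):
        out = (point(e) - point(s)) / (e - s)
    out[(s < 0) | (e > total) | (e <= s)] = np.nan
    return out


def _gene_window_probes(
    gene: GeneModel, anchor: str, upstream: int, downstream: int, probe: int
) -> tuple[np.ndarray, np.ndarray]:
    """Genomic [start, end) of each probe, ordered 5'->3' along the gene."""
    if anchor == "tss5":
        a = gene.tss
    elif anchor == "tts3":
        a = gene.tts
    else:
        raise ValueError(f"anchor must be 'tss5' or 'tts3', got {anchor!r}")
    offsets = np.arange(-upstream, downstream, probe)
    if gene.strand == "+":
        starts = a + offsets
        ends = starts + probe
    else:
        ends = a - offsets
        starts = ends - probe
    return starts.astype(float), ends.astype(float)


def probe_offsets(upstream: int, downstream: int, probe: int = 25) -> np.ndarray:
    """Gene-relative start offset of each probe (anchor at 0)."""
    return np.arange(-upstream, downstream, probe)


def _summarise(matrix: np.ndarray, offsets: np.ndarray, strata: np.ndarray) -> pd.DataFrame:
    """Per-offset, per-stratum mean with normal-approximation 95% CI."""
    rows = []
    for stratum in pd.unique(strata):
        sub = matrix[strata == stratum]
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # offsets with n=0
            n_eff = np.sum(np.isfinite(sub), axis=0)
            mean = np.nanmean(np.where(np.isfinite(sub), sub, np.nan), axis=0)
            sd = np.nanstd(np.where(np.isfinite(sub), sub, np.nan), axis=0, ddof=1)
        se = np.where(n_eff > 1, sd / np.sqrt(np.maximum(n_eff, 1)), np.nan)
        for j, off in enumerate(offsets):
            rows.append(
                {
                    "offset": off,
                    "stratum": stratum,
                    "n": int(n_eff[j]),
                    "mean": mean[j],
                    "ci_low": mean[j] - Z95 * se[j],
                    "ci_high": mean[j] + Z95 * se[j],
                }
            )
    return pd.DataFrame(rows)


def gene_matrix(
    track: BinnedTrack,
    genes: list[GeneModel],
    anchor: str = "tss5",
    upstream: int = 1000,
    downstream: int = 2000,
    probe: int = 25,
) -> np.ndarray:
    """Per-gene probe-value matrix (genes x probes), 5'->3' oriented."""
    offsets = probe_offsets(upstream, downstream, probe)
    mat = np.full((len(genes), len(offsets)), np.nan)
    for gi, g in enumerate(genes):
        if g.chrom not in track.values:
            continue
        starts, ends = _gene_window_probes(g, anchor, upstream, downstream, probe)
        mat[gi] = _interval_means(track.values[g.chrom], track.bin_width, starts, ends)
    return mat


def anchored_profile(
    track: BinnedTrack,
    genes: list[GeneModel],
    anchor: str = "tss5",
    upstream: int = 1000,
    downstream: int = 2000,
    probe: int = 25,
    stratify: bool = True,
) -> pd.DataFrame:
    """Average signal around an anchor, per expression stratum.

    Tiled probes of ``probe`` bp span ``-upstream .. +downstream``
    relative to the anchor, read in gene orientation.  Returns a table
    with columns ``offset, stratum, n, mean, ci_low, ci_high``; offsets
    out of chromosome range for a gene are missing for that gene and
    excluded from the corresponding mean.
    """
    offsets = probe_offsets(upstream, downstream, probe)
    mat = gene_matrix(track, genes, anchor, upstream, downstream, probe)
    if stratify:
        strata = np.array([g.expression_category or "all" for g in genes], dtype=object)
    else:
        strata = np.array(["all"] * len(genes), dtype=object)
    return _summarise(mat, offsets, strata)


def scaled_gene_vector(
    track: BinnedTrack,
    gene: GeneModel,
    body_bins: int = 40,
    flank: int = 1250,
    flank_fragment: int = 25,
) -> np.ndarray | None:
    """One gene's flank5 + scaled-body + flank3 vector, or None if too short.

    The transcript body is resampled to ``body_bins`` equal segments
    (overlap-weighted means); each flank contributes
    ``flank // flank_fragment`` fragments of ``flank_fragment`` bases.
    """
    lo, hi = sorted((gene.tss, gene.tts))
    if hi - lo < body_bins:
        return None
    values = track.values.get(gene.chrom)
    if values is None:
        return None
    n_frag = flank // flank_fragment
    frag = np.arange(n_frag, dtype=float) * flank_fragment

    body_edges = np.linspace(lo, hi, body_bins + 1)
    body = _interval_means(values, track.bin_width, body_edges[:-1], body_edges[1:])

    up_starts = lo - flank + frag
    dn_starts = hi + frag
    up = _interval_means(values, track.bin_width, up_starts, up_starts + flank_fragment)
    dn = _interval_means(values, track.bin_width, dn_starts, dn_starts + flank_fragment)
    vec = np.concatenate([up, body, dn])
    if gene.strand == "-":
        vec = vec[::-1]
    return vec


def scaled_profile(
    track: BinnedTrack,
    genes: list[GeneModel],
    body_bins: int = 40,
    flank: int = 1250,
    flank_fragment: int = 25,
    stratify: bool = True,
) -> pd.DataFrame:
    """Average scaled-gene profile (flank + rescaled body + flank).

    Genes shorter than ``body_bins`` bases are excluded with a warning.
    Output positions are indices into the concatenated
    flank5/body/flank3 vector; the ``segment`` column labels which part
    each position belongs to.
    """
    n_frag = flank // flank_fragment
    vecs, strata = [], []
    n_skipped = 0
    for g in genes:
        v = scaled_gene_vector(track, g, body_bins, flank, flank_fragment)
        if v is None:
            n_skipped += 1
            continue
        vecs.append(v)
        strata.append(g.expression_category or "all" if stratify else "all")
    if n_skipped:
        logger.warning("scaled_profile: %d genes excluded (too short or absent)", n_skipped)
    if not vecs:
        return pd.DataFrame(columns=["offset", "stratum", "n", "mean", "ci_low", "ci_high", "segment"])
    mat = np.vstack(vecs)
    positions = np.arange(mat.shape[1])
    out = _summarise(mat, positions, np.array(strata, dtype=object))
    seg = np.where(
        out["offset"] < n_frag, "flank5",
        np.where(out["offset"] < n_frag + body_bins, "body", "flank3"),
    )
    out["segment"] = seg
    return out


def normalize_occupancy(values: np.ndarray) -> np.ndarray:
    """Scale a profile window so its mean is exactly 1.

    Dividing by the window-average places "random" occupancy at 1;
    a window with non-positive mean is an error.
    """
    arr = np.asarray(values, dtype=float)
    mean = np.nanmean(arr)
    if not np.isfinite(mean) or mean <= 0:
        raise ValueError("window mean must be positive to normalize occupancy")
    return arr / mean


def moving_average_ratio(
    expr_wt: pd.Series,
    expr_mut: pd.Series,
    window: int = 150,
    step: int = 1,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Moving average of mutant/wt expression ratio along the wt-expression axis.

    Genes are sorted by wild-type expression (ties by gene id); a window
    of ``window`` genes slides by ``step``; each window reports the mean
    wt expression (x) and mean per-gene ratio (y).  The number of windows
    is ``(n - window) // step + 1``.
    """
    wt = pd.Series(expr_wt, dtype=float)
    mut = pd.Series(expr_mut, dtype=float).reindex(wt.index)
    if mut.isna().any():
        raise ValueError("expression tables must cover the same genes")
    n = len(wt)
    if window > n:
        raise ValueError(f"window {window} exceeds gene count {n}")
    order = sorted(wt.index, key=lambda gid: (wt[gid], str(gid)))
    w = wt[order].to_numpy()
    ratio = ((mut[order] + pseudocount) / (wt[order] + pseudocount)).to_numpy()
    rows = []
    for start in range(0, n - window + 1, step):
        sl = slice(start, start + window)
        rows.append({"wt_expression": w[sl].mean(), "mean_ratio": ratio[sl].mean()})
    return pd.DataFrame(rows)
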