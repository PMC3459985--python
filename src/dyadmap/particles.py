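"""Size-class chromatin-particle dyad mapping from paired-end alignments.

The core computation: paired-end MNase alignments are sorted into insert
size classes (nominal length +/- a fractional window, e.g. 150 bp +/- 20%
for mono-nucleosomes), the centre of each retained pair is taken as the
putative particle dyad, dyads are binned genome-wide (15 bp default) and
the frequency distribution smoothed with a 3-bin moving average.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
import pandas as pd

from .model import BinnedTrack


def isize_spectrum(pairs: pd.DataFrame) -> Counter:
    """Exact integer counts of each observed insert size (no binning)."""
    if len(pairs) == 0:
        return Counter()
    values, counts = np.unique(pairs["isize"].to_numpy(), return_counts=True)
    return Counter(dict(zip(values.tolist(), counts.tolist())))


def spectrum_local_maxima(spectrum: Counter, min_separation: int = 50) -> list[int]:
    """Insert sizes at local maxima of the (lightly smoothed) spectrum.

    The raw per-base spectrum is noisy; a short moving average is applied
    before scanning, and maxima closer than ``min_separation`` to a higher
    maximum are suppressed.  Used to verify the mono/di/tri-nucleosome
    periodicity of a library.
    """
    if not spectrum:
        return []
    lo, hi = min(spectrum), max(spectrum)
    x = np.arange(lo, hi + 1)
    y = np.array([spectrum.get(int(v), 0) for v in x], dtype=float)
    k = 11
    kernel = np.ones(k) / k
    ys = np.convolve(y, kernel, mode="same")
    cand = [
        i for i in range(1, len(ys) - 1)
        if ys[i] > ys[i - 1] and ys[i] >= ys[i + 1]
    ]
    cand.sort(key=lambda i: -ys[i])
    kept: list[int] = []
    for i in cand:
        if all(abs(i - j) >= min_separation for j in kept):
            kept.append(i)
    return sorted(int(x[i]) for i in kept)


def size_class_filter(pairs: pd.DataFrame, target: int = 150, window_fraction: float = 0.2) -> pd.DataFrame:
    """Keep pairs whose insert size lies in ``target x (1 +/- window_fraction)``.

    Bounds are inclusive: the default 150 bp +/- 20% keeps insert sizes in
    [120, 180], the mono-nucleosome class.
    """
    if target <= 0:
        raise ValueError("target must be positive")
    if not 0 < window_fraction < 1:
        raise ValueError("window_fraction must lie in (0, 1)")
    lo = target * (1 - window_fraction)
    hi = target * (1 + window_fraction)
    isize = pairs["isize"]
    return pairs[(isize >= lo) & (isize <= hi)].reset_index(drop=True)


def dyad_positions(pairs: pd.DataFrame) -> pd.DataFrame:
    """Map each pair to its putative dyad: ``left5 + floor(isize / 2)``.

    Returns a ``(chrom, position)`` table preserving input order.
    """
    return pd.DataFrame(
        {
            "chrom": pairs["chrom"].to_numpy(),
            "position": pairs["left5"].to_numpy() + pairs["isize"].to_numpy() // 2,
        }
    )


def bin_dyads(
    positions: pd.DataFrame,
    bin_width: int = 15,
    chrom_lengths: dict[str, int] | None = None,
) -> BinnedTrack:
    """Genome-wide dyad frequency binned at ``bin_width`` (bin = floor(pos/w)).

    The total over all bins equals the number of input dyads exactly.
    When ``chrom_lengths`` is given, arrays span the full chromosome and
    out-of-range positions are counted in the terminal bin (with a
    warning counter on the returned track's ``clipped`` attribute).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    values: dict[str, np.ndarray] = {}
    clipped = 0
    if chrom_lengths:
        for c, L in chrom_lengths.items():
            values[c] = np.zeros(int(np.ceil(L / bin_width)))
    for chrom, sub in positions.groupby("chrom", sort=True):
        idx = sub["position"].to_numpy() // bin_width
        if chrom in values:
            n = len(values[chrom])
            out_of_range = (idx < 0) | (idx >= n)
            clipped += int(out_of_range.sum())
            idx = np.clip(idx, 0, n - 1)
        else:
            n = int(idx.max()) + 1 if len(idx) else 0
            values[chrom] = np.zeros(n)
        np.add.at(values[chrom], idx.astype(np.int64), 1.0)
    track = BinnedTrack(bin_width=bin_width, values=values, semantics="frequency")
    track.clipped = clipped  # type: ignore[attr-defined]
    return track


def smooth3(track: BinnedTrack) -> BinnedTrack:
    """3-bin moving average; terminal bins average the two available bins."""
    out: dict[str, np.ndarray] = {}
    for chrom, v in track.values.items():
        n = len(v)
        if n <= 2:
            out[chrom] = np.full(n, v.mean()) if n else v.copy()
            continue
        s = np.empty(n)
        s[1:-1] = (v[:-2] + v[1:-1] + v[2:]) / 3.0
        s[0] = (v[0] + v[1]) / 2.0
        s[-1] = (v[-2] + v[-1]) / 2.0
        out[chrom] = s
    return track.copy_with(out)


def map_particles(
    pairs: pd.DataFrame,
    target: int = 150,
    window_fraction: float = 0.2,
    bin_width: int = 15,
    chrom_lengths: dict[str, int] | None = None,
    smooth: bool = True,
) -> BinnedTrack:
    """Full particle-mapping pipeline: filter, centre, bin, smooth."""
    kept = size_class_filter(pairs, target=target, window_fraction=window_fraction)
    track = bin_dyads(dyad_positions(kept), bin_width=bin_width, chrom_lengths=chrom_lengths)
    return smooth3(track) if smooth else track


def local_maxima(values: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima; a plateau reports its leftmost bin.

    A run of equal values counts as one maximum when both its neighbours
    are strictly lower (array ends count as lower).
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n == 0:
        return np.array([], dtype=np.int64)
    if n == 1:
        return np.array([0], dtype=np.int64) if v[0] > 0 else np.array([], dtype=np.int64)
    peaks = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and v[j + 1] == v[i]:
            j += 1
        left_lower = i == 0 or v[i - 1] < v[i]
        right_lower = j == n - 1 or v[j + 1] < v[i]
        if left_lower and right_lower and v[i] > 0:
            peaks.append(i)
        i = j + 1
    return np.array(peaks, dtype=np.int64)


def call_peaks(track: BinnedTrack, size_class: int = 150) -> pd.DataFrame:
    """Local-maximum peak calls on a smoothed track.

    Returns a table ``(chrom, bin, position, position_refined, height)``.
    ``position`` is the peak bin's centre in base coordinates;
    ``position_refined`` adds sub-bin precision from the vertex of the
    parabola through the peak bin and its two neighbours (interior peaks
    only; terminal peaks keep the bin centre).
    """
    rows = []
    bw = track.bin_width
    for chrom, v in track.values.items():
        for i in local_maxima(v):
            center = i * bw + bw / 2.0
            refined = center
            if 0 < i < len(v) - 1:
                denom = v[i - 1] - 2 * v[i] + v[i + 1]
                if denom < 0:
                    delta = 0.5 * (v[i - 1] - v[i + 1]) / denom
                    refined = center + delta * bw
            rows.append((chrom, int(i), center, refined, float(v[i])))
    return pd.DataFrame(
        rows, columns=["chrom", "bin", "position", "position_refined", "height"]
    )
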