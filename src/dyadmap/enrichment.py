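"""Input-normalized ChIP enrichment, occupancy and difference tracks.

Tag counts are binned, corrected for library size and probe length
(reads per million per kilobase of probe), and expressed relative to an
input-DNA library either as a log2 ratio or as linear occupancy.
Genotype comparisons subtract one track from another; per-feature-class
summaries report five-number box statistics of mean enrichment.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .model import BinnedTrack, FeatureInterval

logger = logging.getLogger(__name__)


def bin_tags(
    tags: pd.DataFrame,
    bin_width: int = 10,
    chrom_lengths: dict[str, int] | None = None,
) -> BinnedTrack:
    """Count tag 5' positions per bin; totals are conserved exactly."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    values: dict[str, np.ndarray] = {}
    if chrom_lengths:
        for c, L in chrom_lengths.items():
            values[c] = np.zeros(int(np.ceil(L / bin_width)))
    for chrom, sub in tags.groupby("chrom", sort=True):
        idx = (sub["pos5"].to_numpy() // bin_width).astype(np.int64)
        if chrom in values:
            idx = np.clip(idx, 0, len(values[chrom]) - 1)
        else:
            values[chrom] = np.zeros(int(idx.max()) + 1 if len(idx) else 0)
        np.add.at(values[chrom], idx, 1.0)
    return BinnedTrack(bin_width=bin_width, values=values, semantics="frequency")


def normalize_track(track: BinnedTrack, total_count: float, probe_length: float | None = None) -> BinnedTrack:
    """Correct raw bin counts for library size and probe length.

    value <- raw x (1e6 / total_count) x (1e3 / probe_length): reads per
    million per kilobase of probe.  ``probe_length`` defaults to the
    track's bin width.
    """
    if total_count <= 0:
        raise ValueError("total_count must be positive")
    probe = track.bin_width if probe_length is None else probe_length
    if probe <= 0:
        raise ValueError("probe_length must be positive")
    scale = (1e6 / total_count) * (1e3 / probe)
    out = {c: v * scale for c, v in track.values.items()}
    return track.copy_with(out, semantics="normalized")


def log2_enrichment(
    chip: BinnedTrack, input_track: BinnedTrack, pseudocount: float = 0.5
) -> BinnedTrack:
    """Per-bin ``log2((chip + pc) / (input + pc))`` on normalized tracks.

    Bins where both numerator and denominator are zero with a zero
    pseudocount are emitted as ``nan`` with a logged count.
    """
    if not chip.same_binning(input_track):
        raise ValueError("chip and input tracks must share binning")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    out = {}
    n_missing = 0
    for c in chip.values:
        num = chip.values[c] + pseudocount
        den = input_track.values[c] + pseudocount
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.log2(num / den)
        bad = ~np.isfinite(r)
        n_missing += int(bad.sum())
        r[bad] = np.nan
        out[c] = r
    if n_missing:
        logger.info("log2_enrichment: %d bins undefined (zero input)", n_missing)
    return chip.copy_with(out, semantics="log2-enrichment")


def linear_occupancy(
    chip: BinnedTrack, input_track: BinnedTrack, pseudocount: float = 0.5
) -> BinnedTrack:
    """Per-bin linear ratio of normalized ChIP to input."""
    if not chip.same_binning(input_track):
        raise ValueError("chip and input tracks must share binning")
    out = {}
    n_missing = 0
    for c in chip.values:
        num = chip.values[c] + pseudocount
        den = input_track.values[c] + pseudocount
        with np.errstate(divide="ignore", invalid="ignore"):
            r = num / den
        bad = ~np.isfinite(r)
        n_missing += int(bad.sum())
        r[bad] = np.nan
        out[c] = r
    if n_missing:
        logger.info("linear_occupancy: %d bins undefined (zero input)", n_missing)
    return chip.copy_with(out, semantics="linear-occupancy")


def difference_track(a: BinnedTrack, b: BinnedTrack) -> BinnedTrack:
    """Per-bin ``a - b`` (e.g. mutant minus wild type)."""
    if not a.same_binning(b):
        raise ValueError("tracks must share binning to be subtracted")
    if a.semantics != b.semantics:
        raise ValueError(
            f"value semantics differ: {a.semantics!r} vs {b.semantics!r}"
        )
    out = {c: a.values[c] - b.values[c] for c in a.values}
    return a.copy_with(out, semantics="difference")


def feature_mean(track: BinnedTrack, feature: FeatureInterval) -> float:
    """Mean track value over a feature (bins overlapping the interval)."""
    if feature.chrom not in track.values:
        return float("nan")
    v = track.values[feature.chrom]
    bw = track.bin_width
    lo = feature.start // bw
    hi = int(np.ceil(feature.end / bw))
    window = v[max(lo, 0):min(hi, len(v))]
    return float(np.nanmean(window)) if len(window) else float("nan")


def feature_box_stats(
    track: BinnedTrack, features: list[FeatureInterval]
) -> pd.DataFrame:
    """Five-number summary of per-feature mean enrichment for each class.

    Each feature contributes its mean bin value; quartiles use the
    linear-interpolation convention.  Classes with no usable feature are
    omitted with a warning.
    """
    by_class: dict[str, list[float]] = {}
    for f in features:
        m = feature_mean(track, f)
        if np.isfinite(m):
            by_class.setdefault(f.feature_class, []).append(m)
    rows = []
    for cls, means in sorted(by_class.items()):
        arr = np.array(means)
        rows.append(
            {
                "feature_class": cls,
                "n": len(arr),
                "min": arr.min(),
                "q1": np.percentile(arr, 25),
                "median": np.percentile(arr, 50),
                "q3": np.percentile(arr, 75),
                "max": arr.max(),
            }
        )
    seen = {f.feature_class for f in features}
    for cls in sorted(seen - set(by_class)):
        logger.warning("feature class %s has no usable features; omitted", cls)
    return pd.DataFrame(rows)
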