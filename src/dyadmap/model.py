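"""Core domain types shared across the pipeline.

Coordinates are 0-based, half-open everywhere inside the package;
conversions to 1-based conventions happen only at format boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

#: Canonical column order for a paired-end alignment table.
PAIR_COLUMNS = ("chrom", "left5", "isize")

#: Canonical column order for a single-end tag table.
TAG_COLUMNS = ("chrom", "pos5", "strand")


class AlignedPair(NamedTuple):
    """One properly-oriented paired-end alignment.

    ``left5`` is the 0-based leftmost 5' coordinate; ``isize`` is the
    end-to-end template length in bases (always positive).
    """

    chrom: str
    left5: int
    isize: int


class Tag(NamedTuple):
    """A single-end sequence tag: 0-based 5' coordinate plus strand."""

    chrom: str
    pos5: int
    strand: str


@dataclass(frozen=True)
class FeatureInterval:
    """A genomic feature with a class label (CEN, tRNA, ORF, ...)."""

    chrom: str
    start: int
    end: int
    feature_class: str
    strand: str = "."
    id: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"feature {self.id or self.feature_class}: start {self.start} "
                f"must be < end {self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def pairs_to_frame(pairs: Iterable[AlignedPair]) -> pd.DataFrame:
    """Materialise a pair stream as the canonical three-column table."""
    df = pd.DataFrame(list(pairs), columns=list(PAIR_COLUMNS))
    df["left5"] = df["left5"].astype(np.int64)
    df["isize"] = df["isize"].astype(np.int64)
    return df


def tags_to_frame(tags: Iterable[Tag]) -> pd.DataFrame:
    df = pd.DataFrame(list(tags), columns=list(TAG_COLUMNS))
    df["pos5"] = df["pos5"].astype(np.int64)
    return df


@dataclass
class BinnedTrack:
    """Per-chromosome fixed-width binned signal.

    Bin ``i`` covers ``[i * bin_width, (i + 1) * bin_width)`` with the origin
    fixed at coordinate 0.  ``semantics`` labels what the values mean
    (``frequency``, ``log2-enrichment``, ``linear-occupancy``,
    ``difference``, ...).  Missing values are ``nan``.
    """

    bin_width: int
    values: dict[str, np.ndarray] = field(default_factory=dict)
    semantics: str = "frequency"

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError(f"bin_width must be positive, got {self.bin_width}")
        self.values = {c: np.asarray(v, dtype=float) for c, v in self.values.items()}

    @property
    def chromosomes(self) -> list[str]:
        return list(self.values)

    def n_bins(self, chrom: str) -> int:
        return len(self.values[chrom])

    def total(self) -> float:
        return float(sum(np.nansum(v) for v in self.values.values()))

    def copy_with(self, values: dict[str, np.ndarray], semantics: str | None = None) -> "BinnedTrack":
        return BinnedTrack(
            bin_width=self.bin_width,
            values=values,
            semantics=semantics if semantics is not None else self.semantics,
        )

    def same_binning(self, other: "BinnedTrack") -> bool:
        if self.bin_width != other.bin_width:
            return False
        if set(self.values) != set(other.values):
            return False
        return all(len(self.values[c]) == len(other.values[c]) for c in self.values)

    @classmethod
    def zeros(cls, chrom_lengths: dict[str, int], bin_width: int, semantics: str = "frequency") -> "BinnedTrack":
        vals = {
            c: np.zeros(int(np.ceil(length / bin_width)))
            for c, length in chrom_lengths.items()
        }
        return cls(bin_width=bin_width, values=vals, semantics=semantics)


@dataclass(frozen=True)
class ParticlePeak:
    """A called chromatin-particle dyad peak on a smoothed track.

    ``position`` is the center of the peak bin in base coordinates;
    ``height`` the smoothed dyad frequency; ``size_class`` the nominal
    particle size (bases) of the track the peak was called on.
    """

    chrom: str
    position: float
    height: float
    size_class: int = 150

    def __post_init__(self) -> None:
        if self.height <= 0:
            raise ValueError("peak height must be positive")


class GeneModel:
    """An ORF plus optional UTRs and the contexts derived from them.

    ``tss``/``tts`` are derived from the ORF boundary and the UTR length
    (transcript start / termination site).  ``igr5``/``igr3`` are the
    intergenic intervals flanking the transcript, assigned downstream.
    """

    __slots__ = (
        "id", "chrom", "strand", "orf_start", "orf_end",
        "utr5_len", "utr3_len", "igr5", "igr3",
        "expression_category", "promoter_context", "terminator_context",
        "terminal_flag",
    )

    def __init__(
        self,
        id: str,
        chrom: str,
        strand: str,
        orf_start: int,
        orf_end: int,
        utr5_len: int | None = None,
        utr3_len: int | None = None,
    ) -> None:
        if strand not in ("+", "-"):
            raise ValueError(f"gene {id}: strand must be '+' or '-', got {strand!r}")
        if orf_start >= orf_end:
            raise ValueError(f"gene {id}: orf_start must be < orf_end")
        self.id = id
        self.chrom = chrom
        self.strand = strand
        self.orf_start = int(orf_start)
        self.orf_end = int(orf_end)
        self.utr5_len = None if utr5_len is None else int(utr5_len)
        self.utr3_len = None if utr3_len is None else int(utr3_len)
        self.igr5: tuple[int, int] | None = None
        self.igr3: tuple[int, int] | None = None
        self.expression_category: str | None = None
        self.promoter_context: str | None = None
        self.terminator_context: str | None = None
        self.terminal_flag: bool = False

    @property
    def length(self) -> int:
        return self.orf_end - self.orf_start

    @property
    def tss(self) -> int:
        """Transcript start: ORF start pushed outward by the 5' UTR."""
        u5 = self.utr5_len or 0
        return self.orf_start - u5 if self.strand == "+" else self.orf_end + u5

    @property
    def tts(self) -> int:
        """Transcript end: ORF end pushed outward by the 3' UTR."""
        u3 = self.utr3_len or 0
        return self.orf_end + u3 if self.strand == "+" else self.orf_start - u3

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"GeneModel({self.id}, {self.chrom}:{self.orf_start}-{self.orf_end}"
            f"{self.strand})"
        )


@dataclass(frozen=True)
class OverlapResult:
    """Hypergeometric overlap between two gene lists drawn from a universe."""

    universe_size: int
    list_a_size: int
    list_b_size: int
    overlap: int
    p_value: float
    direction: str = "over"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value out of [0, 1]")


@dataclass
class FlankMatch:
    """A wild-type flanking peak paired (or not) with a mutant peak."""

    wt_peak: ParticlePeak
    mut_peak: ParticlePeak | None
    shift: float | None  # mutant position - wt position, bases


@dataclass
class CenChromatinReport:
    """Per-centromere chromatin comparison between two genotypes."""

    cen_id: str
    chrom: str
    core_wt: ParticlePeak | None
    core_mut: ParticlePeak | None
    core_height_ratio: float | None
    flank_matches: list[FlankMatch]
    mut_only_peaks: list[ParticlePeak]
    calls: list[str]

    @property
    def changed(self) -> bool:
        return any(c != "no-change" for c in self.calls)
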