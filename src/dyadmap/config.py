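"""Simulation configuration: the statistical conditions the pipeline assumes.

The defaults describe a desk-scale mini-genome that preserves the features
the analysis depends on: positioned nucleosome arrays with promoter NDRs, a
~125 bp centromeric core particle per chromosome, a tri-modal insert-size
mixture (mono/di/tri-nucleosome at ~150/300/450 bp), feature-class-specific
ChIP enrichment, genotype perturbations around centromeres, and a subset of
>=1.5-fold differentially expressed genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


class ConfigurationError(ValueError):
    """Raised when a SimConfig field violates its contract."""


GENOTYPES = ("wt", "mutant")
CHIP_TARGETS = ("fun30", "htz1", "h3")


def _default_chip_enrichment() -> dict[str, float]:
    # Fold enrichment of the remodeler-like ChIP target per feature class.
    # Centromeres carry the greatest fold; structural RNA genes and
    # replication/repeat elements intermediate; 3' intergenic regions mild.
    return {
        "CEN": 8.0,
        "tRNA": 4.0,
        "snoRNA": 3.0,
        "snRNA": 3.0,
        "ARS": 2.5,
        "LTR": 2.0,
        "telomere": 2.0,
        "igr3": 2.0,
    }


@dataclass
class SimConfig:
    """All tunable knobs of the synthetic mini-genome and its read sets."""

    n_chromosomes: int = 2
    chrom_length: int = 60_000
    n_genes_per_chrom: int = 24
    nucleosome_spacing: int = 165
    ndr_width: int = 140
    cen_core_width: int = 125
    cen_core_occupancy: float = 1.0
    isize_means: tuple[int, ...] = (150, 300, 450)
    isize_sd: float = 15.0
    isize_class_weights: tuple[float, ...] = (0.6, 0.25, 0.15)
    pairs_per_nucleosome: int = 195
    dyad_jitter: int = 10
    chip_enrichment: dict[str, float] = field(default_factory=_default_chip_enrichment)
    chip_tags: int = 300_000
    input_tags: int = 300_000
    # Promoter H2A.Z-like target: enriched over 5' IGRs in wild type; in the
    # mutant the promoter pool is redistributed into gene bodies.
    htz1_promoter_fold: float = 6.0
    htz1_mutant_promoter_fold: float = 1.5
    htz1_mutant_body_fold: float = 3.0
    # Genotype perturbations around centromeres.
    mutant_flank_shift: int = 30
    mutant_core_height_factor: float = 0.5
    n_flank_nucleosomes: int = 2
    n_perturbed_cens: int | None = None
    # Expression simulation.
    de_fraction: float = 0.1
    de_log2_ratio_range: tuple[float, float] = (0.8074, 1.585)  # |log2 r| in [~1.75x, 3x]
    mean_expression: float = 1000.0
    expression_overdispersion: float = 0.002
    low_expression_ratio_boost: float = 0.0
    utr_missing_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive = (
            "n_chromosomes", "chrom_length", "n_genes_per_chrom",
            "nucleosome_spacing", "ndr_width", "cen_core_width",
            "pairs_per_nucleosome", "chip_tags", "input_tags",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive, got {getattr(self, name)}")
        if abs(sum(self.isize_class_weights) - 1.0) > 1e-9:
            raise ConfigurationError(
                "isize_class_weights must sum to 1 within 1e-9, got "
                f"{sum(self.isize_class_weights)!r}"
            )
        if any(w < 0 for w in self.isize_class_weights):
            raise ConfigurationError("isize_class_weights must be non-negative")
        if len(self.isize_class_weights) != len(self.isize_means):
            raise ConfigurationError(
                "isize_class_weights and isize_means must have equal length"
            )
        if self.cen_core_width >= 2 * self.nucleosome_spacing:
            raise ConfigurationError(
                "cen_core_width must be < 2 x nucleosome_spacing"
            )
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ConfigurationError("de_fraction must lie in [0, 1]")
        if not 0.0 <= self.utr_missing_fraction <= 1.0:
            raise ConfigurationError("utr_missing_fraction must lie in [0, 1]")
        if self.dyad_jitter < 0:
            raise ConfigurationError("dyad_jitter must be >= 0")
        if self.isize_sd < 0:
            raise ConfigurationError("isize_sd must be >= 0")

    # -- (de)serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        for key in ("isize_means", "isize_class_weights", "de_log2_ratio_range"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        unknown = set(d) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigurationError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**d)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
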