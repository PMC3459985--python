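"""Synthetic mini-genome generator with ground truth for recovery tests.

The generator builds, for two genotypes (``wt`` and ``mutant``), everything
the downstream pipeline consumes: a random genome with gene and feature
annotation, a truth table of positioned nucleosome dyads (regular arrays
with promoter nucleosome-depleted regions and one ~125 bp centromeric core
particle per chromosome), paired-end MNase alignments whose insert sizes
follow a mono/di/tri-nucleosome mixture, ChIP and input tag streams with
feature-class-specific enrichment, and per-gene expression counts with a
planted subset of >=1.5-fold changed genes.

All randomness flows from the single ``SimConfig.seed``; every simulated
stream draws from its own deterministic sub-stream keyed by
``(purpose, genotype)`` so adding one simulation never perturbs another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import assign_igrs, classify_orientation
from .config import GENOTYPES, CHIP_TARGETS, ConfigurationError, SimConfig
from .model import FeatureInterval, GeneModel

_ROMAN = [
    "I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X",
    "XI", "XII", "XIII", "XIV", "XV", "XVI", "XVII", "XVIII", "XIX", "XX",
]

TELOMERE_LEN = 500
#: H3-like target folds (coding-biased occupancy, mutant gains at IGRs).
H3_FOLDS = {
    "wt": {"orf": 1.5, "igr5": 0.5, "igr3": 0.5},
    "mutant": {"orf": 1.5, "igr5": 0.9, "igr3": 0.9},
}

NONCODING_CYCLE = ("tRNA", "snoRNA", "snRNA", "ARS", "LTR")
NONCODING_LEN = {"tRNA": 75, "snoRNA": 100, "snRNA": 150, "ARS": 200, "LTR": 300}


def chrom_name(i: int) -> str:
    return "chr" + _ROMAN[i]


def substream(seed: int, *keys) -> np.random.Generator:
    """Deterministic per-purpose random stream derived from the global seed."""
    tail = [zlib.crc32(str(k).encode()) for k in keys]
    return np.random.default_rng([int(seed)] + tail)


@dataclass
class TruthSet:
    """Ground truth the simulator emitted, for recovery scoring.

    ``dyads[genotype]`` is a table with columns
    ``chrom, position, occupancy, is_core, flank_side, cen_id`` where
    ``flank_side`` is ``L``/``R`` for centromere-flanking nucleosomes and
    empty otherwise.
    """

    dyads: dict[str, pd.DataFrame]
    cen_intervals: list[FeatureInterval]
    enrichment_profile: dict[str, float] = field(default_factory=dict)
    de_genes: pd.DataFrame | None = None

    def core_dyads(self, genotype: str) -> pd.DataFrame:
        d = self.dyads[genotype]
        return d[d["is_core"]]


@dataclass
class GenomeBundle:
    """A simulated genome plus annotation and truth, ready for the pipeline."""

    config: SimConfig
    chrom_lengths: dict[str, int]
    sequences: dict[str, str]
    genes: list[GeneModel]
    features: list[FeatureInterval]
    truth: TruthSet

    @property
    def cen_intervals(self) -> list[FeatureInterval]:
        return self.truth.cen_intervals

    def genome_length(self) -> int:
        return sum(self.chrom_lengths.values())


# ---------------------------------------------------------------------------
# genome / annotation
# ---------------------------------------------------------------------------

def _place_chromosome(
    config: SimConfig, chrom: str, rng: np.random.Generator, gene_counter: int
) -> tuple[list[GeneModel], list[FeatureInterval], FeatureInterval]:
    """Lay out genes, noncoding features, telomeres and one centromere."""
    L = config.chrom_length
    cen_mid = L // 2
    cen = FeatureInterval(
        chrom,
        cen_mid - config.cen_core_width // 2,
        cen_mid - config.cen_core_width // 2 + config.cen_core_width,
        "CEN",
        ".",
        f"CEN_{chrom}",
    )
    # Keep a gene-free buffer around the centromere so its flanking
    # nucleosomes are not confounded with promoter NDRs.
    cen_zone = (cen.start - 1200, cen.end + 1200)

    features: list[FeatureInterval] = [
        FeatureInterval(chrom, 0, TELOMERE_LEN, "telomere", ".", f"TEL_{chrom}_L"),
        FeatureInterval(chrom, L - TELOMERE_LEN, L, "telomere", ".", f"TEL_{chrom}_R"),
    ]
    genes: list[GeneModel] = []

    cursor = TELOMERE_LEN + 150
    noncoding_idx = 0
    arm_end = cen_zone[0]
    while len(genes) < config.n_genes_per_chrom:
        gap = int(rng.integers(250, 700))
        # occasionally drop a noncoding element into the gap
        if gap >= 420 and rng.random() < 0.4:
            cls = NONCODING_CYCLE[noncoding_idx % len(NONCODING_CYCLE)]
            noncoding_idx += 1
            flen = NONCODING_LEN[cls]
            fstart = cursor + 60
            strand = "+" if rng.random() < 0.5 else "-"
            if fstart + flen + 60 < min(cursor + gap, arm_end):
                features.append(
                    FeatureInterval(
                        chrom, fstart, fstart + flen, cls, strand,
                        f"{cls}_{chrom}_{noncoding_idx}",
                    )
                )
        cursor += gap
        glen = int(rng.integers(600, 2000))
        utr5 = int(rng.integers(30, 120))
        utr3 = int(rng.integers(50, 200))
        if cursor + utr5 + glen + utr3 > arm_end:
            if arm_end == cen_zone[0]:
                # jump over the centromere to the right arm
                cursor = cen_zone[1] + 150
                arm_end = L - TELOMERE_LEN - 150
                continue
            break  # chromosome full
        strand = "+" if rng.random() < 0.5 else "-"
        has_utr = rng.random() >= config.utr_missing_fraction
        gid = f"gene{gene_counter + len(genes) + 1:04d}"
        orf_start = cursor + utr5
        genes.append(
            GeneModel(
                gid, chrom, strand, orf_start, orf_start + glen,
                utr5_len=utr5 if has_utr else None,
                utr3_len=utr3 if has_utr else None,
            )
        )
        cursor = orf_start + glen + utr3
    return genes, features, cen


def _truth_dyads_wt(
    config: SimConfig,
    chrom_lengths: dict[str, int],
    genes: list[GeneModel],
    cens: dict[str, FeatureInterval],
    rng: np.random.Generator,
) -> pd.DataFrame:
    rows = []
    spacing = config.nucleosome_spacing
    for ci, (chrom, L) in enumerate(chrom_lengths.items()):
        phase = int(rng.integers(0, spacing))
        grid = np.arange(phase, L, spacing, dtype=np.int64)
        keep = np.ones(len(grid), dtype=bool)
        # promoter nucleosome-depleted regions
        for g in genes:
            if g.chrom != chrom:
                continue
            if g.strand == "+":
                lo, hi = g.tss - config.ndr_width, g.tss
            else:
                lo, hi = g.tss, g.tss + config.ndr_width
            keep &= ~((grid >= lo) & (grid < hi))
        cen = cens[chrom]
        # clear the regular array across the centromere, then place the core
        lo = cen.start - spacing // 2
        hi = cen.end + spacing // 2
        keep &= ~((grid >= lo) & (grid < hi))
        grid = grid[keep]
        left = grid[grid < cen.start]
        right = grid[grid >= cen.end]
        nf = config.n_flank_nucleosomes
        flank_side = {}
        for p in left[-nf:]:
            flank_side[int(p)] = "L"
        for p in right[:nf]:
            flank_side[int(p)] = "R"
        for p in grid:
            rows.append(
                (chrom, int(p), 1.0, False, flank_side.get(int(p), ""),
                 cen.id if int(p) in flank_side else "")
            )
        rows.append((chrom, cen.midpoint, config.cen_core_occupancy, True, "", cen.id))
    df = pd.DataFrame(
        rows, columns=["chrom", "position", "occupancy", "is_core", "flank_side", "cen_id"]
    )
    return df.sort_values(["chrom", "position"], kind="mergesort").reset_index(drop=True)


def _perturb_mutant(config: SimConfig, wt: pd.DataFrame, cens: list[FeatureInterval]) -> pd.DataFrame:
    mut = wt.copy()
    if config.n_perturbed_cens is None:
        perturbed = {c.id for c in cens}
    else:
        perturbed = {c.id for c in cens[: config.n_perturbed_cens]}
    in_perturbed = mut["cen_id"].isin(perturbed)
    shift = config.mutant_flank_shift
    if shift:
        mut.loc[in_perturbed & (mut["flank_side"] == "L"), "position"] -= shift
        mut.loc[in_perturbed & (mut["flank_side"] == "R"), "position"] += shift
    if config.mutant_core_height_factor != 1.0:
        mut.loc[in_perturbed & mut["is_core"], "occupancy"] *= config.mutant_core_height_factor
    return mut


def make_genome(config: SimConfig) -> GenomeBundle:
    """Build the mini-genome, its annotation and the two-genotype truth set.

    Raises :class:`ConfigurationError` for invalid configurations (the
    config validates on construction, so a hand-mutated config is
    re-validated here).
    """
    config.validate()
    rng = substream(config.seed, "genome")
    chrom_lengths = {chrom_name(i): config.chrom_length for i in range(config.n_chromosomes)}

    genes: list[GeneModel] = []
    features: list[FeatureInterval] = []
    cens: dict[str, FeatureInterval] = {}
    for chrom in chrom_lengths:
        g, f, cen = _place_chromosome(config, chrom, rng, gene_counter=len(genes))
        genes.extend(g)
        features.extend(f)
        features.append(cen)
        cens[chrom] = cen

    # ORFs as features too, for the per-class box statistics
    for g in genes:
        features.append(
            FeatureInterval(g.chrom, g.orf_start, g.orf_end, "ORF", g.strand, g.id)
        )

    assign_igrs(genes)
    classify_orientation(genes, features)

    sequences = {
        chrom: "".join(rng.choice(list("ACGT"), size=L))
        for chrom, L in chrom_lengths.items()
    }

    wt = _truth_dyads_wt(config, chrom_lengths, genes, cens, rng)
    mut = _perturb_mutant(config, wt, list(cens.values()))
    truth = TruthSet(
        dyads={"wt": wt, "mutant": mut},
        cen_intervals=list(cens.values()),
        enrichment_profile=dict(config.chip_enrichment),
    )
    return GenomeBundle(config, chrom_lengths, sequences, genes, features, truth)


# ---------------------------------------------------------------------------
# paired-end MNase alignments
# ---------------------------------------------------------------------------

def _truncnorm_int(rng, mean, sd, size):
    """Normal draws truncated to mean +/- 3 sd, rounded to integer bases."""
    if sd == 0:
        return np.full(size, int(round(mean)), dtype=np.int64)
    x = rng.normal(mean, sd, size=size)
    lo, hi = mean - 3 * sd, mean + 3 * sd
    bad = (x < lo) | (x > hi)
    while bad.any():
        x[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (x < lo) | (x > hi)
    return np.rint(x).astype(np.int64)


def simulate_mnase_pairs(
    bundle: GenomeBundle, genotype: str, config: SimConfig | None = None
) -> pd.DataFrame:
    """Sample paired-end MNase alignments from the truth dyads of a genotype.

    Each truth dyad emits ``Poisson(pairs_per_nucleosome x occupancy)``
    pairs.  A pair's size class is drawn from the configured mixture;
    mono- and tri-nucleosome fragments centre on the dyad itself (the
    centre of three consecutive nucleosomes is the middle one), while
    di-nucleosome fragments centre on the midpoint between the dyad and
    its neighbour.  Centres receive uniform jitter of up to
    ``dyad_jitter`` bases; insert sizes are truncated-normal around the
    class mean.  Returns the canonical ``(chrom, left5, isize)`` table.
    """
    config = config or bundle.config
    if genotype not in GENOTYPES:
        raise ValueError(f"unknown genotype {genotype!r}; expected one of {GENOTYPES}")
    rng = substream(config.seed, "mnase", genotype)
    dyads = bundle.truth.dyads[genotype]

    frames = []
    for chrom, sub in dyads.groupby("chrom", sort=True):
        pos = sub["position"].to_numpy()
        occ = sub["occupancy"].to_numpy()
        order = np.argsort(pos, kind="mergesort")
        pos, occ = pos[order], occ[order]
        counts = rng.poisson(config.pairs_per_nucleosome * occ)
        n = int(counts.sum())
        if n == 0:
            continue
        dyad_of_pair = np.repeat(pos, counts)
        core_of_pair = np.repeat(sub["is_core"].to_numpy()[order], counts)
        # midpoint with the following dyad (the last dyad uses its predecessor)
        if len(pos) > 1:
            nxt = np.empty_like(pos)
            nxt[:-1] = pos[1:]
            nxt[-1] = pos[-2]
        else:
            nxt = pos.copy()
        di_center_of_pair = np.repeat((pos + nxt) // 2, counts)

        cls = rng.choice(len(config.isize_means), size=n, p=list(config.isize_class_weights))
        # an isolated core particle has no adjacent nucleosome, so it cannot
        # yield di-/tri-nucleosome protection products: core pairs are mono
        cls[core_of_pair] = 0
        centers = np.where(cls == 1, di_center_of_pair, dyad_of_pair)
        if config.dyad_jitter > 0:
            centers = centers + rng.integers(
                -config.dyad_jitter, config.dyad_jitter + 1, size=n
            )
        isize = np.empty(n, dtype=np.int64)
        for k, mean in enumerate(config.isize_means):
            mask = cls == k
            isize[mask] = _truncnorm_int(rng, mean, config.isize_sd, int(mask.sum()))
        left5 = centers - isize // 2
        L = bundle.chrom_lengths[chrom]
        ok = (left5 >= 0) & (left5 + isize <= L) & (isize > 0)
        frames.append(
            pd.DataFrame({"chrom": chrom, "left5": left5[ok], "isize": isize[ok]})
        )
    if not frames:
        return pd.DataFrame({"chrom": pd.Series(dtype=str),
                             "left5": pd.Series(dtype=np.int64),
                             "isize": pd.Series(dtype=np.int64)})
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# ChIP / input tags
# ---------------------------------------------------------------------------

def _depress_background(prof: dict[str, np.ndarray], floor: float = 0.05) -> None:
    """Lower unpainted background so configured folds are ChIP:input ratios.

    ChIP sequencing is compositional: enriching some loci depresses the
    rest of the genome.  Setting the background so the profile mean is 1
    makes the observed input-normalized ratio over a feature equal its
    configured fold.  When enrichment covers too much of the genome for
    that to be feasible the background is floored and observed ratios
    compress, as they would in a real library.
    """
    total = sum(len(v) for v in prof.values())
    masks = {c: v == 1.0 for c, v in prof.items()}
    n_bg = sum(int(m.sum()) for m in masks.values())
    if n_bg == 0 or n_bg == total:
        return
    painted_sum = sum(float(v[~m].sum()) for v, m in zip(prof.values(), masks.values()))
    b = max((total - painted_sum) / n_bg, floor)
    for c in prof:
        prof[c][masks[c]] = b


def _fold_profile(
    bundle: GenomeBundle, config: SimConfig, target: str, genotype: str
) -> dict[str, np.ndarray]:
    """Per-base relative ChIP density (fold over the uniform input)."""
    prof = {c: np.ones(L) for c, L in bundle.chrom_lengths.items()}

    def paint(chrom, start, end, fold):
        L = len(prof[chrom])
        prof[chrom][max(0, start):min(L, end)] = fold

    if target == "fun30":
        folds = config.chip_enrichment
        present = {f.feature_class for f in bundle.features} - {"ORF"}
        missing = present - set(folds)
        if missing:
            raise ConfigurationError(
                f"chip_enrichment lacks a fold for feature class(es) {sorted(missing)}"
            )
        for f in bundle.features:
            if f.feature_class == "ORF":
                continue
            paint(f.chrom, f.start, f.end, folds[f.feature_class])
        if "igr3" in folds:
            for g in bundle.genes:
                if g.igr3 is not None and g.igr3[0] < g.igr3[1]:
                    paint(g.chrom, g.igr3[0], g.igr3[1], folds["igr3"])
    elif target == "htz1":
        if genotype == "wt":
            for g in bundle.genes:
                if g.igr5 is not None and g.igr5[0] < g.igr5[1]:
                    paint(g.chrom, g.igr5[0], g.igr5[1], config.htz1_promoter_fold)
        else:
            for g in bundle.genes:
                paint(g.chrom, g.orf_start, g.orf_end, config.htz1_mutant_body_fold)
            for g in bundle.genes:
                if g.igr5 is not None and g.igr5[0] < g.igr5[1]:
                    paint(g.chrom, g.igr5[0], g.igr5[1], config.htz1_mutant_promoter_fold)
    elif target == "h3":
        folds = H3_FOLDS[genotype]
        for g in bundle.genes:
            paint(g.chrom, g.orf_start, g.orf_end, folds["orf"])
        for g in bundle.genes:
            if g.igr5 is not None and g.igr5[0] < g.igr5[1]:
                paint(g.chrom, g.igr5[0], g.igr5[1], folds["igr5"])
            if g.igr3 is not None and g.igr3[0] < g.igr3[1]:
                paint(g.chrom, g.igr3[0], g.igr3[1], folds["igr3"])
    else:
        raise ValueError(f"unknown ChIP target {target!r}; expected one of {CHIP_TARGETS}")
    _depress_background(prof)
    return prof


def _sample_tags(rng, prof: dict[str, np.ndarray], n: int) -> pd.DataFrame:
    chroms = list(prof)
    lengths = np.array([len(prof[c]) for c in chroms])
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    flat = np.concatenate([prof[c] for c in chroms])
    p = flat / flat.sum()
    idx = rng.choice(len(flat), size=n, p=p)
    strand = np.where(rng.random(n) < 0.5, "+", "-")
    which = np.searchsorted(offsets, idx, side="right") - 1
    pos = idx - offsets[which]
    return pd.DataFrame(
        {"chrom": np.array(chroms, dtype=object)[which], "pos5": pos.astype(np.int64),
         "strand": strand}
    )


def simulate_chip_tags(
    bundle: GenomeBundle,
    target: str = "fun30",
    genotype: str = "wt",
    config: SimConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample a (ChIP, input) tag-stream pair for one target and genotype.

    Input tags are uniform over the genome; ChIP tags are drawn with
    density proportional to the feature-class fold profile.  For the
    H2A.Z-like ``htz1`` target the mutant genotype redistributes the
    promoter pool into gene bodies.
    """
    config = config or bundle.config
    if genotype not in GENOTYPES:
        raise ValueError(f"unknown genotype {genotype!r}")
    prof = _fold_profile(bundle, config, target, genotype)
    chip = _sample_tags(
        substream(config.seed, "chip", target, genotype), prof, config.chip_tags
    )
    flat_input = {c: np.ones(L) for c, L in bundle.chrom_lengths.items()}
    inp = _sample_tags(
        substream(config.seed, "input", target, genotype), flat_input, config.input_tags
    )
    return chip, inp


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(bundle: GenomeBundle, config: SimConfig | None = None) -> pd.DataFrame:
    """Per-gene counts for both genotypes with a planted fold-change subset.

    Baseline abundance is log-normal around ``mean_expression``; counts are
    gamma-Poisson with the configured overdispersion.  Exactly
    ``round(de_fraction x n_genes)`` genes receive a true mutant/wt ratio
    whose magnitude lies in ``2**de_log2_ratio_range`` (up and down split
    evenly); all other genes have a true ratio of 1 unless
    ``low_expression_ratio_boost`` inflates weakly expressed genes.

    Returns a table with columns ``gene_id, wt_count, mut_count,
    base_mean, true_ratio, is_de`` and records the planted subset on
    ``bundle.truth.de_genes``.
    """
    config = config or bundle.config
    rng = substream(config.seed, "expression")
    gene_ids = [g.id for g in bundle.genes]
    n = len(gene_ids)
    base = rng.lognormal(mean=np.log(config.mean_expression), sigma=1.0, size=n)

    n_de = int(round(config.de_fraction * n))
    de_idx = rng.choice(n, size=n_de, replace=False)
    true_ratio = np.ones(n)
    lo, hi = config.de_log2_ratio_range
    mag = rng.uniform(lo, hi, size=n_de)
    sign = np.where(np.arange(n_de) % 2 == 0, 1.0, -1.0)
    rng.shuffle(sign)
    true_ratio[de_idx] = 2.0 ** (sign * mag)

    if config.low_expression_ratio_boost > 0:
        q = np.argsort(np.argsort(base)) / max(n - 1, 1)
        boost = 1.0 + config.low_expression_ratio_boost * np.clip((1 / 3 - q) / (1 / 3), 0, None)
        true_ratio = true_ratio * boost

    def draw(mean):
        phi = config.expression_overdispersion
        if phi > 0:
            lam = rng.gamma(shape=1.0 / phi, scale=mean * phi)
        else:
            lam = mean
        return rng.poisson(lam)

    wt_count = draw(base)
    mut_count = draw(base * true_ratio)
    is_de = np.zeros(n, dtype=bool)
    is_de[de_idx] = True
    table = pd.DataFrame(
        {"gene_id": gene_ids, "wt_count": wt_count, "mut_count": mut_count,
         "base_mean": base, "true_ratio": true_ratio, "is_de": is_de}
    )
    bundle.truth.de_genes = table.loc[is_de, ["gene_id", "true_ratio"]].reset_index(drop=True)
    return table
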