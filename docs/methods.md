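# Methods

## Particle mapping model

The pipeline treats a paired-end MNase-seq template as the footprint of a
single chromatin particle and its centre as an estimate of the particle
dyad. Three assumptions follow:

* the template-length (`ISIZE`) distribution is a mixture over particle
  types, so a fractional size window around a nominal length (150 bp ± 20%
  for mono-nucleosomes) enriches for one type;
* the dyad estimate is `left5 + ⌊ISIZE/2⌋` — for odd template lengths the
  centre is rounded down, a fixed convention documented here because the
  choice is arbitrary at 1 bp scale and invisible at 15 bp bin scale;
* binning (15 bp default; 10 bp supported for higher-resolution traces)
  followed by a 3-bin moving average suppresses counting noise without
  fitting any positional model. No Gaussian fitting or deconvolution is
  performed; peaks are plain local maxima (strictly greater than both
  neighbours; a plateau reports its leftmost bin, so calls are
  deterministic under ties).

Smoothing at array ends shrinks to the available window (terminal bins
average two bins instead of three). This makes constant tracks exact fixed
points, at the cost of slightly underweighting terminal-bin mass relative
to zero-padding; interior mass is conserved.

Peak positions are reported both as bin centres and with sub-bin
refinement from the vertex of the parabola through the peak bin and its
neighbours. Refinement undoes the phase quantization of the bin grid
(up to 7.5 bp at 15 bp bins) when peak accuracy is measured; calls and
matching operate at bin resolution.

## ChIP enrichment tracks

Tag counts per bin are corrected for library size and probe length
(`raw × 10⁶/total × 10³/probe`: reads per million per kilobase of probe)
before any ratio is formed, so tracks from libraries of different depth
are directly comparable. Enrichment is `log2((chip+c)/(input+c))` with a
pseudocount `c = 0.5` normalized units; the pseudocount exists solely to
make zero-input bins finite and is small against typical normalized
values. Bins undefined at `c = 0` are emitted as NaN and counted in the
log. Linear occupancy uses the same machinery without the log; the two
agree exactly (`linear = 2^log2`) when `c = 0`.

Per-feature-class box statistics summarise the *mean* bin value over each
feature (the reduction had to be chosen; the mean is insensitive to
feature length under uniform enrichment), with quartiles by linear
interpolation (numpy default). Changing either convention shifts all
classes coherently and does not affect class rankings on well-separated
folds.

## Gene context

5'/3' intergenic regions (IGRs) are the annotated UTR plus a 150 b
outward extension; genes lacking UTR annotation fall back to the bare
150 b extension from the ORF boundary. IGRs are truncated at the nearest
neighbouring *ORF boundary* (not the midpoint between genes) and at
chromosome ends, which keeps IGRs strictly disjoint from all coding
sequence — the property the intergenic-vs-ORF contrasts rely on. The
cost is that two nearby genes share intergenic bases, double-counting
signal in dense regions.

Orientation classes come from the nearest neighbouring element on each
side, with stranded noncoding genes (tRNA/snoRNA/snRNA) counted as
neighbours: a head-to-head opposite-strand neighbour makes a promoter
*divergent*; a tail-to-tail neighbour makes a terminator *convergent*;
everything else is *tandem*. Chromosome-terminal sides are tandem with a
flag. Expression tiers split genes ranked by `log2(value + 1)` into three
contiguous groups whose sizes differ by at most one; rank ties break by
gene id so the partition is deterministic.

## Metagene profiles

Anchored profiles tile 25 bp probes across a window around the TSS or TTS
(defaults −1000..+2000 and −2000..+1000 respectively), read 5'→3' so
minus-strand genes are mirrored. Probe values are overlap-weighted means
of the underlying bins, which makes the extraction exact for any
probe/bin-width combination and exactly strand-symmetric. Windows
reaching outside a chromosome contribute missing values that are excluded
per offset, not zero-filled. The 95% confidence interval is the normal
approximation `mean ± 1.96·SE`; per-gene profile values are averages of
many bins, so the approximation is adequate at the stratum sizes used.

Scaled profiles resample the transcript body to 40 equal bins and attach
50 flank fragments of 25 bp on each side (1250 bp per flank — the
fragment size is fixed at `flank / n_fragments` so the flank arithmetic
is self-consistent). Occupancy windows can be normalized by their own
mean, placing "random" occupancy exactly at 1.

The expression-ratio curve sorts genes by wild-type expression and slides
a 150-gene window in 1-gene steps, reporting the mean per-gene
mutant/wild-type ratio (pseudocount 1 for silent genes) against the mean
wild-type expression of the window.

## Expression and overlap

Counts are normalized as `count × 10⁹ / (library_total × gene_length)`
(reads per kilobase per million). Fold-change lists use a plain cutoff:
ratio ≥ 1.5 up, ≤ 1/1.5 down, computed on pseudocounted normalized
values; no dispersion model is fitted, deliberately matching cutoff-based
designs. List overlaps are scored with the upper-tail hypergeometric
probability `P(X ≥ k)` (a point-probability option exists, since some
published analyses report `P(X = k)`); the universe defaults to the
annotated gene set.

## Centromere comparison

For each centromere a window of ±5 kb is cut from the smoothed
mono-nucleosome-class track of both genotypes. The core particle is the
highest local maximum inside the CEN interval ± one bin (leftmost on
ties). Flanking peaks are paired greedily, closest first, within a 150 bp
tolerance (about one nucleosome footprint); unpaired peaks are reported
as appeared/disappeared.

Two calls are made per centromere. A **flank shift** requires a matched
peak displaced by at least 2 bins (30 bp at default binning) — one bin of
apparent movement is within quantization noise. A **core accessibility
change** requires the mutant/wild-type ratio of *integrated core mass*
(summed smoothed frequency over CEN ± one bin) to exceed 1.5 in either
direction, or a core detected in only one genotype. The integrated mass
is used instead of the apex height because the apex of a smoothed peak is
an extreme-value statistic: at ~200 mono-class pairs per core its
genotype log-ratio fluctuates with sd ≈ 0.19, whereas the integrated mass
fluctuates with pure counting noise (sd ≈ 0.11), and the 1.5 threshold
then sits ≈ 3.6 sd from a null ratio of 1 while a genuine two-fold
accessibility change lies far beyond it on the other side. Both
thresholds are parameters of `call_changes`.

## The simulator

The synthetic genome generates what the analysis assumes and nothing
more:

* **Nucleosome arrays** on a regular grid (165 bp spacing, random phase
  per chromosome) with 140 bp nucleosome-depleted regions upstream of
  each TSS, and one 125 bp centromere per chromosome whose core particle
  replaces the array locally. Occupancy is uniform (1.0) except the core.
* **Insert sizes** from a truncated-normal mixture at 150/300/450 bp
  (sd 15 bp, weights 0.6/0.25/0.15), emulating mono/di/tri-nucleosome
  protection. Mono- and tri-nucleosome fragments centre on a dyad (the
  centre of three consecutive nucleosomes is the middle one); di
  fragments centre on the midpoint between adjacent dyads. An isolated
  core particle emits mono fragments only, since di/tri protection
  requires adjacent nucleosomes. Centres carry uniform ±10 bp jitter.
* **Coverage** of 195 pairs per nucleosome (Poisson per dyad), the
  per-nucleosome depth the mapping is designed for.
* **ChIP tags** drawn with density proportional to a per-base fold
  profile painted from feature classes (centromeres highest at 8-fold,
  then structural RNA genes, replication/repeat elements and 3' IGRs);
  input tags are uniform. The unpainted background is depressed so the
  profile mean is 1, making a configured fold equal the observed
  ChIP:input ratio (ChIP sequencing is compositional); when enrichment
  covers too much genome for that to be feasible the background floors at
  0.05 and observed ratios compress, as in a real library. The
  H2A.Z-like target is promoter-enriched (6-fold over 5' IGRs) in wild
  type and redistributed (promoters 1.5-fold, gene bodies 3-fold) in the
  mutant.
* **Genotype perturbations**: the mutant shifts the two
  centromere-flanking nucleosomes on each side outward by 30 bp and
  scales core occupancy by 0.5, on all centromeres or a configured
  subset; with neutral parameters the genotypes are identical by
  construction.
* **Expression** counts are gamma-Poisson (overdispersion 0.002 — mild
  biological noise that does not vanish with depth) around log-normal
  baselines (median 1000 counts). A configured fraction of genes
  (default 10%) receives a true ratio whose magnitude is uniform on the
  log2 scale between 1.75- and 3-fold — safely beyond the 1.5 cutoff, so
  recovery measures the pipeline rather than boundary coin-flips — split
  evenly up/down. An optional boost inflates mutant ratios of weakly
  expressed genes to emulate derepression profiles; it is off by default.

One global seed drives everything; each stream (genome, MNase pairs per
genotype, ChIP/input per target and genotype, expression) draws from a
deterministic sub-stream, so outputs are byte-reproducible and adding one
simulation never perturbs another.

**What the simulator does not emulate:** sequence-dependent MNase bias
(AT preference), base-call errors and alignment artifacts, fragment-length
dependence on digestion extent, fuzzy or delocalised nucleosomes,
copy-number variation, and replication-dependent signal. Passing
recovery tests therefore demonstrates the correctness of the
transformations, not robustness to those real-data pathologies.

## Numerical conventions

* Coordinates 0-based, half-open internally; SAM and GFF conversions at
  the format boundary only.
* `.sgr` values serialize with 6 significant digits; integer count tracks
  round-trip exactly, smoothed tracks to 1e-6 relative.
* Discordant (inter-chromosomal) pairs are dropped with a counter; the
  pair's template length is taken from the mate with positive `ISIZE`.
* Division of zero by zero in ratio tracks yields NaN sentinels, never
  raises; downstream means are NaN-aware.
* Problem sizes in tests and the acceptance script (two 60 kb chromosomes,
  ~680 nucleosomes, 300 k tags per library, 500 genes, 16 centromeres at
  12 kb each) were chosen as the smallest sizes at which every recovery
  statistic is far from its decision boundary under counting noise.

## Known limitations

* IGR truncation at neighbour ORF boundaries leaves overlapping-gene
  IGRs zero-length rather than apportioning the shared region.
* The metagene CI is per-offset and pointwise; no simultaneous band.
* Greedy flank-peak matching is not globally optimal; with dense peak
  sets an assignment formulation would differ, but at nucleosomal
  spacing (165 bp) versus 150 bp tolerance the greedy and optimal
  matchings coincide in practice.
* `coverage_report` is bookkeeping (`reads × length / genome`), not an
  effective-coverage estimate accounting for mapping losses.
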