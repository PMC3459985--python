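# dyadmap

Chromatin-particle mapping and ChIP profiling for paired-end MNase-seq,
with a fully ground-truthed synthetic mini-genome for validation.

## The problem

Micrococcal nuclease (MNase) digests linker DNA and leaves behind DNA
protected by chromatin particles: ~150 bp for a mono-nucleosome, ~300 bp
for a di-nucleosome, ~125 bp for the Cse4-containing core particle of a
budding-yeast point centromere. Sequencing the protected fragments in
paired-end mode makes the particle type readable from the template length
(the SAM `ISIZE`): sorting read pairs into size classes and mapping each
retained pair's *centre point* yields a genome-wide frequency distribution
of particle **dyads**. Peaks in that distribution are translationally
positioned nucleosomes; comparing the tracks of two genotypes reveals
remodeler-dependent changes in nucleosome position and centromere-core
accessibility. The same toolkit covers the companion analyses such a study
needs: input-normalized ChIP enrichment tracks, per-feature-class
enrichment statistics, strand-aware metagene (average-gene) profiles
around TSS/TTS anchors, expression fold-change lists at a plain 1.5-fold
cutoff, and hypergeometric gene-list overlap probabilities.

## The core computation

For read pairs with leftmost 5' coordinate `x` and template length `s`:

1. **Size-class filter** — keep pairs with `s ∈ [t(1−w), t(1+w)]`,
   default `t = 150`, `w = 0.2`, i.e. the mono-nucleosome class
   150 bp ± 30 bp (bounds inclusive).
2. **Dyad position** — `d = x + ⌊s/2⌋`, the putative particle dyad.
3. **Binning** — genome-wide dyad counts in fixed 15 bp bins
   (bin `i` covers `[15i, 15(i+1))`, origin at coordinate 0).
4. **Smoothing** — 3-bin moving average (terminal bins average the two
   available bins).

Tracks are written as zero-referenced three-column `.sgr`
(chromosome, bin start, value) or as bedGraph. ChIP tracks are binned tag
counts corrected for library size and probe length
(`raw × 10⁶/total × 10³/probe`), expressed against an input library as
`log2((chip+c)/(input+c))` or as a linear occupancy ratio; genotype
comparisons subtract one track from the other. The centromere report
detects the core particle as the highest local maximum inside the CEN
interval, pairs flanking peaks between genotypes greedily by nearest
position (tolerance 150 bp), and calls flank shifts (≥ 2 bins) and
core-accessibility changes (integrated core-mass ratio ≥ 1.5 either way).

Everything is exercised end-to-end on a simulated mini-genome whose
nucleosome arrays, centromeric core particles, insert-size mixture,
feature-class ChIP enrichment and planted expression changes are known
exactly, so every stage's output can be scored against truth. See
`docs/methods.md` for models, parameters and limitations.

## Worked example

Simulate a two-chromosome genome and map wild-type nucleosome dyads:

```bash
dyadmap simulate --seed 11 --out demo_sim
# simulated genome with 48 genes -> demo_sim
dyadmap map-particles --pairs demo_sim/pairs_wt.bedpe --out demo_wt.sgr
head -3 demo_wt.sgr
# chrI    0       0
# chrI    15      0
# chrI    30      0
```

Run the whole pipeline (simulation → particle mapping for both genotypes
→ ChIP tracks → expression → metagene → centromere report → overlap) and
inspect the per-centromere comparison:

```python
from dyadmap import SimConfig
from dyadmap.pipeline import run_pipeline
import pandas as pd

run_pipeline(SimConfig(seed=11), "demo_run")
print(pd.read_csv("demo_run/cen_report.tsv", sep="\t")
        [["cen_id", "core_height_ratio", "max_abs_shift", "calls"]])
```

```
   cen_id  core_height_ratio  max_abs_shift                                 calls
 CEN_chrI           0.505435           30.0 flank-shift;core-accessibility-change
CEN_chrII           0.502538           30.0 flank-shift;core-accessibility-change
```

Both simulated centromeres were perturbed in the mutant genotype with a
30 bp outward shift of the flanking nucleosomes and a halved core-particle
occupancy — the report recovers the 30 bp shift exactly (at 15 bp bin
resolution) and measures the core mass ratio at ~0.5, calling both change
types. `demo_run/` also contains the `.sgr` dyad tracks, log2 ChIP
enrichment tracks, metagene profile TSVs, up/down gene lists and a
manifest recording every parameter and the seed.

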