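"""Gene-context derivation: intergenic regions, orientation, expression tiers.

The 5' and 3' intergenic regions (IGRs) of a gene comprise its annotated
UTR plus a fixed outward extension (default 150 bases) capturing the
promoter or terminator; genes lacking UTR annotation fall back to the bare
extension from the ORF boundary.  IGRs are truncated at the nearest
neighbouring ORF boundary and at chromosome ends so they never overlap any
coding region.
"""

from __future__ import annotations

import logging
from collections import defaultdict

import numpy as np
import pandas as pd

from .model import FeatureInterval, GeneModel

logger = logging.getLogger(__name__)

ORIENTATION_CLASSES = ("tRNA", "snoRNA", "snRNA")


def assign_igrs(
    genes: list[GeneModel],
    extension: int = 150,
    chrom_lengths: dict[str, int] | None = None,
) -> list[GeneModel]:
    """Attach ``igr5``/``igr3`` intervals to every gene, in place.

    With a UTR the IGR is the UTR interval extended outward by
    ``extension`` bases; without one it is ``extension`` bases outward
    from the ORF boundary.  Intervals are clipped at neighbouring ORF
    boundaries and chromosome ends; an IGR squeezed to nothing by an
    overlapping neighbour becomes zero-length with a warning.
    """
    by_chrom: dict[str, list[GeneModel]] = defaultdict(list)
    for g in genes:
        by_chrom[g.chrom].append(g)

    for chrom, glist in by_chrom.items():
        glist.sort(key=lambda g: (g.orf_start, g.orf_end, g.id))
        chrom_len = None if chrom_lengths is None else chrom_lengths.get(chrom)
        for i, g in enumerate(glist):
            left_limit = max((h.orf_end for h in glist[:i]), default=0)
            right_limit = min(
                (h.orf_start for h in glist[i + 1:]),
                default=chrom_len if chrom_len is not None else np.inf,
            )

            def clip(lo, hi):
                lo2 = int(max(lo, left_limit, 0))
                hi2 = int(min(hi, right_limit))
                if hi2 < lo2:
                    lo2 = hi2 = int(np.clip(lo2, left_limit, right_limit))
                return lo2, hi2

            u5 = g.utr5_len if g.utr5_len is not None else 0
            u3 = g.utr3_len if g.utr3_len is not None else 0
            if g.strand == "+":
                igr5 = clip(g.orf_start - u5 - extension, g.orf_start)
                igr3 = clip(g.orf_end, g.orf_end + u3 + extension)
            else:
                igr5 = clip(g.orf_end, g.orf_end + u5 + extension)
                igr3 = clip(g.orf_start - u3 - extension, g.orf_start)
            if igr5[0] == igr5[1] or igr3[0] == igr3[1]:
                logger.warning("gene %s: zero-length IGR after neighbour truncation", g.id)
            g.igr5, g.igr3 = igr5, igr3
    return genes


def classify_orientation(
    genes: list[GeneModel],
    features: list[FeatureInterval] | None = None,
) -> list[GeneModel]:
    """Label each gene's promoter side (divergent/tandem) and terminator
    side (convergent/tandem), in place.

    The nearest neighbouring element on each side decides the label:
    head-to-head opposite-strand neighbours make a promoter divergent,
    tail-to-tail neighbours make a terminator convergent.  Stranded
    noncoding elements (tRNA/snoRNA/snRNA) count as neighbours.
    Chromosome-terminal sides default to tandem with ``terminal_flag``
    set.
    """
    elements: dict[str, list[tuple[int, int, str, object]]] = defaultdict(list)
    for g in genes:
        elements[g.chrom].append((g.orf_start, g.orf_end, g.strand, g))
    for f in features or []:
        if f.feature_class in ORIENTATION_CLASSES and f.strand in ("+", "-"):
            elements[f.chrom].append((f.start, f.end, f.strand, f))

    for chrom, elist in elements.items():
        elist.sort(key=lambda e: (e[0], e[1]))
        for i, (start, end, strand, obj) in enumerate(elist):
            if not isinstance(obj, GeneModel):
                continue
            prev_el = elist[i - 1] if i > 0 else None
            next_el = elist[i + 1] if i + 1 < len(elist) else None
            upstream = prev_el if strand == "+" else next_el
            downstream = next_el if strand == "+" else prev_el
            facing = "-" if strand == "+" else "+"

            if upstream is None:
                obj.promoter_context = "tandem"
                obj.terminal_flag = True
            else:
                obj.promoter_context = "divergent" if upstream[2] == facing else "tandem"
            if downstream is None:
                obj.terminator_context = "tandem"
                obj.terminal_flag = True
            else:
                obj.terminator_context = "convergent" if downstream[2] == facing else "tandem"
    return genes


def expression_categories(
    expression: pd.Series | dict[str, float],
    n_classes: int = 3,
    pseudocount: float = 1.0,
) -> pd.Series:
    """Split genes into equal-size expression tiers by log2 intensity.

    Genes are ranked by ``log2(value + pseudocount)`` (ties broken by gene
    id) and partitioned into ``n_classes`` contiguous rank groups whose
    sizes differ by at most one.  With three classes the labels are
    ``low``/``medium``/``high`` from the bottom tier up.
    """
    s = pd.Series(expression, dtype=float)
    if (s < 0).any():
        raise ValueError("expression values must be non-negative")
    log = np.log2(s + pseudocount)
    order = sorted(s.index, key=lambda gid: (log[gid], str(gid)))
    if n_classes == 3:
        labels = ["low", "medium", "high"]
    else:
        labels = [f"q{i + 1}" for i in range(n_classes)]
    out = {}
    for label, chunk in zip(labels, np.array_split(np.array(order, dtype=object), n_classes)):
        for gid in chunk:
            out[gid] = label
    return pd.Series(out).reindex(s.index)
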