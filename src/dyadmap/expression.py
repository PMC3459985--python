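"""Per-gene expression quantification, fold-change lists and coverage.

Raw counts are normalized for sequencing depth and gene length (reads per
kilobase per million mapped reads).  Differentially affected genes are
called with a plain fold-change cutoff (default 1.5), matching analyses
that predate dispersion-modelling DE statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def quantify_expression(
    counts: pd.Series, gene_lengths: pd.Series, library_total: float | None = None
) -> pd.Series:
    """Depth- and length-normalized expression: count x 1e9 / (total x length)."""
    c = pd.Series(counts, dtype=float)
    lengths = pd.Series(gene_lengths, dtype=float).reindex(c.index)
    if lengths.isna().any():
        raise ValueError("gene_lengths must cover every gene in counts")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    total = float(c.sum()) if library_total is None else float(library_total)
    if total <= 0:
        raise ValueError("library_total must be positive")
    return c * 1e9 / (total * lengths)


@dataclass
class FoldChangeLists:
    up: list[str]
    down: list[str]
    ratios: pd.Series


def fold_change_lists(
    expr_wt: pd.Series,
    expr_mut: pd.Series,
    cutoff: float = 1.5,
    pseudocount: float = 1.0,
) -> FoldChangeLists:
    """Genes changed at least ``cutoff``-fold between genotypes.

    ratio = (mut + pc) / (wt + pc); up if ratio >= cutoff, down if
    ratio <= 1/cutoff.  The two lists are disjoint for any cutoff > 1.
    """
    wt = pd.Series(expr_wt, dtype=float)
    mut = pd.Series(expr_mut, dtype=float).reindex(wt.index)
    if mut.isna().any():
        raise ValueError("expression tables must cover the same genes")
    ratio = (mut + pseudocount) / (wt + pseudocount)
    up = sorted(ratio.index[ratio >= cutoff])
    down = sorted(ratio.index[ratio <= 1.0 / cutoff])
    return FoldChangeLists(up=up, down=down, ratios=ratio)


def coverage_report(read_count: float, read_length: float, genome_length: float) -> float:
    """Fold genome coverage: read_count x read_length / genome_length."""
    if read_length <= 0 or genome_length <= 0:
        raise ValueError("read_length and genome_length must be positive")
    if read_count < 0:
        raise ValueError("read_count must be non-negative")
    return read_count * read_length / genome_length
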