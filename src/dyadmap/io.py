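"""Readers and writers for every external format the pipeline touches.

All coordinates are 0-based half-open internally; 1-based conventions
(SAM, GFF3) are converted exactly once, here.  Columnar formats are
tab-delimited UTF-8 text.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from pyfaidx import Fasta

from .model import BinnedTrack, FeatureInterval, GeneModel

logger = logging.getLogger(__name__)

SGR_PRECISION = "%.6g"


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    fa = Fasta(str(path))
    return {name: str(fa[name][:]) for name in fa.keys()}


# ---------------------------------------------------------------------------
# paired-end alignments: BEDPE and SAM-subset
# ---------------------------------------------------------------------------

def write_pairs_bedpe(pairs: pd.DataFrame, path: str | Path) -> None:
    """Pairs as 6-column BEDPE; each mate is written as a 36 bp interval
    (clipped to the template for short inserts)."""
    with open(path, "w") as fh:
        for chrom, left5, isize in pairs[["chrom", "left5", "isize"]].itertuples(index=False):
            rlen = min(36, isize)
            s1, e1 = left5, left5 + rlen
            e2 = left5 + isize
            s2 = e2 - rlen
            fh.write(f"{chrom}\t{s1}\t{e1}\t{chrom}\t{s2}\t{e2}\n")


def read_pairs_bedpe(path: str | Path) -> pd.DataFrame:
    """BEDPE -> canonical pair table: leftmost start, end-to-end distance.

    Inter-chromosomal records are skipped with a logged count; malformed
    lines raise :class:`FormatError` with the line number.
    """
    rows = []
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise FormatError(f"{path}:{lineno}: expected >= 6 BEDPE columns")
            try:
                c1, s1, e1, c2, s2, e2 = (
                    parts[0], int(parts[1]), int(parts[2]),
                    parts[3], int(parts[4]), int(parts[5]),
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            if c1 != c2:
                skipped += 1
                continue
            left = min(s1, s2)
            isize = max(e1, e2) - left
            if isize <= 0:
                raise FormatError(f"{path}:{lineno}: non-positive template length")
            rows.append((c1, left, isize))
    if skipped:
        logger.info("read_pairs_bedpe: skipped %d inter-chromosomal pairs", skipped)
    return pd.DataFrame(rows, columns=["chrom", "left5", "isize"]).astype(
        {"left5": np.int64, "isize": np.int64}
    )


def write_pairs_sam(
    pairs: pd.DataFrame, path: str | Path, chrom_lengths: dict[str, int]
) -> None:
    """Minimal SAM with proper-pair flags and the template length field."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for chrom, length in chrom_lengths.items():
            fh.write(f"@SQ\tSN:{chrom}\tLN:{length}\n")
        for i, (chrom, left5, isize) in enumerate(
            pairs[["chrom", "left5", "isize"]].itertuples(index=False)
        ):
            rlen = int(min(36, isize))
            qname = f"pair{i}"
            pos1 = int(left5) + 1
            pos2 = int(left5) + int(isize) - rlen + 1
            seq = "*"
            fh.write(
                f"{qname}\t99\t{chrom}\t{pos1}\t42\t{rlen}M\t=\t{pos2}\t{isize}\t{seq}\t*\n"
            )
            fh.write(
                f"{qname}\t147\t{chrom}\t{pos2}\t42\t{rlen}M\t=\t{pos1}\t{-int(isize)}\t{seq}\t*\n"
            )


def read_pairs_sam(path: str | Path) -> pd.DataFrame:
    """SAM -> canonical pair table.

    One pair is taken per template from the record with positive template
    length (the leftmost mate); unmapped, secondary and supplementary
    records are skipped with a logged count.
    """
    rows = []
    skipped = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                skipped += 1
                continue
            tlen = rec.template_length
            if tlen <= 0:
                continue  # the mate record carries the pair
            rows.append((rec.reference_name, rec.reference_start, tlen))
    if skipped:
        logger.info("read_pairs_sam: skipped %d unmapped/secondary records", skipped)
    return pd.DataFrame(rows, columns=["chrom", "left5", "isize"]).astype(
        {"left5": np.int64, "isize": np.int64}
    )


def read_pairs(path: str | Path, dialect: str = "bedpe") -> pd.DataFrame:
    if dialect in ("bedpe", "BEDPE"):
        return read_pairs_bedpe(path)
    if dialect in ("sam", "SAM", "sam-subset"):
        return read_pairs_sam(path)
    raise ValueError(f"unknown pair dialect {dialect!r}")


# ---------------------------------------------------------------------------
# single-end tags: BED6
# ---------------------------------------------------------------------------

def write_tags_bed(tags: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, pos5, strand in tags[["chrom", "pos5", "strand"]].itertuples(index=False):
            fh.write(f"{chrom}\t{pos5}\t{pos5 + 1}\ttag\t0\t{strand}\n")


def read_tags_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 5],
        names=["chrom", "pos5", "strand"],
        dtype={"chrom": str, "pos5": np.int64, "strand": str},
    )
    return df


# ---------------------------------------------------------------------------
# binned tracks: .sgr and bedGraph
# ---------------------------------------------------------------------------

def write_sgr(track: BinnedTrack, path: str | Path) -> None:
    """Zero-referenced three-column track: chromosome, bin start, value."""
    bw = track.bin_width
    with open(path, "w") as fh:
        for chrom, values in track.values.items():
            for i, v in enumerate(values):
                fh.write(f"{chrom}\t{i * bw}\t{SGR_PRECISION % v}\n")


def read_sgr(path: str | Path, semantics: str = "frequency") -> BinnedTrack:
    """Read an .sgr track; bins must start at 0 and be evenly spaced."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "pos", "value"])
    if len(df) == 0:
        raise FormatError(f"{path}: empty .sgr file")
    values: dict[str, np.ndarray] = {}
    bin_width = None
    for chrom, sub in df.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        if pos[0] != 0:
            raise FormatError(f"{path}: chromosome {chrom} does not start at 0")
        if len(pos) > 1:
            diffs = np.diff(pos)
            if len(set(diffs.tolist())) != 1:
                raise FormatError(f"{path}: uneven bin spacing on {chrom}")
            bw = int(diffs[0])
            if bin_width is None:
                bin_width = bw
            elif bw != bin_width:
                raise FormatError(f"{path}: bin width differs between chromosomes")
        values[str(chrom)] = sub["value"].to_numpy(dtype=float)
    if bin_width is None:
        raise FormatError(f"{path}: cannot infer bin width from single-bin track")
    return BinnedTrack(bin_width=bin_width, values=values, semantics=semantics)


def write_bedgraph(track: BinnedTrack, path: str | Path, name: str = "track") -> None:
    """Standard 4-column bedGraph, one half-open interval per bin."""
    bw = track.bin_width
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{name}"\n')
        for chrom, values in track.values.items():
            for i, v in enumerate(values):
                fh.write(f"{chrom}\t{i * bw}\t{(i + 1) * bw}\t{SGR_PRECISION % v}\n")


# ---------------------------------------------------------------------------
# annotation: GFF3-style table and augmented gene TSV
# ---------------------------------------------------------------------------

def write_annotation_gff(
    genes: list[GeneModel], features: list[FeatureInterval], path: str | Path
) -> None:
    """GFF3-style table: feature class in column 3, gene attrs carry UTRs."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = [f"ID={g.id}"]
            if g.utr5_len is not None:
                attrs.append(f"utr5_len={g.utr5_len}")
            if g.utr3_len is not None:
                attrs.append(f"utr3_len={g.utr3_len}")
            fh.write(
                f"{g.chrom}\tdyadmap\tgene\t{g.orf_start + 1}\t{g.orf_end}\t.\t"
                f"{g.strand}\t.\t{';'.join(attrs)}\n"
            )
        for f in features:
            if f.feature_class == "ORF":
                continue  # redundant with the gene rows
            fh.write(
                f"{f.chrom}\tdyadmap\t{f.feature_class}\t{f.start + 1}\t{f.end}\t.\t"
                f"{f.strand}\t.\tID={f.id}\n"
            )


def _parse_attrs(s: str) -> dict[str, str]:
    out = {}
    for part in s.strip().split(";"):
        if part and "=" in part:
            k, v = part.split("=", 1)
            out[k] = v
    return out


def read_annotation_gff(path: str | Path) -> tuple[list[GeneModel], list[FeatureInterval]]:
    genes: list[GeneModel] = []
    features: list[FeatureInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF columns")
            chrom, _, ftype, start1, end, _, strand, _, attrs_s = parts
            start = int(start1) - 1
            end = int(end)
            attrs = _parse_attrs(attrs_s)
            if ftype == "gene":
                g = GeneModel(
                    attrs.get("ID", f"gene_at_{chrom}_{start}"), chrom, strand,
                    start, end,
                    utr5_len=int(attrs["utr5_len"]) if "utr5_len" in attrs else None,
                    utr3_len=int(attrs["utr3_len"]) if "utr3_len" in attrs else None,
                )
                genes.append(g)
                features.append(FeatureInterval(chrom, start, end, "ORF", strand, g.id))
            else:
                features.append(
                    FeatureInterval(chrom, start, end, ftype, strand, attrs.get("ID", ""))
                )
    return genes, features


_GENE_TSV_COLUMNS = [
    "gene_id", "chrom", "strand", "orf_start", "orf_end", "utr5_len", "utr3_len",
    "tss", "tts", "igr5_start", "igr5_end", "igr3_start", "igr3_end",
    "promoter_context", "terminator_context", "expression_category",
]


def write_gene_table(genes: list[GeneModel], path: str | Path) -> None:
    """Augmented annotation TSV with derived anchors, IGRs and contexts."""
    rows = []
    for g in genes:
        rows.append(
            {
                "gene_id": g.id, "chrom": g.chrom, "strand": g.strand,
                "orf_start": g.orf_start, "orf_end": g.orf_end,
                "utr5_len": "" if g.utr5_len is None else g.utr5_len,
                "utr3_len": "" if g.utr3_len is None else g.utr3_len,
                "tss": g.tss, "tts": g.tts,
                "igr5_start": "" if g.igr5 is None else g.igr5[0],
                "igr5_end": "" if g.igr5 is None else g.igr5[1],
                "igr3_start": "" if g.igr3 is None else g.igr3[0],
                "igr3_end": "" if g.igr3 is None else g.igr3[1],
                "promoter_context": g.promoter_context or "",
                "terminator_context": g.terminator_context or "",
                "expression_category": g.expression_category or "",
            }
        )
    pd.DataFrame(rows, columns=_GENE_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_gene_table(path: str | Path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    genes = []
    for row in df.itertuples(index=False):
        g = GeneModel(
            row.gene_id, row.chrom, row.strand,
            int(row.orf_start), int(row.orf_end),
            utr5_len=int(row.utr5_len) if row.utr5_len != "" else None,
            utr3_len=int(row.utr3_len) if row.utr3_len != "" else None,
        )
        if row.igr5_start != "":
            g.igr5 = (int(row.igr5_start), int(row.igr5_end))
        if row.igr3_start != "":
            g.igr3 = (int(row.igr3_start), int(row.igr3_end))
        g.promoter_context = row.promoter_context or None
        g.terminator_context = row.terminator_context or None
        g.expression_category = row.expression_category or None
        genes.append(g)
    return genes


# ---------------------------------------------------------------------------
# counts and truth tables
# ---------------------------------------------------------------------------

def write_counts(counts: pd.Series, path: str | Path) -> None:
    counts.rename("count").rename_axis("gene_id").to_csv(path, sep="\t")


def read_counts(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0].astype(float)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
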