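"""End-to-end orchestration of the pipeline on simulated data.

Runs simulate -> particle mapping (both genotypes) -> ChIP tracks ->
metagene profiles -> expression analysis -> centromere report -> list
overlap, writing every artifact plus a manifest (parameters, stage status,
package version, seed) into one output directory.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__, io
from .annotation import expression_categories
from .cen import cen_report
from .config import SimConfig
from .enrichment import bin_tags, difference_track, feature_box_stats, \
    linear_occupancy, log2_enrichment, normalize_track
from .expression import fold_change_lists, quantify_expression
from .metagene import anchored_profile, moving_average_ratio
from .overlap import overlap_from_lists
from .particles import isize_spectrum, map_particles
from .simulate import make_genome, simulate_chip_tags, simulate_expression, \
    simulate_mnase_pairs

logger = logging.getLogger(__name__)

STAGES = [
    "simulate", "map-particles", "chip-track", "metagene",
    "expression", "cen-report", "overlap",
]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: SimConfig | str | Path, outdir: str | Path) -> dict:
    """Execute all stages; returns the manifest dictionary."""
    if not isinstance(config, SimConfig):
        config = SimConfig.load(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": {},
    }

    def run_stage(name, fn):
        logger.info("stage %s ...", name)
        try:
            fn()
        except Exception as exc:
            manifest["stages"][name] = {"status": "failed", "error": str(exc)}
            _write_manifest(manifest, outdir)
            raise PipelineError(name, exc) from exc
        manifest["stages"][name] = {"status": "complete"}

    state: dict = {}

    def stage_simulate():
        bundle = make_genome(config)
        state["bundle"] = bundle
        config.save(outdir / "config.yaml")
        io.write_fasta(bundle.sequences, outdir / "genome.fa")
        io.write_annotation_gff(bundle.genes, bundle.features, outdir / "annotation.gff")
        for genotype in ("wt", "mutant"):
            pairs = simulate_mnase_pairs(bundle, genotype)
            state[f"pairs_{genotype}"] = pairs
            io.write_pairs_bedpe(pairs, outdir / f"pairs_{genotype}.bedpe")
            io.write_table(
                bundle.truth.dyads[genotype], outdir / f"truth_dyads_{genotype}.tsv"
            )

    def stage_map_particles():
        bundle = state["bundle"]
        for genotype in ("wt", "mutant"):
            track = map_particles(
                state[f"pairs_{genotype}"], chrom_lengths=bundle.chrom_lengths
            )
            state[f"track_{genotype}"] = track
            io.write_sgr(track, outdir / f"dyads_{genotype}.sgr")
            spec = isize_spectrum(state[f"pairs_{genotype}"])
            pd.DataFrame(
                sorted(spec.items()), columns=["isize", "count"]
            ).to_csv(outdir / f"isize_spectrum_{genotype}.tsv", sep="\t", index=False)

    def stage_chip_track():
        bundle = state["bundle"]
        for target, genotype in (("fun30", "wt"), ("htz1", "wt"), ("htz1", "mutant")):
            chip, inp = simulate_chip_tags(bundle, target=target, genotype=genotype)
            chip_n = normalize_track(
                bin_tags(chip, 10, bundle.chrom_lengths), len(chip)
            )
            inp_n = normalize_track(
                bin_tags(inp, 10, bundle.chrom_lengths), len(inp)
            )
            key = f"{target}_{genotype}"
            state[f"log2_{key}"] = log2_enrichment(chip_n, inp_n)
            state[f"occ_{key}"] = linear_occupancy(chip_n, inp_n)
            io.write_sgr(state[f"log2_{key}"], outdir / f"log2_{key}.sgr")
        diff = difference_track(state["occ_htz1_mutant"], state["occ_htz1_wt"])
        io.write_sgr(diff, outdir / "htz1_occupancy_diff.sgr")
        stats = feature_box_stats(state["log2_fun30_wt"], state["bundle"].features)
        io.write_table(stats, outdir / "feature_stats.tsv")

    def stage_expression():
        bundle = state["bundle"]
        table = simulate_expression(bundle)
        state["expr_table"] = table
        lengths = pd.Series({g.id: g.length for g in bundle.genes})
        wt = quantify_expression(pd.Series(table.wt_count.values, index=table.gene_id), lengths)
        mut = quantify_expression(pd.Series(table.mut_count.values, index=table.gene_id), lengths)
        state["expr_wt"], state["expr_mut"] = wt, mut
        cats = expression_categories(wt)
        for g in bundle.genes:
            g.expression_category = cats[g.id]
        lists = fold_change_lists(wt, mut)
        state["fc_lists"] = lists
        (outdir / "genes_up.txt").write_text("\n".join(lists.up) + "\n")
        (outdir / "genes_down.txt").write_text("\n".join(lists.down) + "\n")
        io.write_table(table, outdir / "expression_counts.tsv")
        io.write_gene_table(bundle.genes, outdir / "genes_annotated.tsv")

    def stage_metagene():
        bundle = state["bundle"]
        profile = anchored_profile(
            state["log2_htz1_wt"], bundle.genes, anchor="tss5",
            upstream=1000, downstream=2000, probe=25,
        )
        io.write_table(profile, outdir / "metagene_tss_htz1_wt.tsv")
        curve = moving_average_ratio(
            state["expr_wt"], state["expr_mut"],
            window=min(150, max(2, len(state["expr_wt"]) // 2)),
        )
        io.write_table(curve, outdir / "expression_ratio_curve.tsv")

    def stage_cen_report():
        bundle = state["bundle"]
        report = cen_report(
            state["track_wt"], state["track_mutant"], bundle.cen_intervals
        )
        state["cen_report"] = report
        io.write_table(report, outdir / "cen_report.tsv")

    def stage_overlap():
        universe = [g.id for g in state["bundle"].genes]
        lists = state["fc_lists"]
        truth_de = set(state["expr_table"].loc[state["expr_table"].is_de, "gene_id"])
        res = overlap_from_lists(universe, lists.up + lists.down, truth_de)
        io.write_table(
            pd.DataFrame(
                [{
                    "universe": res.universe_size, "list_a": res.list_a_size,
                    "list_b": res.list_b_size, "overlap": res.overlap,
                    "p_value": res.p_value,
                }]
            ),
            outdir / "overlap.tsv",
        )

    run_stage("simulate", stage_simulate)
    run_stage("map-particles", stage_map_particles)
    run_stage("chip-track", stage_chip_track)
    run_stage("expression", stage_expression)
    run_stage("metagene", stage_metagene)
    run_stage("cen-report", stage_cen_report)
    run_stage("overlap", stage_overlap)
    _write_manifest(manifest, outdir)
    return manifest


def _write_manifest(manifest: dict, outdir: Path) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
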