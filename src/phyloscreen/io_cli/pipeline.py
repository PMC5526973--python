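"""Stage orchestration: chain the analysis stages over files on disk.

Identical config + inputs + seed produce byte-identical result tables.
Each run writes a plain-text log recording the config, seed, and a
checksum per input file.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import pandas as pd

from .. import network_go, promoter_scan, qpcr_quant, target_screen
from ..qpcr_quant import relative_expression_by_condition
from .config import PipelineConfig
from .readers import (read_annotation_flags, read_bed, read_ct_table,
                      read_dnds_table, read_edge_table, read_expression_table,
                      read_fasta, read_gene_list, read_go_annotations,
                      read_motifs)
from .writers import (write_bedgraph, write_fasta, write_result_table)

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "STAGES", "MissingInputError"]

STAGES = ("screen", "qpcr", "promoters", "network", "go", "dnds")

# stage -> (required input keys, optional input keys)
_REQUIREMENTS = {
    "screen": (("expression",), ("reference_lists", "annotations")),
    "qpcr": (("ct",), ()),
    "promoters": (("genome", "tss", "motifs"), ("reads",)),
    "network": (("edges",), ()),
    "go": (("go_annotations", "sample", "universe"), ()),
    "dnds": (("dnds",), ()),
}


class MissingInputError(FileNotFoundError):
    """A requested stage lacks one of its input files."""


def _check_inputs(stages: list[str], inputs: dict[str, Path]) -> None:
    problems = []
    for stage in stages:
        required, _optional = _REQUIREMENTS[stage]
        for key in required:
            if key not in inputs:
                problems.append(f"stage {stage!r} needs input {key!r}")
            elif not Path(inputs[key]).exists():
                problems.append(
                    f"stage {stage!r}: input file {inputs[key]} not found")
    if problems:
        raise MissingInputError("; ".join(problems))


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(
    config: PipelineConfig,
    inputs: dict[str, Path],
    out_dir: str | Path,
    stages: list[str] | None = None,
) -> dict[str, Path]:
    """Run the requested stages; return a name -> path map of outputs."""
    stages = list(stages) if stages else list(STAGES)
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}")
    _check_inputs(stages, inputs)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    log_path = out_dir / "run.log"
    with open(log_path, "w") as log:
        log.write("phyloscreen run\n")
        log.write(f"seed\t{config.seed}\n")
        for key, value in sorted(config.to_dict().items()):
            log.write(f"config.{key}\t{value}\n")
        for key in sorted(inputs):
            path = Path(inputs[key])
            if path.exists():
                log.write(f"input.{key}\t{path}\t{_sha256(path)}\n")
        log.write(f"stages\t{','.join(stages)}\n")
    outputs["log"] = log_path

    if "screen" in stages:
        outputs.update(_run_screen(config, inputs, out_dir))
    if "qpcr" in stages:
        outputs.update(_run_qpcr(config, inputs, out_dir))
    if "promoters" in stages:
        outputs.update(_run_promoters(config, inputs, out_dir))
    if "network" in stages:
        outputs.update(_run_network(config, inputs, out_dir))
    if "go" in stages:
        outputs.update(_run_go(config, inputs, out_dir))
    if "dnds" in stages:
        outputs.update(_run_dnds(inputs, out_dir))
    return outputs


def _run_screen(config, inputs, out_dir) -> dict[str, Path]:
    expr = read_expression_table(inputs["expression"], config)
    candidates = target_screen.entry_screen(expr, config)
    stats = target_screen.screen_statistics(expr, config,
                                            genes=sorted(candidates))
    twofold = target_screen.twofold_filter(candidates, stats, config)
    reference_lists = {}
    for item in str(inputs.get("reference_lists", "")).split(","):
        if item and Path(item).exists():
            reference_lists[Path(item).stem] = read_gene_list(item)
    annotations = (read_annotation_flags(inputs["annotations"])
                   if "annotations" in inputs else None)
    results = target_screen.classify(candidates, twofold, stats,
                                     reference_lists, annotations, config)
    frame = target_screen.screen_results_frame(results)
    path = out_dir / "screen_results.tsv"
    write_result_table(frame, path)
    return {"screen_results": path}


def _run_qpcr(config, inputs, out_dir) -> dict[str, Path]:
    records = read_ct_table(inputs["ct"])
    means = qpcr_quant.collapse_technical(records)
    rel = qpcr_quant.delta_delta_ct(means, config.reference_genes,
                                    config.calibrator)
    rel_path = out_dir / "relative_expression.tsv"
    write_result_table(rel, rel_path)
    values = relative_expression_by_condition(rel)
    results = target_screen.validate(values, config)
    verdicts = target_screen.validation_verdicts(results, config)
    val_path = out_dir / "qpcr_validation.tsv"
    write_result_table(verdicts, val_path)
    return {"relative_expression": rel_path, "qpcr_validation": val_path}


def _run_promoters(config, inputs, out_dir) -> dict[str, Path]:
    genome = read_fasta(inputs["genome"])
    tss = read_bed(inputs["tss"])
    motifs = read_motifs(inputs["motifs"])
    regions = promoter_scan.extract_promoters(
        tss, genome, promoter_length=config.promoter_length)
    write_fasta({r.gene: r.sequence for r in regions},
                out_dir / "promoters.fasta")
    outputs = {"promoters": out_dir / "promoters.fasta"}

    hit_rows = []
    all_hits = {}
    for region in regions:
        hits = promoter_scan.scan_motifs(region, motifs)
        all_hits[region.gene] = hits
        hit_rows.extend(
            {"gene": h.gene, "motif": h.motif_id, "offset": h.offset,
             "strand": h.strand_of_match} for h in hits)
    hits_path = out_dir / "motif_hits.tsv"
    write_result_table(pd.DataFrame(
        hit_rows, columns=["gene", "motif", "offset", "strand"]), hits_path)
    outputs["motif_hits"] = hits_path

    if "reads" in inputs and Path(inputs["reads"]).exists():
        reads = read_bed(inputs["reads"])
        genome_length = sum(len(s) for s in genome.values())
        total_mapped = len(reads)
        read_length = int((reads["end"] - reads["start"]).median())
        summary_rows = []
        for region in regions:
            track = promoter_scan.promoter_coverage(
                reads, region, total_mapped, genome_length, read_length)
            bg_path = out_dir / f"coverage_{region.gene}.bedgraph"
            write_bedgraph(region.chrom, region.start, track.normalized,
                           bg_path)
            outputs[f"coverage_{region.gene}"] = bg_path
            report = promoter_scan.cooccurrence_report(
                all_hits[region.gene], track)
            summary_rows.append({
                "gene": region.gene,
                "n_motif_hits": report["n_motif_hits"],
                "n_overlapping_hits": report["n_overlapping_hits"]})
        summary_path = out_dir / "promoter_summary.tsv"
        write_result_table(pd.DataFrame(summary_rows), summary_path)
        outputs["promoter_summary"] = summary_path
    return outputs


def _run_network(config, inputs, out_dir) -> dict[str, Path]:
    net = read_edge_table(inputs["edges"])
    stat_rows = []
    degree_rows = []
    for threshold in config.network_thresholds:
        view = network_go.threshold_view(net, threshold)
        stats = network_go.lcc_stats(view)
        stat_rows.append({
            "threshold": threshold,
            "n_nodes": view.number_of_nodes(),
            "n_edges": view.number_of_edges(),
            "lcc_size": stats.lcc_size,
            "mean_degree_lcc": stats.mean_degree_lcc,
            "isolated": stats.isolated_count,
            "clustering": network_go.clustering_coefficient(view),
        })
        degree_rows.extend(
            {"threshold": threshold, "node": n, "degree": d}
            for n, d in sorted(stats.degrees.items()))
    stats_path = out_dir / "network_stats.tsv"
    degrees_path = out_dir / "node_degrees.tsv"
    write_result_table(pd.DataFrame(stat_rows), stats_path)
    write_result_table(pd.DataFrame(degree_rows), degrees_path)
    return {"network_stats": stats_path, "node_degrees": degrees_path}


def _run_go(config, inputs, out_dir) -> dict[str, Path]:
    annotations = read_go_annotations(inputs["go_annotations"])
    sample = read_gene_list(inputs["sample"])
    universe = read_gene_list(inputs["universe"])
    results = network_go.go_enrichment(sample, annotations, universe,
                                       go_alpha=config.go_alpha)
    frame = pd.DataFrame([{
        "term": r.term, "k": r.k, "K": r.K, "n": r.n,
        "N_universe": r.N_universe, "p": r.p, "fdr": r.fdr,
        "fdr_adjusted": r.fdr_adjusted, "enriched": r.enriched,
    } for r in results])
    path = out_dir / "go_enrichment.tsv"
    write_result_table(frame, path)
    return {"go_enrichment": path}


def _run_dnds(inputs, out_dir) -> dict[str, Path]:
    records = read_dnds_table(inputs["dnds"])
    cmp = target_screen.compare_dnds(records)
    frame = pd.DataFrame([{
        "n": len(records),
        "mean_a": cmp.mean_a, "mean_b": cmp.mean_b,
        "median_a": cmp.median_a, "median_b": cmp.median_b,
        "U": cmp.mwu.U, "p_two_sided": cmp.mwu.p_two_sided,
        "negative_selection": cmp.negative_selection,
    }])
    path = out_dir / "dnds_comparison.tsv"
    write_result_table(frame, path)
    return {"dnds_comparison": path}
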