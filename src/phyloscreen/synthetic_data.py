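"""Synthetic input generators with planted, serialized ground truth.

Every generator is deterministic given (parameters, seed) and emits data
in exactly the shapes the readers consume, alongside a truth table that
downstream tests compare against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_cli.config import PipelineConfig
from .io_cli.tables import ExpressionTable

__all__ = [
    "simulate_expression",
    "simulate_ct",
    "simulate_promoters_and_reads",
    "simulate_network_and_go",
    "PromoterTruth",
    "NetworkTruth",
]

_ALPHABET = np.array(list("ACGT"))


def _lognormal_noise(rng: np.random.Generator, cv: float,
                     size) -> np.ndarray:
    """Mean-one multiplicative noise with the requested CV."""
    if cv == 0.0:
        return np.ones(size)
    sigma2 = math.log1p(cv * cv)
    sigma = math.sqrt(sigma2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=sigma, size=size)


def simulate_expression(
    n_genes: int,
    design: PipelineConfig,
    fraction_affected: float = 0.05,
    log2_effect: float = 1.5,
    replicate_cv: float = 0.15,
    n_replicates: int = 2,
    seed: int = 0,
) -> tuple[ExpressionTable, pd.DataFrame]:
    """Replicate expression table with planted focal up/down effects.

    Baseline abundances are log-normal per gene; affected genes shift
    the focal condition by ±``log2_effect`` (sign drawn per gene)
    against every comparison condition; replicates carry multiplicative
    noise at the stated CV. Returns the table and a truth frame with
    columns gene, planted_effect (signed log2), planted_direction.
    """
    rng = np.random.default_rng(seed)
    genes = [f"g{i:05d}" for i in range(n_genes)]
    baseline = 2.0 ** rng.normal(loc=2.0, scale=2.0, size=n_genes)
    n_affected = int(round(fraction_affected * n_genes))
    affected = rng.choice(n_genes, size=n_affected, replace=False)
    signs = rng.choice([1.0, -1.0], size=n_affected)
    effect = np.zeros(n_genes)
    effect[affected] = signs * log2_effect

    conditions = design.conditions
    columns = {}
    for cond in conditions:
        cond_mean = baseline * (2.0 ** effect
                                if cond == design.focal_condition else 1.0)
        for rep in range(1, n_replicates + 1):
            noise = _lognormal_noise(rng, replicate_cv, n_genes)
            columns[f"{cond}_{rep}"] = cond_mean * noise
    values = pd.DataFrame(columns, index=pd.Index(genes, name="gene"))
    mapping = {col: col.rsplit("_", 1)[0] for col in values.columns}
    table = ExpressionTable(values=values, design=mapping)

    direction = np.where(effect > 0, "up",
                         np.where(effect < 0, "down", "none"))
    truth = pd.DataFrame({
        "gene": genes,
        "planted_effect": effect,
        "planted_direction": direction,
    })
    return table, truth


def simulate_ct(
    relative_abundances: Mapping[str, Mapping[str, float]],
    reference_genes: Sequence[str],
    noise_sd: float = 0.0,
    n_bio: int = 2,
    n_tech: int = 3,
    base_ct: float = 25.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Ct records consistent with the comparative-Ct model.

    ``relative_abundances[gene][condition]`` gives the linear abundance
    (the calibrator condition should carry abundance 1 for planted
    values to be recovered as-is). Ct = base_ct - log2(abundance) +
    N(0, noise_sd); reference genes sit at abundance 1 in every
    condition, up to the same noise. Biological replicates are labeled
    with roman numerals.
    """
    rng = np.random.default_rng(seed)
    romans = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X"]
    if n_bio > len(romans):
        raise ValueError("too many biological replicates")
    conditions = sorted({c for v in relative_abundances.values() for c in v})
    rows = []
    all_genes = list(relative_abundances) + [g for g in reference_genes
                                             if g not in relative_abundances]
    for gene in all_genes:
        for cond in conditions:
            if gene in reference_genes:
                abundance = 1.0
            else:
                abundance = relative_abundances[gene][cond]
            if abundance <= 0:
                raise ValueError(f"abundance must be > 0 for {gene}/{cond}")
            for b in range(n_bio):
                for t in range(1, n_tech + 1):
                    ct = (base_ct - math.log2(abundance)
                          + (rng.normal(0.0, noise_sd) if noise_sd else 0.0))
                    rows.append({"gene": gene, "condition": cond,
                                 "bio_rep": romans[b], "tech_rep": t,
                                 "ct": ct})
    return pd.DataFrame(rows)


@dataclass
class PromoterTruth:
    gene: str
    planted_motif_positions: dict[str, list[int]]
    planted_peak: tuple[int, int]  # offsets within the promoter

    def to_rows(self) -> list[dict]:
        rows = []
        for motif_id, offsets in self.planted_motif_positions.items():
            for off in offsets:
                rows.append({"gene": self.gene, "kind": "motif",
                             "label": motif_id, "start": off,
                             "end": off})
        rows.append({"gene": self.gene, "kind": "peak", "label": "peak",
                     "start": self.planted_peak[0],
                     "end": self.planted_peak[1]})
        return rows


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length)


def _plant_free_sequence(
    rng: np.random.Generator,
    length: int,
    motifs: Mapping[str, str],
    n_instances: int,
    max_tries: int = 60,
) -> tuple[str, dict[str, list[int]]]:
    """Random sequence containing each motif exactly ``n_instances``
    times (both strands counted), at recorded non-overlapping offsets."""
    from .promoter_scan import PromoterRegion, scan_motifs

    max_len = max(len(m) for m in motifs.values())
    for _ in range(max_tries):
        arr = _random_sequence(rng, length)
        seq = "".join(_ALPHABET[arr])
        planted: dict[str, list[int]] = {m: [] for m in motifs}
        taken: list[tuple[int, int]] = []
        ok = True
        for motif_id, motif in motifs.items():
            for _k in range(n_instances):
                for _try in range(200):
                    off = int(rng.integers(0, length - len(motif) + 1))
                    if all(off + len(motif) <= s or off >= e
                           for s, e in taken):
                        break
                else:
                    ok = False
                    break
                seq = seq[:off] + motif + seq[off + len(motif):]
                taken.append((off, off + len(motif)))
                planted[motif_id].append(off)
            if not ok:
                break
        if not ok:
            continue
        region = PromoterRegion(gene="tmp", chrom="tmp", start=0,
                                end=length, strand="+", sequence=seq)
        hits = scan_motifs(region, motifs, both_strands=True)
        found = {m: sorted(h.offset for h in hits if h.motif_id == m
                           and h.strand_of_match == "+") for m in motifs}
        spurious = any(
            found[m] != sorted(planted[m]) for m in motifs
        ) or any(h.strand_of_match == "-" for h in hits)
        if not spurious:
            return seq, {m: sorted(v) for m, v in planted.items()}
    raise RuntimeError(
        "could not generate a collision-free promoter; use longer or "
        "less degenerate motifs")


def simulate_promoters_and_reads(
    n_genes: int,
    promoter_length: int,
    motifs: Mapping[str, str],
    instances_per_motif: int = 2,
    peak_length: int = 400,
    background_depth: float = 1.0,
    peak_enrichment: float = 8.0,
    read_length: int = 50,
    gap: int = 1000,
    seed: int = 0,
) -> tuple[dict[str, str], pd.DataFrame, pd.DataFrame, list[PromoterTruth]]:
    """Genome with planted promoter motifs plus reads enriched at
    planted peaks over a uniform background.

    Genes sit on one chromosome, + strand, promoters back to back with a
    gap; the TSS of gene i is at the right edge of its promoter window.
    Returns (genome, TSS BED frame, reads BED frame, truth records).
    """
    if any(len(m) >= promoter_length for m in motifs.values()):
        raise ValueError("motif length must be below promoter_length")
    if peak_length > promoter_length:
        raise ValueError("peak_length must not exceed promoter_length")
    rng = np.random.default_rng(seed)
    unit = promoter_length + gap
    genome_length = n_genes * unit + gap
    chrom = "chr1"

    pieces = ["".join(_ALPHABET[_random_sequence(rng, gap)])]
    tss_rows = []
    truths = []
    for i in range(n_genes):
        gene = f"g{i:05d}"
        prom_start = gap + i * unit
        seq, planted = _plant_free_sequence(
            rng, promoter_length, motifs, instances_per_motif)
        pieces.append(seq)
        pieces.append("".join(_ALPHABET[_random_sequence(rng, gap)]))
        tss = prom_start + promoter_length
        tss_rows.append({"chrom": chrom, "start": tss, "end": tss + 1,
                         "name": gene, "score": 0, "strand": "+"})
        peak_off = int(rng.integers(0, promoter_length - peak_length + 1))
        truths.append(PromoterTruth(
            gene=gene,
            planted_motif_positions=planted,
            planted_peak=(peak_off, peak_off + peak_length)))

    genome = {chrom: "".join(pieces)}
    assert len(genome[chrom]) == genome_length

    n_background = int(round(background_depth * genome_length / read_length))
    starts = rng.integers(0, genome_length - read_length + 1,
                          size=n_background)
    read_rows = [{"chrom": chrom, "start": int(s), "end": int(s + read_length),
                  "name": f"bg{j}", "score": 0, "strand": "+"}
                 for j, s in enumerate(starts)]
    for truth in truths:
        prom_start = gap + int(truth.gene[1:]) * unit
        peak_lo = prom_start + truth.planted_peak[0]
        peak_hi = prom_start + truth.planted_peak[1]
        n_extra = int(round((peak_enrichment - 1.0) * background_depth
                            * peak_length / read_length))
        extra = rng.integers(peak_lo, max(peak_hi - read_length, peak_lo) + 1,
                             size=n_extra)
        read_rows.extend(
            {"chrom": chrom, "start": int(s), "end": int(s + read_length),
             "name": f"{truth.gene}_peak{j}", "score": 0, "strand": "+"}
            for j, s in enumerate(extra))
    reads = pd.DataFrame(read_rows)
    tss = pd.DataFrame(tss_rows)
    return genome, tss, reads, truths


@dataclass
class NetworkTruth:
    module_nodes: frozenset[str]
    planted_term: str
    edge_prob_within: float
    edge_prob_between: float


def simulate_network_and_go(
    n_nodes: int = 60,
    edge_prob_within: float = 0.5,
    edge_prob_between: float = 0.05,
    planted_module_size: int = 15,
    n_terms: int = 20,
    planted_term: str = "GO:PLANTED",
    background_term_prob: float = 0.08,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, set[str]], set[str], set[str],
           NetworkTruth]:
    """Two-block random scored graph plus GO annotations with one
    planted enriched term.

    The dense module doubles as the analysis sample; the planted term
    annotates every module gene plus background genes at the base rate,
    while the remaining terms annotate genes uniformly at the base rate.
    Returns (edge frame, annotations, sample, universe, truth).
    """
    if planted_module_size > n_nodes:
        raise ValueError("module size exceeds node count")
    rng = np.random.default_rng(seed)
    nodes = [f"p{i:04d}" for i in range(n_nodes)]
    module = set(nodes[:planted_module_size])
    edge_rows = []
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            within = nodes[i] in module and nodes[j] in module
            p = edge_prob_within if within else edge_prob_between
            if rng.random() < p:
                edge_rows.append({
                    "node_a": nodes[i], "node_b": nodes[j],
                    "score": float(rng.uniform(0.15, 1.0))})
    edges = pd.DataFrame(edge_rows, columns=["node_a", "node_b", "score"])

    annotations: dict[str, set[str]] = {n: set() for n in nodes}
    for node in nodes:
        if node in module or rng.random() < background_term_prob:
            annotations[node].add(planted_term)
        for t in range(n_terms - 1):
            if rng.random() < background_term_prob:
                annotations[node].add(f"GO:{t:07d}")
    truth = NetworkTruth(
        module_nodes=frozenset(module), planted_term=planted_term,
        edge_prob_within=edge_prob_within,
        edge_prob_between=edge_prob_between)
    return edges, annotations, set(module), set(nodes), truth


def truth_frame(truths: Iterable[PromoterTruth]) -> pd.DataFrame:
    """Serialize promoter truth records to a flat frame for TSV output."""
    rows: list[dict] = []
    for t in truths:
        rows.extend(t.to_rows())
    return pd.DataFrame(rows)
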