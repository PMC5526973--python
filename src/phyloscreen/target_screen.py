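"""Multi-stage candidate selection and validation.

Stages: an entry screen for unidirectional expression differences
(focal condition vs every comparison condition), a mean-vs-mean fold
threshold, classification against user-supplied reference gene lists,
validation statistics on qPCR/densitometric values, reduced-sample
re-analysis, and the evolutionary-rate (dN/dS) comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .group_stats import (GroupComparison, MWUResult, bh_fdr, compare_groups,
                          min_fold_change, mwu_test)
from .io_cli.config import PipelineConfig
from .io_cli.tables import DesignError, ExpressionTable

__all__ = [
    "ScreenResult",
    "DnDsComparison",
    "entry_screen",
    "screen_statistics",
    "twofold_filter",
    "classify",
    "validate",
    "reduced_sample_reanalysis",
    "compare_dnds",
    "screen_results_frame",
]


@dataclass
class ScreenResult:
    gene: str
    passes_entry: bool
    passes_twofold: bool
    protein_coding: bool
    brain_expressed: bool
    in_reference_lists: frozenset[str]
    category: str  # reproduced | new_candidate | rejected
    stats: GroupComparison | None = None
    below_fold_threshold: bool = False


@dataclass(frozen=True)
class DnDsComparison:
    mwu: MWUResult
    mean_a: float
    mean_b: float
    median_a: float
    median_b: float
    negative_selection: bool  # every dN/dS value < 1


def _comparison_conditions(expr: ExpressionTable,
                           config: PipelineConfig) -> list[str]:
    """Comparison set for the screen: configured comparisons plus the
    control condition when it carries samples."""
    comps = list(config.comparison_conditions)
    ctrl = config.control_condition
    if ctrl and any(c == ctrl for c in expr.design.values()):
        comps.append(ctrl)
    return comps


def entry_screen(expr: ExpressionTable,
                 config: PipelineConfig) -> dict[str, str]:
    """Genes whose focal mean lies strictly above (or below) the mean of
    every comparison condition, mapped to their direction."""
    comps = _comparison_conditions(expr, config)
    for cond in [config.focal_condition, *comps]:
        if len(expr.condition_samples(cond)) < 2:
            raise DesignError(f"condition {cond!r} has fewer than 2 replicates")
    focal = expr.condition_means(config.focal_condition)
    means = {c: expr.condition_means(c) for c in comps}
    above = np.logical_and.reduce([focal > means[c] for c in comps])
    below = np.logical_and.reduce([focal < means[c] for c in comps])
    out: dict[str, str] = {}
    for gene, up, down in zip(expr.genes, above, below):
        if up:
            out[gene] = "up"
        elif down:
            out[gene] = "down"
    return out


def screen_statistics(expr: ExpressionTable, config: PipelineConfig,
                      genes: Sequence[str] | None = None,
                      ) -> dict[str, GroupComparison]:
    """Full contrast statistics per gene, FDR across the tested family.

    The focal sample is tested against the values pooled over the
    non-control comparison conditions (mirroring the validation stages);
    fold changes span all comparison conditions including the control.
    """
    genes = list(genes) if genes is not None else expr.genes
    comps = _comparison_conditions(expr, config)
    stat_conds = list(config.comparison_conditions)
    results: dict[str, GroupComparison] = {}
    for gene in genes:
        focal = expr.condition_values(gene, config.focal_condition)
        by_cond = {c: expr.condition_values(gene, c) for c in stat_conds}
        gc = compare_groups(gene, focal, by_cond, alpha=config.alpha,
                            variant=config.t_variant)
        fold_conds = {c: float(np.mean(expr.condition_values(gene, c)))
                      for c in comps}
        if all(m > 0 for m in fold_conds.values()) and gc.mean_focal > 0:
            folds, mfc, direction, excluded = min_fold_change(
                gc.mean_focal, fold_conds)
            gc.fold_by_condition = folds
            gc.min_fold_change = mfc
            gc.direction = direction
            gc.excluded_conditions = excluded
        results[gene] = gc
    attach_fdr(results)
    return results


def attach_fdr(results: Mapping[str, GroupComparison]) -> None:
    """BH-adjust p-values across one family of comparisons, in place."""
    genes = list(results)
    if not genes:
        return
    fdrs = bh_fdr([results[g].p_two_sided for g in genes])
    for g, f in zip(genes, fdrs):
        results[g].fdr = float(f)


def twofold_filter(candidates: Mapping[str, str],
                   stats: Mapping[str, GroupComparison],
                   config: PipelineConfig) -> set[str]:
    """Retain candidates whose min fold-change is at least the threshold
    in either direction: |log2(min fold)| >= log2(fold_threshold)."""
    log_thr = math.log2(config.fold_threshold)
    kept = set()
    for gene in candidates:
        gc = stats.get(gene)
        if gc is None or not math.isfinite(gc.min_fold_change):
            continue
        if abs(math.log2(gc.min_fold_change)) >= log_thr:
            kept.add(gene)
    return kept


def classify(
    candidates: Mapping[str, str],
    twofold: set[str],
    stats: Mapping[str, GroupComparison],
    reference_lists: Mapping[str, set[str]],
    annotations: pd.DataFrame | None,
    config: PipelineConfig,
) -> list[ScreenResult]:
    """Sort entry-passing genes into reproduced / new_candidate / rejected.

    reproduced: present in at least one reference list with FDR < alpha.
    new_candidate: absent from every list, passes entry + fold threshold,
    and is flagged protein-coding and brain-expressed. Genes that pass
    significance but fail the fold threshold keep an explicit
    ``below_fold_threshold`` flag instead of being dropped silently.
    """
    out = []
    for gene, _direction in sorted(candidates.items()):
        gc = stats.get(gene)
        refs = frozenset(label for label, members in reference_lists.items()
                         if gene in members)
        if annotations is not None and gene in annotations.index:
            coding = bool(annotations.loc[gene, "protein_coding"])
            brain = bool(annotations.loc[gene, "brain_expressed"])
        else:
            coding = brain = False
        passes_twofold = gene in twofold
        significant = gc is not None and not math.isnan(gc.fdr) \
            and gc.fdr < config.alpha
        if refs and significant:
            category = "reproduced"
        elif not refs and passes_twofold and coding and brain:
            category = "new_candidate"
        else:
            category = "rejected"
        out.append(ScreenResult(
            gene=gene,
            passes_entry=True,
            passes_twofold=passes_twofold,
            protein_coding=coding,
            brain_expressed=brain,
            in_reference_lists=refs,
            category=category,
            stats=gc,
            below_fold_threshold=significant and not passes_twofold,
        ))
    return out


def validate(
    values: Mapping[str, Mapping[str, Sequence[float]]],
    config: PipelineConfig,
    comparison_conditions: Sequence[str] | None = None,
) -> dict[str, GroupComparison]:
    """Validation statistics on relative-expression (or densitometric)
    values: ``values[gene][condition]`` holds per-replicate measurements.

    Returns one GroupComparison per gene with FDR adjusted within this
    family. The verdict logic (significant vs large-effect fallback)
    lives in :func:`validation_verdicts` so the two are never merged.
    """
    comps = list(comparison_conditions or config.comparison_conditions)
    results: dict[str, GroupComparison] = {}
    for gene in sorted(values):
        per_cond = values[gene]
        if config.focal_condition not in per_cond:
            raise DesignError(f"gene {gene!r}: no focal-condition values")
        by_cond = {c: per_cond[c] for c in comps if c in per_cond}
        if not by_cond:
            raise DesignError(f"gene {gene!r}: no comparison-condition values")
        results[gene] = compare_groups(
            gene, per_cond[config.focal_condition], by_cond,
            alpha=config.alpha, variant=config.t_variant)
    attach_fdr(results)
    return results


def validation_verdicts(results: Mapping[str, GroupComparison],
                        config: PipelineConfig) -> pd.DataFrame:
    """Per-gene verdict: ``significant`` (FDR < alpha), ``large_effect``
    (non-significant but r above the effect threshold, reported as a
    flagged fallback), or ``not_supported``."""
    rows = []
    for gene, gc in results.items():
        significant = not math.isnan(gc.fdr) and gc.fdr < config.alpha
        large_effect = (not math.isnan(gc.r_effect)
                        and gc.r_effect > config.effect_r_threshold)
        if significant:
            verdict = "significant"
        elif large_effect:
            verdict = "large_effect"
        else:
            verdict = "not_supported"
        rows.append({
            "gene": gene, "verdict": verdict, "fdr": gc.fdr,
            "r_effect": gc.r_effect, "power": gc.power,
            "min_fold_change": gc.min_fold_change,
            "direction": gc.direction,
            "discordant": large_effect and not significant,
        })
    return pd.DataFrame(rows)


def reduced_sample_reanalysis(
    values: Mapping[str, Mapping[str, Sequence[float]]],
    drop_conditions: set[str],
    config: PipelineConfig,
) -> dict[str, GroupComparison]:
    """Re-run :func:`validate` excluding the given comparison conditions.

    N stays unchanged; M shrinks, and the 1/(p*q) term of r uses the
    reduced sizes. An empty drop set reproduces the full analysis.
    """
    remaining = [c for c in config.comparison_conditions
                 if c not in drop_conditions]
    if not remaining:
        raise ValueError("cannot drop every comparison condition")
    return validate(values, config, comparison_conditions=remaining)


def compare_dnds(records: pd.DataFrame) -> DnDsComparison:
    """Compare the two dN/dS columns of a (gene, pair_a, pair_b) table."""
    if len(records) < 2:
        raise ValueError("need at least 2 dN/dS records")
    a = records["dnds_pair_a"].to_numpy(dtype=float)
    b = records["dnds_pair_b"].to_numpy(dtype=float)
    res = mwu_test(a, b)
    return DnDsComparison(
        mwu=res,
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        median_a=float(np.median(a)), median_b=float(np.median(b)),
        negative_selection=bool((a < 1.0).all() and (b < 1.0).all()),
    )


def screen_results_frame(results: Sequence[ScreenResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        gc = r.stats
        rows.append({
            "gene": r.gene,
            "category": r.category,
            "passes_entry": r.passes_entry,
            "passes_twofold": r.passes_twofold,
            "below_fold_threshold": r.below_fold_threshold,
            "protein_coding": r.protein_coding,
            "brain_expressed": r.brain_expressed,
            "reference_lists": ",".join(sorted(r.in_reference_lists)),
            "direction": gc.direction if gc else "",
            "min_fold_change": gc.min_fold_change if gc else math.nan,
            "p_two_sided": gc.p_two_sided if gc else math.nan,
            "fdr": gc.fdr if gc else math.nan,
            "d_av": gc.d_av if gc else math.nan,
            "r_effect": gc.r_effect if gc else math.nan,
            "power": gc.power if gc else math.nan,
        })
    return pd.DataFrame(rows)
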