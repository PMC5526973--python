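"""Entry screen, fold filter, classification, validation, dN/dS tests."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from phyloscreen.io_cli.tables import DesignError, ExpressionTable
from phyloscreen.synthetic_data import simulate_expression
from phyloscreen.target_screen import (compare_dnds, classify, entry_screen,
                                       reduced_sample_reanalysis,
                                       screen_statistics, twofold_filter,
                                       validate, validation_verdicts)

from conftest import PUBLISHED_ROWS


def make_table(gene_rows, conditions=("hsa", "ptr", "mmu", "cja", "vector"),
               n_reps=2):
    columns = [f"{c}_{r}" for c in conditions for r in range(1, n_reps + 1)]
    values = pd.DataFrame(gene_rows, columns=columns)
    values.index = [f"g{i}" for i in range(len(values))]
    design = {col: col.rsplit("_", 1)[0] for col in columns}
    return ExpressionTable(values=values, design=design)


# ------------------------------------------------------------ entry_screen


def test_entry_screen_definitions(config):
    table = make_table([
        [9, 10, 1, 2, 1, 2, 1, 2, 1, 2],   # above all -> up
        [1, 2, 9, 10, 9, 10, 9, 10, 9, 10],  # below all -> down
        [5, 6, 1, 2, 9, 10, 1, 2, 1, 2],   # mixed -> excluded
    ])
    result = entry_screen(table, config)
    assert result == {"g0": "up", "g1": "down"}


def test_entry_screen_control_counts_as_comparison(config):
    # above the three primate conditions but below the vector control
    table = make_table([[5, 6, 1, 2, 1, 2, 1, 2, 9, 10]])
    assert entry_screen(table, config) == {}


def test_entry_screen_requires_replicates(config):
    table = make_table([[1, 2, 3, 4, 5, 6, 7, 8]],
                       conditions=("hsa", "ptr", "mmu", "cja"), n_reps=2)
    single = table.values.drop(columns=["ptr_2"])
    broken = ExpressionTable(values=single,
                             design={c: c.rsplit("_", 1)[0]
                                     for c in single.columns})
    with pytest.raises(DesignError):
        entry_screen(broken, config)


def brute_force_entry(expr, config):
    comps = list(config.comparison_conditions)
    if config.control_condition and config.control_condition in set(
            expr.design.values()):
        comps.append(config.control_condition)
    out = {}
    for gene in expr.genes:
        f = expr.condition_values(gene, config.focal_condition).mean()
        ms = [expr.condition_values(gene, c).mean() for c in comps]
        if all(f > m for m in ms):
            out[gene] = "up"
        elif all(f < m for m in ms):
            out[gene] = "down"
    return out


def test_entry_screen_matches_brute_force_on_synthetic(config):
    table, truth = simulate_expression(
        300, config, fraction_affected=0.1, log2_effect=2.0,
        replicate_cv=0.1, seed=config.seed)
    result = entry_screen(table, config)
    assert result == brute_force_entry(table, config)
    planted = set(truth[truth["planted_direction"] != "none"]["gene"])
    assert planted <= set(result) or \
        len(planted - set(result)) / max(len(planted), 1) < 0.1


# ---------------------------------------------------------- twofold_filter


def test_twofold_filter_boundaries(config):
    table = make_table([
        [40, 42, 1, 2, 1, 2, 1, 2, 1, 2],      # huge fold: retained
        [4.0, 4.0, 2.0, 2.0, 1.0, 1.0, 2.0, 2.0, 2.0, 2.0],  # exactly 2.0
        [3.0, 3.0, 2.0, 2.0, 1.0, 1.0, 2.0, 2.0, 2.0, 2.0],  # min fold 1.5
    ])
    candidates = entry_screen(table, config)
    stats = screen_statistics(table, config, genes=sorted(candidates))
    kept = twofold_filter(candidates, stats, config)
    assert "g0" in kept
    assert "g1" in kept   # boundary inclusive ("at least twofold")
    assert "g2" not in kept


def test_twofold_published_examples(config):
    # min fold 25.657 retained; 0.572 excluded
    values = {
        "SEBOX": PUBLISHED_ROWS["SEBOX"],
        "DCDC2": PUBLISHED_ROWS["DCDC2"],
    }
    stats = {}
    candidates = {}
    for gene, data in values.items():
        from phyloscreen.group_stats import compare_groups
        stats[gene] = compare_groups(gene, data["focal"],
                                     data["by_condition"])
        candidates[gene] = data["direction"]
    kept = twofold_filter(candidates, stats, config)
    assert kept == {"SEBOX"}


# ---------------------------------------------------------------- classify


def test_classify_rules(config):
    table = make_table([
        [8, 9, 1, 2, 1, 2, 1, 2, 1, 2],
        [16, 18, 1, 2, 1, 2, 1, 2, 1, 2],
        [12, 13, 1, 2, 1, 2, 1, 2, 1, 2],
    ])
    candidates = entry_screen(table, config)
    stats = screen_statistics(table, config, genes=sorted(candidates))
    twofold = twofold_filter(candidates, stats, config)
    annotations = pd.DataFrame(
        {"protein_coding": [True, True, False],
         "brain_expressed": [True, True, True]},
        index=["g0", "g1", "g2"])
    reference_lists = {"studyA": {"g0"}}
    results = classify(candidates, twofold, stats, reference_lists,
                       annotations, config)
    by_gene = {r.gene: r for r in results}
    assert by_gene["g0"].category == "reproduced"
    assert by_gene["g1"].category == "new_candidate"
    assert by_gene["g2"].category == "rejected"  # not protein-coding


def test_classify_planted_counts(config):
    table, truth = simulate_expression(
        200, config, fraction_affected=0.15, log2_effect=3.0,
        replicate_cv=0.05, seed=9)
    candidates = entry_screen(table, config)
    stats = screen_statistics(table, config, genes=sorted(candidates))
    twofold = twofold_filter(candidates, stats, config)
    planted = sorted(truth[truth["planted_direction"] != "none"]["gene"])
    reference_lists = {"ref": set(planted[:10])}
    annotations = pd.DataFrame(
        {"protein_coding": True, "brain_expressed": True},
        index=list(table.genes))
    results = classify(candidates, twofold, stats, reference_lists,
                       annotations, config)
    by_cat = {}
    for r in results:
        by_cat.setdefault(r.category, set()).add(r.gene)
    # planted reference genes with significant FDR land in reproduced,
    # the other planted genes in new_candidate
    assert by_cat.get("reproduced", set()) <= set(planted[:10])
    assert len(by_cat.get("new_candidate", set()) & set(planted[10:])) >= \
        0.9 * len(planted[10:])


# ---------------------------------------------------------------- validate


def _row_values(row, conditions=None):
    data = PUBLISHED_ROWS[row]
    vals = {"hsa": data["focal"], **data["by_condition"]}
    if conditions:
        vals = {c: v for c, v in vals.items() if c in conditions}
    return vals


def test_validate_bace2_significant(config_no_control):
    values = {name: _row_values(name) for name in
              ("BACE2", "SEBOX", "GABRE", "MSN_rna", "MYH8", "MYH13",
               "FOXL1", "DCDC2", "CDH4_rna", "PHOX2B", "PTPRQ",
               "NURR1", "TMEM200A")}
    results = validate(values, config_no_control)
    verdicts = validation_verdicts(results, config_no_control)
    bace2 = results["BACE2"]
    assert bace2.r_effect == pytest.approx(0.735, abs=1e-3)
    assert bace2.min_fold_change == pytest.approx(0.355, abs=1e-3)
    v = verdicts.set_index("gene")
    assert v.loc["BACE2", "verdict"] == "significant"


def test_validate_nurr1_discordant(config_no_control):
    values = {name: _row_values(name) for name in
              ("BACE2", "SEBOX", "GABRE", "MSN_rna", "MYH8", "MYH13",
               "FOXL1", "DCDC2", "CDH4_rna", "PHOX2B", "PTPRQ",
               "NURR1", "TMEM200A")}
    results = validate(values, config_no_control)
    verdicts = validation_verdicts(results, config_no_control).set_index("gene")
    nurr1 = results["NURR1"]
    assert nurr1.r_effect == pytest.approx(0.743, abs=1e-3)
    if verdicts.loc["NURR1", "verdict"] == "large_effect":
        assert verdicts.loc["NURR1", "discordant"]


def test_validate_constant_gene(config_no_control):
    values = {"flat": {"hsa": [1.0, 1.0],
                       "ptr": [1.0, 1.0], "mmu": [1.0, 1.0],
                       "cja": [1.0, 1.0]}}
    results = validate(values, config_no_control)
    verdicts = validation_verdicts(results, config_no_control)
    assert results["flat"].r_effect == pytest.approx(0.0)
    assert verdicts.loc[0, "verdict"] == "not_supported"


# ----------------------------------------------- reduced_sample_reanalysis


def test_reduced_reanalysis_bace2(config_no_control):
    values = {"BACE2": _row_values("BACE2")}
    reduced = reduced_sample_reanalysis(values, {"cja"}, config_no_control)
    gc = reduced["BACE2"]
    assert gc.M == 4
    assert gc.r_effect == pytest.approx(0.986, abs=1e-3)


def test_reduced_reanalysis_nurr1_min_fold(config_no_control):
    values = {"NURR1": _row_values("NURR1")}
    reduced = reduced_sample_reanalysis(values, {"cja"}, config_no_control)
    assert reduced["NURR1"].min_fold_change == pytest.approx(0.044, abs=1e-3)


def test_reduced_empty_drop_is_identity(config_no_control):
    values = {"BACE2": _row_values("BACE2"), "SEBOX": _row_values("SEBOX")}
    full = validate(values, config_no_control)
    reduced = reduced_sample_reanalysis(values, set(), config_no_control)
    for gene in values:
        assert full[gene] == reduced[gene]


def test_reduced_cannot_drop_all(config_no_control):
    values = {"BACE2": _row_values("BACE2")}
    with pytest.raises(ValueError):
        reduced_sample_reanalysis(values, {"ptr", "mmu", "cja"},
                                  config_no_control)


# ------------------------------------------------------------ compare_dnds


def test_dnds_identical_columns():
    df = pd.DataFrame({"gene": list("abcd"),
                       "dnds_pair_a": [0.1, 0.2, 0.3, 0.4],
                       "dnds_pair_b": [0.1, 0.2, 0.3, 0.4]})
    cmp = compare_dnds(df)
    assert cmp.mwu.p_two_sided >= 0.9
    assert cmp.mean_a == pytest.approx(cmp.mean_b)
    assert cmp.negative_selection


def test_dnds_enumeration_oracle():
    df = pd.DataFrame({"gene": list("abc"),
                       "dnds_pair_a": [0.1, 0.2, 0.3],
                       "dnds_pair_b": [0.4, 0.5, 0.6]})
    cmp = compare_dnds(df)
    # all 3 values of column a precede column b: 1 of C(6,3)=20 orderings
    # each tail -> two-sided p = 2/20
    assert cmp.mwu.p_two_sided == pytest.approx(0.1)


def test_dnds_positive_selection_flag():
    df = pd.DataFrame({"gene": list("ab"),
                       "dnds_pair_a": [0.5, 1.4],
                       "dnds_pair_b": [0.2, 0.3]})
    assert not compare_dnds(df).negative_selection
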