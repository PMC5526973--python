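"""Shared fixtures: published replicate values and a default config."""

from __future__ import annotations

import pytest

from phyloscreen import PipelineConfig

# Published per-replicate measurement rows (focal condition "hsa" vs three
# comparison conditions), with the printed min fold-change, effect-size r
# and post-hoc power for each contrast. "*_red" rows are the reduced-sample
# re-analyses that drop one comparison condition.
PUBLISHED_ROWS = {
    "BACE2": {
        "focal": [0.177, 0.211],
        "by_condition": {"ptr": [1.875, 1.973], "mmu": [1.598, 1.999],
                         "cja": [0.595, 0.497]},
        "min_fold": 0.355, "r": 0.735, "power": 0.725, "direction": "down",
    },
    "BACE2_red": {
        "focal": [0.177, 0.211],
        "by_condition": {"ptr": [1.875, 1.973], "mmu": [1.598, 1.999]},
        "min_fold": 0.108, "r": 0.986, "power": 1.000, "direction": "down",
    },
    "DCDC2": {
        "focal": [0.289, 0.230],
        "by_condition": {"ptr": [0.562, 0.879], "mmu": [0.433, 0.474],
                         "cja": [0.889, 0.800]},
        "min_fold": 0.572, "r": 0.767, "power": 0.803, "direction": "down",
    },
    "CDH4_rna": {
        "focal": [0.284, 0.387],
        "by_condition": {"ptr": [1.128, 1.661], "mmu": [3.003, 3.565],
                         "cja": [2.437, 2.154]},
        "min_fold": 0.241, "r": 0.808, "power": 0.895, "direction": "down",
    },
    "FOXL1": {
        "focal": [0.378, 0.308],
        "by_condition": {"ptr": [3.404, 2.443], "mmu": [3.140, 3.661],
                         "cja": [2.235, 1.790]},
        "min_fold": 0.170, "r": 0.897, "power": 0.997, "direction": "down",
    },
    "GABRE": {
        "focal": [0.014, 0.012],
        "by_condition": {"ptr": [0.423, 0.455], "mmu": [0.606, 0.562],
                         "cja": [0.361, 0.348]},
        "min_fold": 0.037, "r": 0.933, "power": 1.000, "direction": "down",
    },
    "MSN_rna": {
        "focal": [0.111, 0.180],
        "by_condition": {"ptr": [1.217, 1.825], "mmu": [0.981, 1.237],
                         "cja": [1.391, 1.474]},
        "min_fold": 0.131, "r": 0.931, "power": 1.000, "direction": "down",
    },
    "MYH8": {
        "focal": [0.253, 0.293],
        "by_condition": {"ptr": [1.369, 1.620], "mmu": [1.337, 1.285],
                         "cja": [1.974, 2.067]},
        "min_fold": 0.208, "r": 0.923, "power": 1.000, "direction": "down",
    },
    "MYH13": {
        "focal": [0.044, 0.049],
        "by_condition": {"ptr": [1.011, 0.897], "mmu": [0.565, 0.536],
                         "cja": [0.808, 0.826]},
        "min_fold": 0.084, "r": 0.922, "power": 1.000, "direction": "down",
    },
    "NURR1": {
        "focal": [0.092, 0.131],
        "by_condition": {"ptr": [2.742, 2.331], "mmu": [3.386, 3.915],
                         "cja": [0.840, 1.007]},
        "min_fold": 0.121, "r": 0.743, "power": 0.745, "direction": "down",
    },
    "NURR1_red": {
        "focal": [0.092, 0.131],
        "by_condition": {"ptr": [2.742, 2.331], "mmu": [3.386, 3.915]},
        "min_fold": 0.044, "r": 0.943, "power": 0.999, "direction": "down",
    },
    "PHOX2B": {
        "focal": [0.091, 0.083],
        "by_condition": {"ptr": [0.942, 0.598], "mmu": [0.877, 0.447],
                         "cja": [2.598, 3.094]},
        "min_fold": 0.131, "r": 0.589, "power": 0.411, "direction": "down",
    },
    "PHOX2B_red": {
        "focal": [0.091, 0.083],
        "by_condition": {"ptr": [0.942, 0.598], "mmu": [0.877, 0.447]},
        "min_fold": 0.131, "r": 0.873, "power": 0.899, "direction": "down",
    },
    "PTPRQ": {
        "focal": [0.147, 0.131],
        "by_condition": {"ptr": [0.401, 0.300], "mmu": [1.357, 1.119],
                         "cja": [0.331, 0.377]},
        "min_fold": 0.397, "r": 0.556, "power": 0.357, "direction": "down",
    },
    "PTPRQ_red": {
        "focal": [0.147, 0.131],
        "by_condition": {"ptr": [0.401, 0.300], "cja": [0.331, 0.377]},
        "min_fold": 0.397, "r": 0.950, "power": 1.000, "direction": "down",
    },
    "SEBOX": {
        "focal": [4.423, 4.172],
        "by_condition": {"ptr": [0.105, 0.143], "mmu": [0.143, 0.169],
                         "cja": [0.153, 0.182]},
        "min_fold": 25.657, "r": 0.998, "power": 1.000, "direction": "up",
    },
    "TMEM200A": {
        "focal": [0.124, 0.088],
        "by_condition": {"ptr": [1.110, 0.839], "mmu": [1.567, 1.207],
                         "cja": [0.326, 0.483]},
        "min_fold": 0.262, "r": 0.731, "power": 0.715, "direction": "down",
    },
    "TMEM200A_red": {
        "focal": [0.124, 0.088],
        "by_condition": {"ptr": [1.110, 0.839], "mmu": [1.567, 1.207]},
        "min_fold": 0.109, "r": 0.921, "power": 0.987, "direction": "down",
    },
    # densitometric (protein-level) rows, two-replicate design
    "CDH4_protein": {
        "focal": [0.431, 0.650],
        "by_condition": {"ptr": [0.952, 1.171], "mmu": [1.018, 1.045],
                         "cja": [1.336, 1.213]},
        "min_fold": None, "r": 0.861, "power": 0.976, "direction": "down",
    },
    "MSN_protein": {
        "focal": [0.051, 0.116],
        "by_condition": {"ptr": [0.695, 0.728], "mmu": [2.046, 1.694],
                         "cja": [2.562, 2.228]},
        "min_fold": None, "r": 0.775, "power": 0.822, "direction": "down",
    },
    "BACE2_protein": {
        "focal": [0.358, 0.348],
        "by_condition": {"ptr": [0.749, 0.731], "mmu": [1.071, 0.989]},
        "min_fold": None, "r": 0.900, "power": 0.958, "direction": "down",
    },
}


@pytest.fixture
def config() -> PipelineConfig:
    return PipelineConfig(
        focal_condition="hsa",
        comparison_conditions=["ptr", "mmu", "cja"],
        control_condition="vector",
        reference_genes=["REF1", "REF2"],
        seed=11,
    )


@pytest.fixture
def config_no_control() -> PipelineConfig:
    return PipelineConfig(
        focal_condition="hsa",
        comparison_conditions=["ptr", "mmu", "cja"],
        seed=11,
    )
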