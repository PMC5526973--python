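"""Writers mirroring the readers; floats keep 6 significant digits."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .tables import ExpressionTable

__all__ = [
    "write_expression_table",
    "write_ct_table",
    "write_result_table",
    "write_gene_list",
    "write_fasta",
    "write_bed",
    "write_bedgraph",
]

FLOAT_FORMAT = "%.6g"


def _fmt(v) -> str:
    if isinstance(v, (float, np.floating)):
        return FLOAT_FORMAT % v
    return str(v)


def write_expression_table(table: ExpressionTable, path: str | Path) -> None:
    table.values.to_csv(path, sep="\t", index_label="gene",
                        float_format=FLOAT_FORMAT)


def write_ct_table(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def write_result_table(df: pd.DataFrame, path: str | Path,
                       index: bool = False) -> None:
    """Generic tab-separated result table with stable float formatting."""
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(genes)))


def write_fasta(sequences: Mapping[str, str], path: str | Path,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    cols = ["chrom", "start", "end", "name", "score", "strand"]
    df[cols].to_csv(path, sep="\t", index=False, header=False)


def write_bedgraph(chrom: str, start: int, values: np.ndarray,
                   path: str | Path) -> None:
    """Write per-base values as a run-length-collapsed bedGraph."""
    with open(path, "w") as fh:
        if len(values) == 0:
            return
        run_start = 0
        current = values[0]
        for i in range(1, len(values) + 1):
            if i == len(values) or values[i] != current:
                fh.write(f"{chrom}\t{start + run_start}\t{start + i}\t"
                         f"{_fmt(current)}\n")
                if i < len(values):
                    run_start = i
                    current = values[i]
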