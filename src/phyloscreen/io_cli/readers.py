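"""Readers for the plain-text input formats of the pipeline.

All tabular inputs are tab-separated; interval inputs are 6-column BED
(0-based, half-open); sequences are FASTA. Gene and protein identifiers
are opaque case-sensitive strings: no symbol normalization is performed.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO

from .config import PipelineConfig
from .tables import DesignError, ExpressionTable, FormatError

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression_table",
    "read_ct_table",
    "read_relative_expression",
    "read_edge_table",
    "read_gene_list",
    "read_annotation_flags",
    "read_go_annotations",
    "read_dnds_table",
    "read_bed",
    "read_fasta",
    "read_motifs",
]

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_expression_table(path: str | Path,
                          design: PipelineConfig | dict[str, str],
                          ) -> ExpressionTable:
    """Read a gene x sample TSV and bind samples to conditions.

    With a :class:`PipelineConfig`, sample columns must be named
    ``<condition>_<replicate>``; with an explicit mapping, every column
    must appear as a key.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    for col in df.columns:
        series = pd.to_numeric(df[col], errors="coerce")
        bad = series.isna() | ~np.isfinite(series) | (series < 0)
        if bad.any():
            gene = df.index[bad.to_numpy().nonzero()[0][0]]
            raise FormatError(
                f"{path}: invalid expression value at gene {gene!r}, "
                f"sample {col!r}")
        df[col] = series.astype(float)
    if isinstance(design, PipelineConfig):
        known = design.conditions
        mapping = {}
        for col in df.columns:
            cond = col.rsplit("_", 1)[0]
            if cond not in known:
                raise DesignError(
                    f"{path}: sample {col!r} does not match any condition "
                    f"in {known}")
            mapping[col] = cond
    else:
        mapping = dict(design)
        unknown = [c for c in df.columns if c not in mapping]
        if unknown:
            raise DesignError(f"{path}: samples not in design: {unknown}")
    return ExpressionTable(values=df, design=mapping)


def read_ct_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "condition": str,
                                            "bio_rep": str})
    required = ["gene", "condition", "bio_rep", "tech_rep", "ct"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: Ct table missing columns {missing}")
    if not np.isfinite(df["ct"].to_numpy(dtype=float)).all():
        raise FormatError(f"{path}: non-finite Ct value")
    return df


def read_relative_expression(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "condition": str,
                                            "bio_rep": str})
    required = ["gene", "condition", "bio_rep", "value"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: relative-expression table missing {missing}")
    vals = df["value"].to_numpy(dtype=float)
    if not np.isfinite(vals).all() or (vals <= 0).any():
        raise FormatError(f"{path}: relative expression values must be > 0")
    return df


def read_edge_table(path: str | Path) -> nx.Graph:
    """Read a (node, node, combined score) TSV into a simple scored graph.

    Duplicate pairs (in either orientation) collapse to the maximum
    score; self-pairs are dropped with a warning. Scores must lie in
    (0, 1].
    """
    graph = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(
                    f"{path}:{lineno}: expected 3 tab-separated columns")
            a, b, raw = parts
            if lineno == 1:
                try:
                    float(raw)
                except ValueError:
                    continue  # header line
            score = float(raw)
            if not 0.0 < score <= 1.0:
                raise FormatError(
                    f"{path}:{lineno}: score {score} outside (0, 1]")
            if a == b:
                logger.warning("%s:%d: self-pair %r dropped", path, lineno, a)
                graph.add_node(a)
                continue
            if graph.has_edge(a, b):
                score = max(score, graph[a][b]["score"])
            graph.add_edge(a, b, score=score)
    return graph


def read_gene_list(path: str | Path) -> set[str]:
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return out


def read_annotation_flags(path: str | Path) -> pd.DataFrame:
    """Per-gene boolean flags: gene, protein_coding, brain_expressed."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    for col in ("gene", "protein_coding", "brain_expressed"):
        if col not in df.columns:
            raise FormatError(f"{path}: annotation table missing {col!r}")
    for col in ("protein_coding", "brain_expressed"):
        df[col] = df[col].astype(bool)
    return df.set_index("gene")


def read_go_annotations(path: str | Path) -> dict[str, set[str]]:
    """Gene -> set of annotated terms from a two-column (gene, term) TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "gene" not in df.columns or "term" not in df.columns:
        raise FormatError(f"{path}: annotation table needs 'gene' and 'term'")
    out: dict[str, set[str]] = {}
    for gene, term in zip(df["gene"], df["term"]):
        out.setdefault(gene, set()).add(term)
    return out


def read_dnds_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    required = ["gene", "dnds_pair_a", "dnds_pair_b"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: dN/dS table missing columns {missing}")
    vals = df[["dnds_pair_a", "dnds_pair_b"]].to_numpy(dtype=float)
    if (vals < 0).any() or not np.isfinite(vals).all():
        raise FormatError(f"{path}: dN/dS values must be finite and >= 0")
    return df


def read_bed(path: str | Path) -> pd.DataFrame:
    """6-column BED (chrom, start, end, name, score, strand)."""
    df = pd.read_csv(path, sep="\t", header=None, names=BED_COLUMNS,
                     dtype={"chrom": str, "name": str, "strand": str},
                     comment="#")
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    if (df["start"] < 0).any() or (df["end"] < df["start"]).any():
        raise FormatError(f"{path}: invalid BED interval")
    bad = ~df["strand"].isin(["+", "-"])
    if bad.any():
        raise FormatError(f"{path}: strand must be '+' or '-'")
    return df


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def read_motifs(path: str | Path) -> dict[str, str]:
    """Motif file: FASTA, or lines of ``id<TAB>sequence``.

    Motifs may use the IUPAC nucleotide alphabet.
    """
    text = Path(path).read_text()
    if text.lstrip().startswith(">"):
        motifs = read_fasta(path)
    else:
        motifs = {}
        for lineno, line in enumerate(text.splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(
                    f"{path}:{lineno}: expected 'id<TAB>sequence'")
            motifs[parts[0]] = parts[1].upper()
    for mid, seq in motifs.items():
        if not seq:
            raise FormatError(f"{path}: motif {mid!r} is empty")
        if set(seq) - set("ACGTRYSWKMBDHVN"):
            raise FormatError(f"{path}: motif {mid!r} has non-IUPAC letters")
    return motifs
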