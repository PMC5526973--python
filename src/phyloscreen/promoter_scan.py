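"""Promoter extraction, exact IUPAC motif scanning, and read coverage.

Promoters are the fixed-length window immediately upstream of each TSS,
returned promoter-5'->3' (minus-strand windows are reverse complemented).
Motif matching is exact with IUPAC degeneracy allowed in the motif only;
coverage over a promoter is normalized against the expected depth under
uniform genome-wide read placement.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PromoterRegion",
    "MotifHit",
    "CoverageTrack",
    "reverse_complement",
    "extract_promoters",
    "scan_motifs",
    "promoter_coverage",
    "cooccurrence_report",
]

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

# IUPAC code -> concrete bases it may match; N in the subject sequence
# never matches because these classes contain only A/C/G/T.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PromoterRegion:
    gene: str
    chrom: str
    start: int  # 0-based half-open genomic interval
    end: int
    strand: str
    sequence: str
    truncated: bool = False

    def __post_init__(self) -> None:
        if len(self.sequence) != self.end - self.start:
            raise ValueError(
                f"{self.gene}: sequence length {len(self.sequence)} != "
                f"interval span {self.end - self.start}")


@dataclass(frozen=True)
class MotifHit:
    gene: str
    motif_id: str
    offset: int  # 0-based position within the promoter sequence
    strand_of_match: str
    length: int


@dataclass
class CoverageTrack:
    gene: str
    raw: np.ndarray  # per-base read depth over the promoter
    normalized: np.ndarray

    @property
    def total_mass(self) -> int:
        return int(self.raw.sum())


def extract_promoters(
    tss_records: pd.DataFrame,
    genome: Mapping[str, str],
    promoter_length: int = 5000,
) -> list[PromoterRegion]:
    """Extract the ``promoter_length`` bases upstream of each TSS.

    ``tss_records`` needs columns chrom, start, strand, name, where
    ``start`` is the TSS coordinate (0-based). A + strand gene with TSS
    t yields the genomic interval [t-L, t); a - strand gene yields
    [t+1, t+1+L) reverse complemented, so the returned sequence always
    runs promoter-5'->3'. Windows hitting a chromosome edge are
    truncated and flagged.
    """
    regions = []
    for rec in tss_records.itertuples():
        if rec.chrom not in genome:
            raise KeyError(f"chromosome {rec.chrom!r} not in genome")
        chrom_seq = genome[rec.chrom]
        tss = int(rec.start)
        if rec.strand == "+":
            start, end = tss - promoter_length, tss
        else:
            start, end = tss + 1, tss + 1 + promoter_length
        truncated = start < 0 or end > len(chrom_seq)
        start_c, end_c = max(start, 0), min(end, len(chrom_seq))
        if truncated:
            logger.warning("promoter of %s truncated to [%d, %d)",
                           rec.name, start_c, end_c)
        seq = chrom_seq[start_c:end_c].upper()
        if rec.strand == "-":
            seq = reverse_complement(seq)
        regions.append(PromoterRegion(
            gene=rec.name, chrom=rec.chrom, start=start_c, end=end_c,
            strand=rec.strand, sequence=seq, truncated=truncated))
    return regions


def _motif_regex(motif: str) -> re.Pattern:
    pattern = "".join(
        f"[{IUPAC[c]}]" if len(IUPAC[c]) > 1 else IUPAC[c] for c in motif)
    return re.compile(f"(?=({pattern}))")  # lookahead: overlapping matches


def scan_motifs(
    region: PromoterRegion,
    motifs: Mapping[str, str],
    both_strands: bool = True,
) -> list[MotifHit]:
    """All exact occurrences of each motif in the promoter sequence.

    Overlapping occurrences are each reported. With ``both_strands``
    the reverse complement of every motif is scanned too and labeled
    '-'; offsets always refer to the promoter sequence as given.
    """
    hits: list[MotifHit] = []
    for motif_id, motif in motifs.items():
        if not motif:
            raise ValueError(f"motif {motif_id!r} is empty")
        motif = motif.upper()
        strands = [("+", motif)]
        if both_strands:
            rc = reverse_complement(motif)
            strands.append(("-", rc))
        for strand, pattern in strands:
            if strand == "-" and pattern == motif:
                continue  # palindromic: one strand suffices
            for m in _motif_regex(pattern).finditer(region.sequence):
                hits.append(MotifHit(
                    gene=region.gene, motif_id=motif_id, offset=m.start(),
                    strand_of_match=strand, length=len(motif)))
    hits.sort(key=lambda h: (h.offset, h.motif_id, h.strand_of_match))
    return hits


def promoter_coverage(
    reads: pd.DataFrame,
    region: PromoterRegion,
    total_mapped: int,
    genome_length: int,
    read_length: int,
) -> CoverageTrack:
    """Per-base read depth over the promoter, normalized to the expected
    depth under uniform genome-wide placement.

    ``reads`` holds aligned intervals (chrom, start, end). The
    normalization constant is total_mapped * read_length / genome_length.
    """
    if total_mapped <= 0 or genome_length <= 0 or read_length <= 0:
        raise ValueError("totals must be positive")
    span = region.end - region.start
    diff = np.zeros(span + 1, dtype=np.int64)
    if len(reads):
        sub = reads[(reads["chrom"] == region.chrom)
                    & (reads["end"] > region.start)
                    & (reads["start"] < region.end)]
    else:
        sub = reads.reindex(columns=["chrom", "start", "end"])
    for s, e in zip(sub["start"].to_numpy(), sub["end"].to_numpy()):
        lo = max(int(s) - region.start, 0)
        hi = min(int(e) - region.start, span)
        diff[lo] += 1
        diff[hi] -= 1
    raw = np.cumsum(diff[:-1])
    expected = total_mapped * read_length / genome_length
    normalized = raw / expected
    if region.strand == "-":
        # promoter coordinates run 5'->3' on the minus strand
        raw = raw[::-1].copy()
        normalized = normalized[::-1].copy()
    return CoverageTrack(gene=region.gene, raw=raw, normalized=normalized)


def cooccurrence_report(
    hits: Sequence[MotifHit],
    track: CoverageTrack,
    enrichment_threshold: float = 1.0,
) -> dict:
    """Per-gene summary of motif hits vs covered positions.

    A hit overlaps coverage when any base of its interval has normalized
    coverage above the threshold.
    """
    for h in hits:
        if h.gene != track.gene:
            raise ValueError("hits and track refer to different genes")
    covered = track.normalized > enrichment_threshold
    overlapping = [
        h for h in hits
        if covered[h.offset:h.offset + h.length].any()
    ]
    return {
        "gene": track.gene,
        "n_motif_hits": len(hits),
        "n_overlapping_hits": len(overlapping),
        "hit_positions": [(h.motif_id, h.offset, h.strand_of_match)
                          for h in hits],
        "overlap_positions": [(h.motif_id, h.offset, h.strand_of_match)
                              for h in overlapping],
    }
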