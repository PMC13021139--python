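"""Strand-aware 5' end-motif extraction and the 256-motif frequency matrix.

Nuclease cleavage leaves characteristic k-mers at cfDNA fragment ends
(DNASE1L3 favors CC-starts such as CCCA, CAD/DFFB favors A-ends).  Each
retained read contributes the 4-mer at its 5' terminus: forward-strand reads
read it off the first four stored bases; reverse-strand reads take the
reference at the fragment's 5' genomic end (= ref_end) and
reverse-complement it.  Reads clipped at the 5' end or yielding motifs with
ambiguous bases are excluded.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
import pysam

from .ionmodel import AlignedFragment, Strand, revcomp

#: the 256 4-mers in fixed lexicographic order (AAAA ... TTTT)
MOTIFS: tuple[str, ...] = tuple(
    "".join(p) for p in itertools.product("ACGT", repeat=4))
MOTIF_INDEX: dict[str, int] = {m: i for i, m in enumerate(MOTIFS)}

BASES = ("A", "C", "G", "T")


class ReferenceAccessor:
    """Uppercasing FASTA accessor (soft-masked bases are not a sequence
    difference for motif purposes)."""

    def __init__(self, fasta_path):
        self._fa = pysam.FastaFile(str(fasta_path))

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._fa.references

    def chromosomes(self) -> list[str]:
        return list(self._fa.references)

    def length(self, chrom: str) -> int:
        return self._fa.get_reference_length(chrom)

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return self._fa.fetch(chrom, start, end).upper()

    def close(self) -> None:
        self._fa.close()


def extract_end_motif(record: AlignedFragment, reference) -> Optional[str]:
    """The 4-mer at the fragment's 5' end, or None when excluded.

    ``reference`` needs ``fetch(chrom, start, end)``, ``length(chrom)`` and
    ``__contains__``.
    """
    if not record.is_mapped or record.chrom is None:
        return None
    if record.clip_5prime > 0:
        return None
    if record.strand is Strand.FORWARD:
        if len(record.query_sequence) < 4:
            return None
        motif = record.query_sequence[:4].upper()
    else:
        if record.chrom not in reference:
            return None
        if record.ref_end - 4 < 0 or record.ref_end > reference.length(record.chrom):
            return None
        window = reference.fetch(record.chrom, record.ref_end - 4, record.ref_end)
        if len(window) < 4:
            return None
        motif = revcomp(window)
    if any(b not in "ACGT" for b in motif):
        return None
    return motif


def count_end_motifs(
    records: Iterable[AlignedFragment], reference,
) -> tuple[Counter, int]:
    """Motif counts over a record stream; returns (counts, n_reads_used)."""
    counts: Counter = Counter()
    used = 0
    for rec in records:
        motif = extract_end_motif(rec, reference)
        if motif is not None:
            counts[motif] += 1
            used += 1
    return counts, used


@dataclass
class MotifMatrix:
    """samples x 256 matrix of normalized 5' 4-mer frequencies."""

    sample_ids: list[str]
    freq: np.ndarray          # shape (n_samples, 256), rows sum to 1 (or 0)
    n_reads_used: np.ndarray  # per-sample retained-motif counts

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.freq, index=self.sample_ids, columns=list(MOTIFS))
        df.insert(0, "n_reads_used", self.n_reads_used)
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="sample")

    @classmethod
    def from_tsv(cls, path) -> "MotifMatrix":
        df = pd.read_csv(path, sep="\t", index_col="sample")
        return cls(
            sample_ids=list(df.index),
            freq=df[list(MOTIFS)].to_numpy(float),
            n_reads_used=df["n_reads_used"].to_numpy(int),
        )


def build_motif_matrix(
    per_sample_counts: Mapping[str, Mapping[str, int]],
) -> MotifMatrix:
    """Normalize per-sample motif counts into the fixed 256-column layout.

    Motifs not observed in a sample are exactly 0.  A sample with zero
    retained motifs gets a zero row (flagged by n_reads_used == 0).
    """
    sample_ids = list(per_sample_counts)
    freq = np.zeros((len(sample_ids), len(MOTIFS)))
    n_used = np.zeros(len(sample_ids), dtype=int)
    for i, sid in enumerate(sample_ids):
        for motif, count in per_sample_counts[sid].items():
            if motif not in MOTIF_INDEX:
                raise ValueError(f"invalid motif {motif!r}")
            freq[i, MOTIF_INDEX[motif]] = count
        total = freq[i].sum()
        n_used[i] = int(total)
        if total > 0:
            freq[i] /= total
    return MotifMatrix(sample_ids=sample_ids, freq=freq, n_reads_used=n_used)


def end_base_composition(matrix: MotifMatrix) -> pd.DataFrame:
    """Per-sample 5'-terminal base frequencies: the first-character marginal
    of the motif matrix (exact)."""
    comp = np.zeros((len(matrix.sample_ids), 4))
    for j, motif in enumerate(MOTIFS):
        comp[:, BASES.index(motif[0])] += matrix.freq[:, j]
    return pd.DataFrame(comp, index=matrix.sample_ids, columns=list(BASES))
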