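"""Fragment-length QC statistics and size-class stratification.

cfDNA fragment lengths are multimodal (mononucleosomal ~167 bp,
dinucleosomal ~320 bp, plus a shorter tumor-enriched mode); the pipeline
summarizes the native read-length distribution and stratifies reads into
three classes: short (<150 bp), intermediate (150-300 bp, both endpoints
included), long (>300 bp).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .ionmodel import AlignedFragment

SHORT_MAX = 150   # lengths strictly below are "short"
LONG_MIN = 300    # lengths strictly above are "long"

CLASS_NAMES = ("short", "intermediate", "long")


def classify_length(length: int) -> str:
    if length < SHORT_MAX:
        return "short"
    if length > LONG_MIN:
        return "long"
    return "intermediate"


@dataclass
class SizeClassProfile:
    n_short: int
    n_intermediate: int
    n_long: int

    @property
    def total(self) -> int:
        return self.n_short + self.n_intermediate + self.n_long

    @property
    def proportions(self) -> tuple[float, float, float]:
        t = self.total
        if t == 0:
            return (0.0, 0.0, 0.0)
        return (self.n_short / t, self.n_intermediate / t, self.n_long / t)


@dataclass
class LengthSummary:
    n_reads: int
    mean: float
    median: float
    n50: float
    hist_edges: np.ndarray = field(default_factory=lambda: np.zeros(0))
    hist_counts: np.ndarray = field(default_factory=lambda: np.zeros(0, int))

    @classmethod
    def empty(cls) -> "LengthSummary":
        return cls(n_reads=0, mean=float("nan"), median=float("nan"),
                   n50=float("nan"))


def n50(lengths: Sequence[int]) -> float:
    """Smallest length L such that bases in reads >= L cover half the total,
    found by descending cumulative sum; a member of the input multiset."""
    arr = np.sort(np.asarray(lengths))[::-1]
    csum = np.cumsum(arr)
    half = csum[-1] / 2.0
    idx = int(np.searchsorted(csum, half))
    return float(arr[min(idx, len(arr) - 1)])


def length_summary(lengths: Sequence[int], bin_width: int = 10) -> LengthSummary:
    lengths = np.asarray(list(lengths), dtype=float)
    if lengths.size == 0:
        return LengthSummary.empty()
    if np.any(lengths <= 0):
        raise ValueError("lengths must be positive")
    edges = np.arange(0, lengths.max() + bin_width, bin_width)
    if edges[-1] <= lengths.max():
        edges = np.append(edges, edges[-1] + bin_width)
    counts, edges = np.histogram(lengths, bins=edges)
    return LengthSummary(
        n_reads=int(lengths.size),
        mean=float(lengths.mean()),
        median=float(np.median(lengths)),
        n50=n50(lengths),
        hist_edges=edges,
        hist_counts=counts,
    )


def size_class_profile(lengths: Iterable[int]) -> SizeClassProfile:
    counts = {"short": 0, "intermediate": 0, "long": 0}
    for length in lengths:
        counts[classify_length(length)] += 1
    return SizeClassProfile(counts["short"], counts["intermediate"],
                            counts["long"])


def split_by_size_class(
    records: Iterable[AlignedFragment],
) -> dict[str, list[AlignedFragment]]:
    """Partition records into the three size classes by query_length."""
    streams: dict[str, list[AlignedFragment]] = {n: [] for n in CLASS_NAMES}
    for rec in records:
        streams[classify_length(rec.query_length)].append(rec)
    return streams
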