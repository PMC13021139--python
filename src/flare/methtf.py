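"""Marker-level methylation summaries and beta-mixture tumor-fraction
estimation.

Each read overlapping a cancer-specific methylation marker contributes a
(methylated, total) CpG-call pair (x, y); the methylation level of tumor and
normal reads at a marker is modeled by Beta(alpha_t, beta_t) and
Beta(alpha_n, beta_n).  Integrating the per-read binomial against the class
beta prior gives the beta-binomial kernel (the combinatorial coefficient
cancels in the tumor/normal ratio):

    L(x, y | a, b) = B(a + x, b + y - x) / B(a, b)

The tumor fraction theta maximizes the weighted mixture log-likelihood

    l(theta) = sum_j w_j log(theta L_t(j) + (1 - theta) L_n(j))

over a dense grid on [0, 1], where w_j = d_j / (lambda + d_j) with
d_j = |log L_t - log L_n| damps uninformative reads (lambda = 0.5 default;
lambda = 0 reduces to the unweighted likelihood).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import betaln

from .ionmodel import AlignedFragment, is_autosome

log = logging.getLogger(__name__)

_FRACTION_EPS = 0.01
_VAR_FLOOR = 1e-4
_S_FLOOR = 0.01


@dataclass(frozen=True)
class MarkerRegion:
    """A methylation marker interval with tumor/normal beta parameters."""

    marker_id: str
    chrom: str
    start: int
    end: int
    alpha_t: float = 1.0
    beta_t: float = 1.0
    alpha_n: float = 1.0
    beta_n: float = 1.0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"marker {self.marker_id}: empty interval")
        for p in (self.alpha_t, self.beta_t, self.alpha_n, self.beta_n):
            if p <= 0:
                raise ValueError(f"marker {self.marker_id}: non-positive "
                                 "beta parameter")

    @property
    def mean_tumor(self) -> float:
        return self.alpha_t / (self.alpha_t + self.beta_t)

    @property
    def mean_normal(self) -> float:
        return self.alpha_n / (self.alpha_n + self.beta_n)

    @property
    def informativeness(self) -> float:
        return abs(self.mean_tumor - self.mean_normal)


@dataclass(frozen=True)
class ReadMethylationSummary:
    read_id: str
    marker_id: str
    x: int           # methylated CpG calls in the marker
    y: int           # total CpG calls in the marker
    mean_prob: float


@dataclass
class TumorFractionEstimate:
    theta_hat: float
    grid: np.ndarray
    curve: np.ndarray            # penalized log-likelihood at each grid point
    n_reads_used: int
    n_markers_used: int
    lam: float
    uninformative: bool = False


def read_marker_bed(path) -> list[MarkerRegion]:
    """BED4+ marker panel: chrom, start, end, marker_id
    [, alpha_t, beta_t, alpha_n, beta_n].  Markers must be non-overlapping
    (checked after sorting)."""
    markers: list[MarkerRegion] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"marker BED needs >= 4 columns: {line!r}")
            kwargs = {}
            if len(parts) >= 8:
                kwargs = dict(alpha_t=float(parts[4]), beta_t=float(parts[5]),
                              alpha_n=float(parts[6]), beta_n=float(parts[7]))
            markers.append(MarkerRegion(
                marker_id=parts[3], chrom=parts[0],
                start=int(parts[1]), end=int(parts[2]), **kwargs))
    markers.sort(key=lambda m: (m.chrom, m.start))
    for a, b in zip(markers, markers[1:]):
        if a.chrom == b.chrom and b.start < a.end:
            raise ValueError(f"overlapping markers {a.marker_id}/{b.marker_id}")
    return markers


def write_marker_bed(markers: Sequence[MarkerRegion], path) -> None:
    with open(path, "w") as fh:
        for m in markers:
            fh.write(f"{m.chrom}\t{m.start}\t{m.end}\t{m.marker_id}\t"
                     f"{m.alpha_t}\t{m.beta_t}\t{m.alpha_n}\t{m.beta_n}\n")


class _MarkerIndex:
    def __init__(self, markers: Sequence[MarkerRegion]):
        self.by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[MarkerRegion]]] = {}
        for chrom in {m.chrom for m in markers}:
            sub = sorted((m for m in markers if m.chrom == chrom),
                         key=lambda m: m.start)
            starts = np.array([m.start for m in sub])
            ends = np.array([m.end for m in sub])
            self.by_chrom[chrom] = (starts, ends, sub)

    def find(self, chrom: str, pos: int) -> Optional[MarkerRegion]:
        loc = self.by_chrom.get(chrom)
        if loc is None:
            return None
        starts, ends, sub = loc
        j = int(np.searchsorted(starts, pos, side="right")) - 1
        if j >= 0 and pos < ends[j]:
            return sub[j]
        return None


def summarize_marker_methylation(
    records: Iterable[AlignedFragment],
    markers: Sequence[MarkerRegion],
    call_threshold: float = 0.5,
    autosomes_only: bool = True,
) -> tuple[list[ReadMethylationSummary], pd.DataFrame]:
    """Per-read, per-marker (x, y) methylation counts and the pooled
    marker-mean table (sum x / sum y over reads).

    A call counts as methylated iff probability >= call_threshold.  Records
    on non-autosomal chromosomes or with undecodable MM/ML (meth_calls is
    None) are excluded, as are reads with no calls in any marker.
    """
    index = _MarkerIndex(markers)
    summaries: list[ReadMethylationSummary] = []
    agg: dict[str, list[int]] = {m.marker_id: [0, 0] for m in markers}
    for rec in records:
        if rec.meth_calls is None or not rec.meth_calls:
            continue
        if autosomes_only and not is_autosome(rec.chrom):
            continue
        per_marker: dict[str, list] = {}
        for call in rec.meth_calls:
            if call.genomic_pos is None:
                continue
            marker = index.find(rec.chrom, call.genomic_pos)
            if marker is None:
                continue
            entry = per_marker.setdefault(marker.marker_id, [0, 0, 0.0])
            entry[1] += 1
            entry[2] += call.probability
            if call.probability >= call_threshold:
                entry[0] += 1
        for marker_id, (x, y, psum) in per_marker.items():
            summaries.append(ReadMethylationSummary(
                read_id=rec.read_id, marker_id=marker_id,
                x=x, y=y, mean_prob=psum / y))
            agg[marker_id][0] += x
            agg[marker_id][1] += y
    rows = []
    for m in markers:
        x, y = agg[m.marker_id]
        rows.append({"marker_id": m.marker_id, "chrom": m.chrom,
                     "start": m.start, "end": m.end,
                     "n_calls": y,
                     "mean_methylation": x / y if y else np.nan})
    return summaries, pd.DataFrame(rows)


def train_marker_betas(
    table: pd.DataFrame,
    min_samples: int = 3,
) -> dict[str, tuple[float, float, float, float]]:
    """Method-of-moments beta parameters per marker and class.

    ``table`` columns: sample, class in {tumor, normal}, marker_id, fraction.
    Fractions are clamped to [eps, 1-eps]; the variance is floored at 1e-4
    and the common factor s = m(1-m)/v - 1 at 0.01.  Markers lacking
    ``min_samples`` per class are dropped with a warning.
    """
    out: dict[str, tuple[float, float, float, float]] = {}
    for marker_id, sub in table.groupby("marker_id"):
        params = {}
        for cls in ("tumor", "normal"):
            fr = sub.loc[sub["class"] == cls, "fraction"].to_numpy(float)
            if len(fr) < min_samples:
                params = None
                break
            fr = np.clip(fr, _FRACTION_EPS, 1 - _FRACTION_EPS)
            m = float(fr.mean())
            v = max(float(fr.var(ddof=1)), _VAR_FLOOR)
            s = max(m * (1 - m) / v - 1.0, _S_FLOOR)
            params[cls] = (m * s, (1 - m) * s)
        if params is None:
            log.warning("marker %s dropped: a class has < %d samples",
                        marker_id, min_samples)
            continue
        out[marker_id] = (*params["tumor"], *params["normal"])
    return out


def log_read_class_likelihood(x, y, alpha, beta) -> np.ndarray:
    """log of the beta-binomial kernel B(a+x, b+y-x) / B(a, b)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return betaln(alpha + x, beta + y - x) - betaln(alpha, beta)


def read_class_likelihood(x: int, y: int, alpha: float, beta: float) -> float:
    return float(np.exp(log_read_class_likelihood(x, y, alpha, beta)))


def estimate_tumor_fraction(
    summaries: Sequence[ReadMethylationSummary],
    markers: Mapping[str, MarkerRegion] | Sequence[MarkerRegion],
    lam: float = 0.5,
    grid_step: float = 5e-4,
) -> TumorFractionEstimate:
    """Grid maximization of the weighted beta-mixture log-likelihood.

    Ties on the grid break toward smaller theta.  If every read has zero
    weight (lam > 0 and all reads uninformative) theta_hat = 0 with the
    ``uninformative`` flag set.
    """
    if not summaries:
        raise ValueError("no usable read summaries")
    marker_map = (markers if isinstance(markers, Mapping)
                  else {m.marker_id: m for m in markers})
    lt = np.empty(len(summaries))
    ln = np.empty(len(summaries))
    used_markers = set()
    for j, s in enumerate(summaries):
        m = marker_map[s.marker_id]
        lt[j] = log_read_class_likelihood(s.x, s.y, m.alpha_t, m.beta_t)
        ln[j] = log_read_class_likelihood(s.x, s.y, m.alpha_n, m.beta_n)
        used_markers.add(s.marker_id)
    d = np.abs(lt - ln)
    if lam > 0:
        w = d / (lam + d)
    else:
        w = np.ones_like(d)

    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    grid = np.minimum(grid, 1.0)
    curve = np.empty(len(grid))
    uninformative = bool(np.all(w == 0))
    if uninformative:
        curve.fill(0.0)
        theta_hat = 0.0
    else:
        with np.errstate(divide="ignore"):
            log_grid = np.log(grid)
            log_1m = np.log1p(-grid)
        # chunk over the grid to bound memory
        for lo in range(0, len(grid), 256):
            hi = min(lo + 256, len(grid))
            a = log_grid[lo:hi, None] + lt[None, :]
            b = log_1m[lo:hi, None] + ln[None, :]
            curve[lo:hi] = np.sum(w[None, :] * np.logaddexp(a, b), axis=1)
        theta_hat = float(grid[int(np.argmax(curve))])

    return TumorFractionEstimate(
        theta_hat=theta_hat, grid=grid, curve=curve,
        n_reads_used=len(summaries), n_markers_used=len(used_markers),
        lam=lam, uninformative=uninformative,
    )


def export_cftools_table(
    marker_means: Mapping[str, pd.DataFrame],
    theta_by_sample: Mapping[str, float],
    means_path,
    theta_path,
) -> None:
    """Tab-delimited marker-by-sample means and per-sample tumor/normal
    fractions, with deterministic column order."""
    samples = list(marker_means)
    merged: Optional[pd.DataFrame] = None
    for sid in samples:
        df = marker_means[sid][["marker_id", "chrom", "start", "end",
                                "mean_methylation"]].rename(
            columns={"mean_methylation": sid})
        merged = df if merged is None else merged.merge(
            df, on=["marker_id", "chrom", "start", "end"], how="outer")
    if merged is None:
        merged = pd.DataFrame(
            columns=["marker_id", "chrom", "start", "end"])
    merged.to_csv(means_path, sep="\t", index=False)

    rows = [{"sample": sid, "tumor_fraction": theta,
             "normal_fraction": 1.0 - theta}
            for sid, theta in theta_by_sample.items()]
    pd.DataFrame(rows, columns=["sample", "tumor_fraction",
                                "normal_fraction"]).to_csv(
        theta_path, sep="\t", index=False)
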