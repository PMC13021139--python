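"""Bin-level coverage normalization and HMM copy-number / tumor-fraction
inference for shallow cfDNA sequencing.

Reads are counted in fixed genomic bins, GC-corrected by local regression,
and normalized against a panel of normals to per-bin log2 ratios.  A hidden
Markov model over copy states c in {0, 1, 2, 3} with Gaussian emissions
centered at

    mu_c(n, phi) = log2( (2 n + (1 - n) c) / (2 n + (1 - n) phi) )

(n = normal fraction, phi = tumor ploidy) is fitted by EM from a grid of
restarts of the normal-fraction parameter (0.95, 0.99, 0.995, 0.999) with
ploidy restarted at 2; the restart with the highest penalized log-likelihood
is reported and tumor fraction is 1 - n_hat.  The EM is a MAP-EM: a weak
Beta prior on n centered at the restart value keeps the aberrant-state means
identified when the genome is effectively flat (see docs/methods.md).
Subclonal states are not modeled and the maximum copy number is 3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import betaln
from statsmodels.nonparametric.smoothers_lowess import lowess

from .ionmodel import AlignedFragment

log = logging.getLogger(__name__)

STATES = np.array([0, 1, 2, 3])
#: chain-start distribution; the neutral diploid state is favored so that
#: a flat genome (all emission means collapsing as n -> 1) decodes as
#: diploid rather than by an arbitrary tie-break
INIT_STATE_PROBS = np.array([0.05, 0.10, 0.75, 0.10])
RESTART_NORMAL_FRACTIONS = (0.95, 0.99, 0.995, 0.999)
PLOIDY_RESTART = 2.0
PLOIDY_BOUNDS = (1.5, 3.0)
_NUM_FLOOR = 1e-3   # floor on 2n + (1-n)c to keep the c=0 mean finite
_PRIOR_STRENGTH = 2.0


@dataclass
class GenomeBins:
    """Sorted, non-overlapping fixed bins with GC content."""

    frame: pd.DataFrame  # columns: chrom, start, end, gc

    def __post_init__(self) -> None:
        df = self.frame
        for col in ("chrom", "start", "end", "gc"):
            if col not in df.columns:
                raise ValueError(f"bins missing column {col!r}")
        if ((df["gc"] < 0) | (df["gc"] > 1)).any():
            raise ValueError("gc must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.frame)

    @classmethod
    def from_reference(cls, reference, width: int) -> "GenomeBins":
        """Tile every chromosome of a reference accessor into ``width`` bins
        (last partial bin dropped) and compute per-bin GC."""
        rows = []
        for chrom in reference.chromosomes():
            clen = reference.length(chrom)
            for start in range(0, clen - width + 1, width):
                seq = reference.fetch(chrom, start, start + width)
                acgt = sum(seq.count(b) for b in "ACGT")
                gc = (seq.count("G") + seq.count("C")) / max(acgt, 1)
                rows.append({"chrom": chrom, "start": start,
                             "end": start + width, "gc": gc})
        return cls(pd.DataFrame(rows))

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "GenomeBins":
        return cls(pd.read_csv(path, sep="\t"))


def bin_reads(
    records: Iterable[AlignedFragment], bins: GenomeBins,
) -> tuple[np.ndarray, int]:
    """Count records by the bin containing ref_start.  Records on
    chromosomes absent from the bins go to the ``unbinned`` tally."""
    df = bins.frame
    counts = np.zeros(len(df), dtype=float)
    unbinned = 0
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        by_chrom[chrom] = (sub["start"].to_numpy(), sub["end"].to_numpy(),
                           sub.index.to_numpy())
    for rec in records:
        loc = by_chrom.get(rec.chrom)
        if loc is None:
            unbinned += 1
            continue
        starts, ends, idx = loc
        j = int(np.searchsorted(starts, rec.ref_start, side="right")) - 1
        if j >= 0 and rec.ref_start < ends[j]:
            counts[idx[j]] += 1
        else:
            unbinned += 1
    return counts, unbinned


def correct_gc(
    raw_counts: np.ndarray,
    gc: np.ndarray,
    span: float = 0.3,
    gc_bounds: tuple[float, float] = (0.2, 0.8),
) -> tuple[np.ndarray, np.ndarray]:
    """GC-correct bin counts by a lowess fit of count vs GC.

    corrected_i = raw_i / f(gc_i), rescaled so the median corrected count
    equals the median raw count on usable bins.  Bins with GC outside
    ``gc_bounds`` or zero coverage are masked (corrected = NaN).
    Returns (corrected, usable_mask).
    """
    raw = np.asarray(raw_counts, dtype=float)
    gc = np.asarray(gc, dtype=float)
    mask = (raw > 0) & (gc >= gc_bounds[0]) & (gc <= gc_bounds[1])
    corrected = np.full_like(raw, np.nan)
    if mask.sum() < 2:
        return corrected, mask
    if np.ptp(gc[mask]) < 1e-9:
        # degenerate constant GC: correction is identity up to scale
        corrected[mask] = raw[mask]
        return corrected, mask
    fit = lowess(raw[mask], gc[mask], frac=span, return_sorted=True)
    fx, fy = fit[:, 0], np.maximum(fit[:, 1], 1e-9)
    f = np.interp(gc[mask], fx, fy)
    adj = raw[mask] / f
    med = np.median(adj)
    if med > 0:
        adj *= np.median(raw[mask]) / med
    corrected[mask] = adj
    return corrected, mask


def normalize_pon(
    corrected: np.ndarray, pon: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Median-scaled log2 ratio of corrected counts against the panel of
    normals; bins with PoN 0 or masked correction are masked."""
    corrected = np.asarray(corrected, dtype=float)
    pon = np.asarray(pon, dtype=float)
    mask = np.isfinite(corrected) & (corrected > 0) & np.isfinite(pon) & (pon > 0)
    if not mask.any():
        raise ValueError("all bins masked: no usable coverage")
    log2_ratio = np.full_like(corrected, np.nan)
    med_c = np.median(corrected[mask])
    med_p = np.median(pon[mask])
    log2_ratio[mask] = np.log2(
        (corrected[mask] / med_c) / (pon[mask] / med_p))
    return log2_ratio, mask


def expected_log_ratio(c, n: float, phi: float):
    """Emission mean mu_c(n, phi) = log2((2n + (1-n)c) / (2n + (1-n)phi)).

    The neutral state c=2 has mean 0 whenever phi = 2, for every n.
    """
    c = np.asarray(c, dtype=float)
    num = np.maximum(2.0 * n + (1.0 - n) * c, _NUM_FLOOR)
    den = np.maximum(2.0 * n + (1.0 - n) * phi, _NUM_FLOOR)
    out = np.log2(num / den)
    return out if out.ndim else float(out)


@dataclass
class CNVSolution:
    states: np.ndarray           # per usable bin, NaN-masked bins get -1
    segments: pd.DataFrame       # chrom, start_bin, end_bin, state (+coords)
    n_hat: float
    phi_hat: float
    log_likelihood: float        # penalized (MAP) objective used for selection
    data_log_likelihood: float
    sigma: float
    restart_grid: list[tuple[float, float]]
    restart_log_likelihoods: list[float]
    chosen_restart: int
    n_iter: int
    converged: bool

    @property
    def tumor_fraction(self) -> float:
        return 1.0 - self.n_hat


def _log_transition_matrix(e: float = 1e-6) -> np.ndarray:
    k = len(STATES)
    T = np.full((k, k), e)
    np.fill_diagonal(T, 1.0 - (k - 1) * e)
    return np.log(T)


def _emission_logpdf(obs: np.ndarray, means: np.ndarray, var: float) -> np.ndarray:
    return (-0.5 * np.log(2 * np.pi * var)
            - (obs[:, None] - means[None, :]) ** 2 / (2 * var))


def forward_backward(
    logB: np.ndarray, log_trans: np.ndarray, log_init: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Posterior state marginals and log-likelihood for one chain.

    logB: (T, K) emission log-densities.  Scaled forward-backward in the
    probability domain (per-position renormalization); exact up to float
    error (cross-checked against explicit path enumeration in the tests).
    """
    T, K = logB.shape
    m = logB.max(axis=1)
    B = np.exp(logB - m[:, None])
    trans = np.exp(log_trans)
    init = np.exp(log_init)

    alpha = np.empty((T, K))
    scale = np.empty(T)
    a = init * B[0]
    scale[0] = a.sum()
    alpha[0] = a / scale[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ trans) * B[t]
        scale[t] = a.sum()
        alpha[t] = a / scale[t]
    beta = np.empty((T, K))
    beta[-1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (trans @ (B[t + 1] * beta[t + 1])) / scale[t + 1]
    ll = float(np.sum(np.log(scale)) + np.sum(m))
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    return gamma, ll


def viterbi(
    logB: np.ndarray, log_trans: np.ndarray, log_init: np.ndarray,
) -> np.ndarray:
    T, K = logB.shape
    delta = np.zeros((T, K))
    back = np.zeros((T, K), dtype=int)
    delta[0] = log_init + logB[0]
    for t in range(1, T):
        scores = delta[t - 1][:, None] + log_trans
        back[t] = np.argmax(scores, axis=0)
        delta[t] = logB[t] + np.max(scores, axis=0)
    path = np.zeros(T, dtype=int)
    path[-1] = int(np.argmax(delta[-1]))
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1][path[t + 1]]
    return path


def _beta_log_prior(n: float, n0: float, strength: float = _PRIOR_STRENGTH) -> float:
    a = 1.0 + strength * n0
    b = 1.0 + strength * (1.0 - n0)
    n = min(max(n, 1e-9), 1 - 1e-9)
    return float((a - 1) * np.log(n) + (b - 1) * np.log1p(-n)
                 - betaln(a, b))


def _chain_slices(chroms: np.ndarray) -> list[slice]:
    """Contiguous runs of equal chromosome label (chain resets)."""
    slices = []
    start = 0
    for i in range(1, len(chroms) + 1):
        if i == len(chroms) or chroms[i] != chroms[i - 1]:
            slices.append(slice(start, i))
            start = i
    return slices


def fit_cnv_hmm(
    log2_ratio: np.ndarray,
    chroms: Optional[Sequence[str]] = None,
    mask: Optional[np.ndarray] = None,
    bins: Optional[GenomeBins] = None,
    restarts: Sequence[float] = RESTART_NORMAL_FRACTIONS,
    phi0: float = PLOIDY_RESTART,
    e_transition: float = 1e-3,
    tol: float = 1e-6,
    max_iter: int = 200,
    min_usable_bins: int = 50,
    exclude_chroms_from_updates: tuple[str, ...] = ("chrX", "X"),
) -> CNVSolution:
    """MAP-EM fit of the copy-state HMM; the restart with the highest
    penalized log-likelihood is reported.

    ``chroms`` labels each bin; chromosome boundaries reset the chain and
    chromosomes in ``exclude_chroms_from_updates`` (sex chromosome baseline)
    are decoded but excluded from parameter updates.
    """
    obs_all = np.asarray(log2_ratio, dtype=float)
    n_bins = len(obs_all)
    if chroms is None and bins is not None:
        chroms = bins.frame["chrom"].to_numpy()
    if chroms is None:
        chroms = np.array(["chrom"] * n_bins)
    chroms = np.asarray(chroms)
    if mask is None:
        mask = np.isfinite(obs_all)
    else:
        mask = np.asarray(mask, dtype=bool) & np.isfinite(obs_all)
    obs = obs_all[mask]
    chrom_used = chroms[mask]
    if len(obs) < min_usable_bins:
        raise ValueError(f"only {len(obs)} usable bins (< {min_usable_bins})")

    update_w = np.array([c not in exclude_chroms_from_updates
                         for c in chrom_used], dtype=float)
    if update_w.sum() < min_usable_bins:
        update_w = np.ones_like(update_w)

    log_trans = _log_transition_matrix(e_transition)
    log_init = np.log(INIT_STATE_PROBS)
    slices = _chain_slices(chrom_used)

    def e_step(n, phi, var, ltrans):
        means = expected_log_ratio(STATES, n, phi)
        logB = _emission_logpdf(obs, means, var)
        gamma = np.zeros_like(logB)
        ll = 0.0
        for sl in slices:
            g, l = forward_backward(logB[sl], ltrans, log_init)
            gamma[sl] = g
            ll += l
        return gamma, ll

    # robust noise-scale initialization from successive differences
    # (insensitive to the planted copy-number structure)
    if len(obs) > 1:
        mad = np.median(np.abs(np.diff(obs)))
        sd0 = max(mad / np.sqrt(2.0) * 1.4826, 0.01)
    else:
        sd0 = 0.1

    def m_step(gamma, n, phi, var, phi_free, n0):
        """(n, phi) update via the closed-form-moment expected squared
        residual, scanned on a global grid (the joint Q surface has
        EM-trapping local optima) then polished; variance closed form."""
        w = gamma * update_w[:, None]
        s0 = w.sum(axis=0)
        s1 = w.T @ obs
        s2 = w.T @ (obs ** 2)

        def neg_q(params):
            nn, pp = params
            means = expected_log_ratio(STATES, nn, pp)
            q = np.sum(s2 - 2.0 * means * s1 + means ** 2 * s0)
            return q / (2 * var) - _beta_log_prior(nn, n0)

        phi_bounds = PLOIDY_BOUNDS if phi_free else (phi, phi)
        ngrid = np.linspace(1e-4, 1 - 1e-6, 201)
        pgrid = (np.linspace(*PLOIDY_BOUNDS, 61) if phi_free
                 else np.array([phi]))
        nn, pp = np.meshgrid(ngrid, pgrid, indexing="ij")
        num = np.maximum(2 * nn[..., None]
                         + (1 - nn[..., None]) * STATES, _NUM_FLOOR)
        den = np.maximum(2 * nn + (1 - nn) * pp, _NUM_FLOOR)
        mu_grid = np.log2(num / den[..., None])
        q_grid = np.sum(s2 - 2 * mu_grid * s1 + mu_grid ** 2 * s0,
                        axis=-1) / (2 * var)
        a0 = 1.0 + _PRIOR_STRENGTH * n0
        b0 = 1.0 + _PRIOR_STRENGTH * (1.0 - n0)
        q_grid -= ((a0 - 1) * np.log(nn) + (b0 - 1) * np.log1p(-nn)
                   - betaln(a0, b0))
        gi, gj = np.unravel_index(np.argmin(q_grid), q_grid.shape)
        best_np, best_val = (n, phi), neg_q([n, phi])
        for x0 in [(float(ngrid[gi]), float(pgrid[gj])), (n, phi)]:
            res = minimize(neg_q, x0=list(x0), method="L-BFGS-B",
                           bounds=[(1e-4, 1 - 1e-6), phi_bounds])
            if res.fun < best_val:
                best_val = float(res.fun)
                best_np = (float(res.x[0]), float(res.x[1]))
        n, phi = best_np
        means = expected_log_ratio(STATES, n, phi)
        sq = (obs[:, None] - means[None, :]) ** 2
        var = max(float(np.sum(gamma * sq) / np.sum(gamma)), 1e-6)
        return n, phi, var

    # a weakly sticky chain for the very first responsibilities, so the
    # initial segmentation is emission-driven: at high normal-fraction
    # restarts the state means are nearly degenerate and a fully sticky
    # chain would merge neutral and aberrant segments, trapping the EM
    log_trans_warm = _log_transition_matrix(0.1)

    def run_em(n_init, n0):
        n, phi = float(n_init), float(phi0)
        var = max(sd0 ** 2, 1e-6)
        gamma, _ = e_step(n, phi, var, log_trans_warm)
        n, phi, var = m_step(gamma, n, phi, var, False, n0)

        prev_pll = -np.inf
        n_iter = 0
        converged = False
        # phase 1 keeps the ploidy at its restart value so the normal
        # fraction and segmentation settle first; phase 2 frees phi inside
        # PLOIDY_BOUNDS.  Widening the M-step feasible set preserves the
        # monotonicity of the penalized log-likelihood.
        phi_free = False
        gamma, ll = e_step(n, phi, var, log_trans)
        pll = ll + _beta_log_prior(n, n0)
        for n_iter in range(1, max_iter + 1):
            if pll < prev_pll - 1e-8:
                raise RuntimeError(
                    "EM penalized log-likelihood decreased "
                    f"({prev_pll} -> {pll}): update bug")
            if prev_pll > -np.inf and (pll - prev_pll) < tol * abs(prev_pll):
                if phi_free:
                    converged = True
                    break
                phi_free = True
            prev_pll = pll
            n, phi, var = m_step(gamma, n, phi, var, phi_free, n0)
            gamma, ll = e_step(n, phi, var, log_trans)
            pll = ll + _beta_log_prior(n, n0)
        return {"n": n, "phi": phi, "var": var, "pll": pll,
                "ll": ll, "n_iter": n_iter, "converged": converged}

    results = []
    for n0 in restarts:
        # EM is basin-limited from high-n starts when aberrant segments are
        # short, so each restart (which fixes the prior center) tries a few
        # initial normal fractions and keeps the best penalized solution
        best = None
        for n_init in dict.fromkeys((float(n0), 0.8, 0.6)):
            cand = run_em(n_init, n0)
            if best is None or cand["pll"] > best["pll"]:
                best = cand
        results.append(best)

    plls = [r["pll"] for r in results]
    chosen = int(np.argmax(plls))
    best = results[chosen]
    n, phi, var = best["n"], best["phi"], best["var"]

    means = expected_log_ratio(STATES, n, phi)
    logB = _emission_logpdf(obs, means, var)
    path = np.zeros(len(obs), dtype=int)
    for sl in slices:
        path[sl] = viterbi(logB[sl], log_trans, log_init)

    states = np.full(n_bins, -1, dtype=int)
    states[mask] = STATES[path]

    seg_rows = []
    used_idx = np.flatnonzero(mask)
    start = 0
    for i in range(1, len(obs) + 1):
        boundary = (i == len(obs)
                    or chrom_used[i] != chrom_used[i - 1]
                    or path[i] != path[i - 1])
        if boundary:
            row = {"chrom": chrom_used[start],
                   "start_bin": int(used_idx[start]),
                   "end_bin": int(used_idx[i - 1]) + 1,
                   "state": int(STATES[path[start]]),
                   "n_bins": i - start}
            if bins is not None:
                row["start"] = int(bins.frame.iloc[used_idx[start]]["start"])
                row["end"] = int(bins.frame.iloc[used_idx[i - 1]]["end"])
            seg_rows.append(row)
            start = i
    segments = pd.DataFrame(seg_rows)

    return CNVSolution(
        states=states,
        segments=segments,
        n_hat=n,
        phi_hat=phi,
        log_likelihood=best["pll"],
        data_log_likelihood=best["ll"],
        sigma=float(np.sqrt(var)),
        restart_grid=[(r, phi0) for r in restarts],
        restart_log_likelihoods=plls,
        chosen_restart=chosen,
        n_iter=best["n_iter"],
        converged=best["converged"],
    )


def run_cnv(
    records: Iterable[AlignedFragment],
    bins: GenomeBins,
    pon: np.ndarray,
    **fit_kwargs,
) -> tuple[CNVSolution, pd.DataFrame]:
    """Counts -> GC correction -> PoN log2 ratio -> HMM fit.

    Returns the solution and the per-bin table (chrom, start, end,
    raw, corrected, log2_ratio, state).
    """
    raw, unbinned = bin_reads(records, bins)
    if unbinned:
        log.info("%d reads on unbinned chromosomes", unbinned)
    corrected, cmask = correct_gc(raw, bins.frame["gc"].to_numpy())
    l2r, mask = normalize_pon(corrected, np.asarray(pon, dtype=float))
    sol = fit_cnv_hmm(l2r, chroms=bins.frame["chrom"].to_numpy(),
                      mask=mask, bins=bins, **fit_kwargs)
    table = bins.frame.copy()
    table["raw"] = raw
    table["corrected"] = corrected
    table["log2_ratio"] = l2r
    table["state"] = sol.states
    return sol, table
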