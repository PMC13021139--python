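"""NMF decomposition of the end-motif matrix into latent fragmentation profiles.

The samples x 256 motif-frequency matrix V is factorized as V ~ W H with
W >= 0 (per-sample profile contributions) and H >= 0 (per-profile motif
compositions), using Lee-Seung multiplicative updates on the Frobenius
objective.  Stability is assessed over an ensemble of random restarts
(default 100): each run assigns every sample to its dominant profile
(argmax of its W row); the consensus matrix holds co-assignment frequencies
and its cophenetic correlation summarizes rank stability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from .endmotif import MOTIFS, MotifMatrix

log = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass
class NMFResult:
    W: np.ndarray                 # samples x k, L1-compensated
    H: np.ndarray                 # k x 256, rows L1-normalized
    k: int
    objective: float              # 0.5 * ||V - WH||_F^2 of the best run
    n_runs: int
    best_run_seed: int
    consensus: np.ndarray         # samples x samples co-assignment freq
    cophenetic: float
    objectives: np.ndarray        # per-iteration objective of the best run
    zero_rows: list[int] = field(default_factory=list)
    run_objectives: np.ndarray = field(default_factory=lambda: np.zeros(0))


def _mu_nmf(
    V: np.ndarray, k: int, rng: np.random.Generator,
    tol: float = 1e-6, max_iter: int = 2000,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One multiplicative-update run from uniform-random initialization.

    Returns (W, H, per-iteration objectives).  The Frobenius objective is
    non-increasing across iterations (Lee-Seung).
    """
    n, m = V.shape
    scale = np.sqrt(V.mean() / k) if V.mean() > 0 else 1.0
    W = rng.uniform(0.0, 1.0, size=(n, k)) * scale + _EPS
    H = rng.uniform(0.0, 1.0, size=(k, m)) * scale + _EPS

    objectives = []
    prev = np.inf
    for _ in range(max_iter):
        H *= (W.T @ V) / (W.T @ W @ H + _EPS)
        W *= (V @ H.T) / (W @ (H @ H.T) + _EPS)
        obj = 0.5 * float(np.sum((V - W @ H) ** 2))
        objectives.append(obj)
        if prev < np.inf and (prev - obj) < tol * max(prev, _EPS):
            break
        prev = obj
    return W, H, np.asarray(objectives)


def _consensus_and_cophenetic(
    labels: np.ndarray,
) -> tuple[np.ndarray, float]:
    """labels: n_runs x n_samples dominant-profile assignments."""
    n_runs, n = labels.shape
    consensus = np.zeros((n, n))
    for r in range(n_runs):
        same = labels[r][:, None] == labels[r][None, :]
        consensus += same
    consensus /= n_runs
    np.fill_diagonal(consensus, 1.0)
    if n_runs == 1 or n < 3:
        return consensus, 1.0
    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    if np.allclose(condensed.std(), 0.0):
        return consensus, 1.0
    Z = linkage(condensed, method="average")
    coph, _ = cophenet(Z, condensed)
    return consensus, float(coph)


def nmf_factorize(
    V,
    k: int,
    n_runs: int = 100,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 2000,
) -> NMFResult:
    """Best-of-``n_runs`` NMF; run r is seeded with ``seed + r``.

    The reported (W, H) comes from the run with the lowest final objective.
    H rows are L1-normalized afterwards with W rescaled compensatorily, so
    the product W H is unchanged.  Zero rows of V are flagged and excluded
    from the factorization (their W rows are zero).
    """
    sample_ids = None
    if isinstance(V, MotifMatrix):
        sample_ids = V.sample_ids
        V = V.freq
    V = np.asarray(V, dtype=float)
    if np.any(V < 0):
        raise ValueError("V must be non-negative")
    n_samples = V.shape[0]
    zero_rows = [i for i in range(n_samples) if V[i].sum() == 0]
    active = [i for i in range(n_samples) if i not in zero_rows]
    if k >= len(active):
        raise ValueError(f"k={k} must be < number of non-zero samples "
                         f"({len(active)})")
    if zero_rows:
        log.warning("zero rows excluded from NMF: %s", zero_rows)
    Va = V[active]

    best = None
    labels = np.zeros((n_runs, len(active)), dtype=int)
    run_objs = np.zeros(n_runs)
    for r in range(n_runs):
        rng = np.random.default_rng(seed + r)
        W, H, objs = _mu_nmf(Va, k, rng, tol=tol, max_iter=max_iter)
        labels[r] = np.argmax(W, axis=1)
        run_objs[r] = objs[-1]
        if best is None or objs[-1] < best[2][-1]:
            best = (W, H, objs, seed + r)

    W, H, objs, best_seed = best
    # resolve scale indeterminacy: L1-normalize H rows, rescale W columns
    row_sums = H.sum(axis=1)
    row_sums[row_sums == 0] = 1.0
    H = H / row_sums[:, None]
    W = W * row_sums[None, :]

    W_full = np.zeros((n_samples, k))
    W_full[active] = W

    labels_full = np.zeros((n_runs, n_samples), dtype=int)
    labels_full[:, active] = labels
    consensus, coph = _consensus_and_cophenetic(
        labels if not zero_rows else labels_full)

    return NMFResult(
        W=W_full, H=H, k=k, objective=float(objs[-1]), n_runs=n_runs,
        best_run_seed=best_seed, consensus=consensus, cophenetic=coph,
        objectives=objs, zero_rows=zero_rows, run_objectives=run_objs,
    )


def select_rank(
    V,
    k_min: int = 2,
    k_max: int = 6,
    n_runs: int = 20,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 2000,
) -> pd.DataFrame:
    """Rank survey: per-k best objective and consensus cophenetic correlation.

    No automatic choice is made; the default pipeline rank is 3.
    """
    if isinstance(V, MotifMatrix):
        V = V.freq
    V = np.asarray(V, dtype=float)
    n_samples = V.shape[0]
    if k_max >= n_samples:
        log.warning("k_max %d truncated to n_samples-1 = %d",
                    k_max, n_samples - 1)
        k_max = n_samples - 1
    rows = []
    for k in range(k_min, k_max + 1):
        res = nmf_factorize(V, k, n_runs=n_runs, seed=seed, tol=tol,
                            max_iter=max_iter)
        rows.append({"k": k, "objective": res.objective,
                     "cophenetic": res.cophenetic})
    return pd.DataFrame(rows)


def top_profile_motifs(
    H: np.ndarray, q: int = 10, motifs: Sequence[str] = MOTIFS,
) -> list[list[str]]:
    """Per profile, the q motifs with the largest weight; ties broken
    lexicographically; q clamped to the motif count."""
    q = min(q, len(motifs))
    out = []
    for row in np.asarray(H):
        order = sorted(range(len(motifs)), key=lambda j: (-row[j], motifs[j]))
        out.append([motifs[j] for j in order[:q]])
    return out


def compare_profile_contributions(
    W: np.ndarray,
    sample_ids: Sequence[str],
    pairing: Mapping[str, tuple[str, str]],
    conditions: tuple[str, str] = ("C1D1", "C5D1"),
) -> pd.DataFrame:
    """Paired Wilcoxon signed-rank per profile column of W.

    ``pairing`` maps sample id -> (condition, subject); subjects lacking one
    sample per condition are excluded with a warning.  Direction is the sign
    of the median within-subject difference (second condition minus first).
    """
    from .stats import wilcoxon_signed_rank

    by_subject: dict[str, dict[str, int]] = {}
    for i, sid in enumerate(sample_ids):
        if sid not in pairing:
            continue
        cond, subj = pairing[sid]
        by_subject.setdefault(subj, {})[cond] = i
    pairs_idx = []
    for subj, conds in sorted(by_subject.items()):
        if conditions[0] in conds and conditions[1] in conds:
            pairs_idx.append((conds[conditions[0]], conds[conditions[1]]))
        else:
            log.warning("subject %s lacks a complete %s/%s pair; excluded",
                        subj, *conditions)

    if len(pairs_idx) < 2:
        raise ValueError("paired test undefined for fewer than 2 subjects")

    W = np.asarray(W)
    rows = []
    for p in range(W.shape[1]):
        a = np.array([W[i, p] for i, _ in pairs_idx])
        b = np.array([W[j, p] for _, j in pairs_idx])
        diffs = b - a
        try:
            res = wilcoxon_signed_rank(list(zip(a, b)))
            pval, stat = res.p_value, res.statistic
        except ValueError:
            pval, stat = 1.0, float("nan")
        rows.append({
            "profile": p,
            "n_pairs": len(pairs_idx),
            "statistic": stat,
            "p_value": pval,
            "direction": float(np.sign(np.median(diffs))) if len(diffs) else 0.0,
        })
    return pd.DataFrame(rows)
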