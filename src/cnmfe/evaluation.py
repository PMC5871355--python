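"""Matching estimated components to ground truth and quality metrics."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MatchReport",
    "cosine_similarity",
    "match_components",
    "compute_snr",
    "pairwise_correlations",
]


def cosine_similarity(u, v) -> float:
    """``u'v / (||u|| ||v||)``; raises on zero vectors."""
    u = np.asarray(u, dtype=np.float64).ravel()
    v = np.asarray(v, dtype=np.float64).ravel()
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity undefined for zero vectors")
    return float(u @ v / (nu * nv))


@dataclass
class MatchReport:
    """One-to-one assignment of estimated to ground-truth components."""

    pairs: list                       # (est index, truth index)
    spatial_cosine: np.ndarray        # per pair
    temporal_cosine: np.ndarray       # per pair
    unmatched_truth: list = field(default_factory=list)
    unmatched_est: list = field(default_factory=list)

    @property
    def n_matched(self) -> int:
        return len(self.pairs)


def _cosine_matrix(U, V):
    Un = np.linalg.norm(U, axis=0, keepdims=True)
    Vn = np.linalg.norm(V, axis=0, keepdims=True)
    Un[Un == 0] = 1.0
    Vn[Vn == 0] = 1.0
    return (U / Un).T @ (V / Vn)


def match_components(A_est, C_est, A_true, C_true, min_sim=0.5,
                     method="greedy") -> MatchReport:
    """Match estimated components to truth by spatial cosine similarity.

    Greedy descending assignment by default (pairs below ``min_sim`` are
    left unmatched); ``method="hungarian"`` uses an optimal assignment for
    auditing.
    """
    if A_true.shape[1] == 0:
        raise ValueError("ground truth must be nonempty")
    S = _cosine_matrix(A_est, A_true)   # (K_est, K_true)
    pairs = []
    if method == "hungarian":
        from scipy.optimize import linear_sum_assignment

        rows, cols = linear_sum_assignment(-S)
        for i, j in zip(rows, cols):
            if S[i, j] >= min_sim:
                pairs.append((int(i), int(j)))
    else:
        S_work = S.copy()
        while True:
            i, j = np.unravel_index(np.argmax(S_work), S_work.shape)
            if S_work[i, j] < min_sim:
                break
            pairs.append((int(i), int(j)))
            S_work[i, :] = -np.inf
            S_work[:, j] = -np.inf
    spatial = np.array([S[i, j] for i, j in pairs])
    temporal = np.array([
        cosine_similarity(C_est[i], C_true[j]) if
        np.linalg.norm(C_est[i]) > 0 and np.linalg.norm(C_true[j]) > 0 else 0.0
        for i, j in pairs
    ]) if pairs else np.zeros(0)
    matched_e = {i for i, _ in pairs}
    matched_t = {j for _, j in pairs}
    return MatchReport(
        pairs=pairs, spatial_cosine=spatial, temporal_cosine=temporal,
        unmatched_truth=[j for j in range(A_true.shape[1]) if j not in matched_t],
        unmatched_est=[i for i in range(A_est.shape[1]) if i not in matched_e],
    )


def compute_snr(y_raw, c) -> float:
    """Trace SNR: ``||c||^2 / ||y_raw - c||^2`` (+inf when the residual is 0)."""
    y_raw = np.asarray(y_raw, dtype=np.float64)
    c = np.asarray(c, dtype=np.float64)
    if y_raw.shape != c.shape:
        raise ValueError("length mismatch")
    den = float(((y_raw - c) ** 2).sum())
    num = float((c**2).sum())
    if den == 0:
        return np.inf
    return num / den


def pairwise_correlations(C) -> np.ndarray:
    """Pearson correlation matrix of the trace rows (unit diagonal).

    Constant rows produce zero correlations (with a warning) rather than
    NaNs.
    """
    C = np.asarray(C, dtype=np.float64)
    K = C.shape[0]
    Cc = C - C.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Cc, axis=1)
    const = norms == 0
    if const.any():
        warnings.warn("constant trace rows; their correlations reported as 0")
    norms[const] = 1.0
    Cn = Cc / norms[:, None]
    M = Cn @ Cn.T
    M[const, :] = 0.0
    M[:, const] = 0.0
    np.fill_diagonal(M, 1.0)
    return np.clip(M, -1.0, 1.0)
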