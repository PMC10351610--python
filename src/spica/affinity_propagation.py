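"""Exemplar-based clustering by responsibility/availability message passing.

Affinity propagation treats every point as a candidate exemplar and exchanges
two messages: the responsibility ``r(i,k)`` — how well suited point ``k`` is
to serve as the exemplar of ``i`` — and the availability ``a(i,k)`` — how
appropriate it is for ``i`` to choose ``k``. The number of clusters emerges
from the shared ``preference`` (the self-similarity) rather than being fixed
in advance.

Basis columns from ICA carry an arbitrary sign, so the default similarity is
a sign-free negative squared Euclidean distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["APCResult", "similarity_matrix", "apc"]


def similarity_matrix(columns, metric: str = "neg_sqeuclid_signfree") -> np.ndarray:
    """Pairwise similarities of equal-length vectors (diagonal left at 0).

    neg_sqeuclid_signfree
        ``s(i,k) = -min(||x_i - x_k||^2, ||x_i + x_k||^2)`` — invariant to
        sign flips of either vector.
    abs_correlation
        ``s(i,k) = |pearson r| - 1`` (shifted so similarities are <= 0).
    """
    X = np.asarray(columns, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need >= 2 equal-length columns")
    if metric == "neg_sqeuclid_signfree":
        sq = np.sum(X**2, axis=1)
        gram = X @ X.T
        d_minus = sq[:, None] + sq[None, :] - 2 * gram
        d_plus = sq[:, None] + sq[None, :] + 2 * gram
        S = -np.minimum(d_minus, d_plus)
        S = np.minimum(S, 0.0)  # clip tiny positive round-off
    elif metric == "abs_correlation":
        sd = X.std(axis=1)
        if np.any(sd == 0):
            i = int(np.argmax(sd == 0))
            raise ValueError(f"zero-variance column at index {i}")
        R = np.corrcoef(X)
        S = np.abs(R) - 1.0
    else:
        raise ValueError(f"unknown similarity metric {metric!r}")
    np.fill_diagonal(S, 0.0)
    S = 0.5 * (S + S.T)
    return S


@dataclass
class APCResult:
    """Converged state of the affinity-propagation message loop."""

    similarity: np.ndarray
    responsibility: np.ndarray
    availability: np.ndarray
    preference: np.ndarray
    damping: float
    labels: np.ndarray
    exemplars: np.ndarray
    n_clusters: int
    converged: bool
    n_iter: int


def apc(similarity: np.ndarray, preference="median", damping: float = 0.9,
        max_iter: int = 1000, conv_window: int = 50,
        tie_noise: float = 1e-12, seed: int = 0) -> APCResult:
    """Run affinity propagation on a symmetric similarity matrix.

    ``preference`` may be a scalar, a per-point vector, or ``'median'`` (the
    median of off-diagonal similarities, the common convention). Iterates the
    damped message updates until the exemplar set is stable for
    ``conv_window`` iterations. A tiny seeded symmetric perturbation breaks
    exact ties.
    """
    S = np.array(similarity, dtype=float)
    n = S.shape[0]
    if S.shape != (n, n) or not np.allclose(S, S.T, atol=1e-8):
        raise ValueError("similarity must be square and symmetric")
    if not 0.5 <= damping < 1.0:
        raise ValueError("damping must be in [0.5, 1)")
    off = S[~np.eye(n, dtype=bool)]
    if isinstance(preference, str):
        if preference != "median":
            raise ValueError(f"unknown preference rule {preference!r}")
        pref = np.full(n, np.median(off) if off.size else 0.0)
    else:
        pref = np.broadcast_to(np.asarray(preference, dtype=float), (n,)).copy()
    np.fill_diagonal(S, pref)
    if tie_noise:
        rng = np.random.default_rng(seed)
        eps = rng.standard_normal((n, n)) * tie_noise
        S = S + 0.5 * (eps + eps.T)

    if n == 1:
        zeros = np.zeros((1, 1))
        return APCResult(S, zeros, zeros, pref, damping,
                         labels=np.array([0]), exemplars=np.array([0]),
                         n_clusters=1, converged=True, n_iter=0)

    R = np.zeros((n, n))
    A = np.zeros((n, n))
    idx = np.arange(n)
    stable = 0
    prev_exemplars: np.ndarray | None = None
    n_iter = max_iter
    converged = False

    for it in range(max_iter):
        # responsibilities: r(i,k) = s(i,k) - max_{k'!=k}[a(i,k') + s(i,k')]
        AS = A + S
        first = np.argmax(AS, axis=1)
        max1 = AS[idx, first]
        AS_tmp = AS.copy()
        AS_tmp[idx, first] = -np.inf
        max2 = np.max(AS_tmp, axis=1)
        Rnew = S - max1[:, None]
        Rnew[idx, first] = S[idx, first] - max2
        R = damping * R + (1 - damping) * Rnew
        # availabilities: a(i,k) = min(0, r(k,k) + sum_{i' not in {i,k}} r+)
        Rp = np.maximum(R, 0.0)
        np.fill_diagonal(Rp, R.diagonal())
        col = Rp.sum(axis=0)
        Anew = np.minimum(0.0, col[None, :] - Rp)
        Anew[idx, idx] = col - R.diagonal()
        A = damping * A + (1 - damping) * Anew
        if not (np.all(np.isfinite(R)) and np.all(np.isfinite(A))):
            raise FloatingPointError("affinity-propagation messages diverged")
        exemplars = np.flatnonzero(R.diagonal() + A.diagonal() > 0)
        if prev_exemplars is not None and np.array_equal(exemplars, prev_exemplars):
            stable += 1
        else:
            stable = 0
        prev_exemplars = exemplars
        if stable >= conv_window and exemplars.size:
            converged = True
            n_iter = it + 1
            break

    exemplars = np.flatnonzero(R.diagonal() + A.diagonal() > 0)
    if exemplars.size == 0:
        raise RuntimeError(
            "no exemplar emerged; raise the preference (it is likely too low)"
        )
    labels = exemplars[np.argmax(S[:, exemplars], axis=1)]
    labels[exemplars] = exemplars
    # relabel each point to its own exemplar index
    return APCResult(similarity=S, responsibility=R, availability=A,
                     preference=pref, damping=damping, labels=labels,
                     exemplars=exemplars, n_clusters=int(exemplars.size),
                     converged=converged, n_iter=n_iter)
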