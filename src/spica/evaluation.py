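"""Reconstruction, source-recovery and co-module-recovery metrics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["sample_correlations", "amari_index", "set_recovery",
           "RecoveryScores", "correlation_histogram"]


def sample_correlations(X: np.ndarray, X_hat: np.ndarray
                        ) -> tuple[np.ndarray, float, float]:
    """Per-sample Pearson r between a block and its reconstruction.

    Both matrices are features x samples; one correlation is computed per
    sample (column) across its features. Zero-variance samples yield NaN and
    are excluded from the mean/SD summary.
    """
    X = np.asarray(X, dtype=float)
    X_hat = np.asarray(X_hat, dtype=float)
    if X.shape != X_hat.shape:
        raise ValueError(f"shape mismatch: {X.shape} vs {X_hat.shape}")
    xc = X - X.mean(axis=0)
    yc = X_hat - X_hat.mean(axis=0)
    num = np.sum(xc * yc, axis=0)
    den = np.sqrt(np.sum(xc**2, axis=0) * np.sum(yc**2, axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    valid = r[np.isfinite(r)]
    mean = float(valid.mean()) if valid.size else float("nan")
    sd = float(valid.std()) if valid.size else float("nan")
    return r, mean, sd


def amari_index(P: np.ndarray) -> float:
    """Distance of a square matrix from a scaled permutation, in [0, 1].

    For P = W_est @ M_true, rows of |P| are first normalized by their maxima
    (removing the ICA scale indeterminacy), then

        (1 / (2k(k-1))) * [ sum_i ( sum_j q_ij / max_j q_ij - 1 )
                          + sum_j ( sum_i q_ij / max_i q_ij - 1 ) ]

    with q the normalized matrix; 0 iff P is a permutation times a
    nonsingular diagonal, and invariant to row permutation and nonzero row
    scaling of W_est.
    """
    P = np.abs(np.asarray(P, dtype=float))
    k, k2 = P.shape if P.ndim == 2 else (0, -1)
    if k != k2:
        raise ValueError("amari_index needs a square matrix")
    if k == 1:
        return 0.0
    row_max = P.max(axis=1)
    if np.any(row_max == 0):
        raise ValueError("matrix has an all-zero row")
    Q = P / row_max[:, None]
    col_max = Q.max(axis=0)
    if np.any(col_max == 0):
        raise ValueError("matrix has an all-zero column")
    rows = np.sum(Q, axis=1) - 1.0
    cols = np.sum(Q / col_max[None, :], axis=0) - 1.0
    return float((rows.sum() + cols.sum()) / (2 * k * (k - 1)))


@dataclass
class RecoveryScores:
    precision: float
    recall: float
    f1: float


def _prf(truth: set, found: set) -> RecoveryScores:
    tp = len(truth & found)
    precision = tp / len(found) if found else (1.0 if not truth else 0.0)
    recall = tp / len(truth) if truth else 1.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    return RecoveryScores(precision, recall, f1)


def set_recovery(truth: dict[str, set], found: dict[str, set]
                 ) -> dict[str, RecoveryScores]:
    """Precision/recall/F1 of selected vs planted sets, per block and pooled.

    ``truth`` and ``found`` map block names to feature-ID sets; the pooled
    entry (key ``'pooled'``) tags members with their block to keep IDs from
    colliding across blocks.
    """
    out: dict[str, RecoveryScores] = {}
    pooled_t: set = set()
    pooled_f: set = set()
    for name in truth:
        t = set(truth[name])
        f = set(found.get(name, set()))
        out[name] = _prf(t, f)
        pooled_t |= {(name, x) for x in t}
        pooled_f |= {(name, x) for x in f}
    out["pooled"] = _prf(pooled_t, pooled_f)
    return out


def correlation_histogram(r: np.ndarray, path, bins: int = 30,
                          title: str = "sample-wise correlations") -> None:
    """Histogram of per-sample correlations with the mean +- SD marked."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    r = np.asarray(r, dtype=float)
    r = r[np.isfinite(r)]
    fig, ax = plt.subplots(figsize=(5, 3.5))
    lo = float(r.min()) if r.size else 0.0
    ax.hist(r, bins=np.linspace(min(lo, 1.0), 1.0, bins + 1),
            color="steelblue", edgecolor="white")
    if r.size:
        ax.axvline(r.mean(), color="red", lw=1.5)
        ax.axvline(r.mean() - r.std(), color="red", lw=1.0, ls="--")
        ax.axvline(r.mean() + r.std(), color="red", lw=1.0, ls="--")
    ax.set_xlabel("Pearson r")
    ax.set_ylabel("samples")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
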