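"""Count normalization and PCA reduction of the sample dimension.

The decomposition works on a reduced matrix whose rows live in a
low-dimensional sample space: the concatenated profile matrix is transposed to
samples x total_features, centered per feature, and projected onto the leading
principal directions over samples until a target cumulative variance fraction
(default 90%) is reached. The working matrix thereafter is k x total_features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_model import OmicsBlock

__all__ = ["PCAResult", "normalize", "pca_reduce"]

_RANK_RTOL = 1e-10  # singular values below sv_max * _RANK_RTOL count as zero


def normalize(block: OmicsBlock, method: str = "log_cpm") -> OmicsBlock:
    """Normalize one block's expression values.

    log_cpm
        Scale each sample (column) to a library size of 1e6, then log2(x+1).
        Zero-total samples are left at zero counts.
    log1p
        log2(x+1) without library scaling.
    none
        Identity.
    """
    if method == "none":
        return block
    v = block.values
    if method in ("log_cpm", "log1p") and np.any(v < 0):
        raise ValueError(f"method {method!r} requires non-negative values")
    if method == "log_cpm":
        lib = v.sum(axis=0)
        scale = np.divide(1e6, lib, out=np.zeros_like(lib), where=lib > 0)
        out = np.log2(v * scale[None, :] + 1.0)
    elif method == "log1p":
        out = np.log2(v + 1.0)
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    return OmicsBlock(block.name, list(block.feature_ids),
                      list(block.sample_ids), out)


@dataclass
class PCAResult:
    """PCA of samples x total_features data, reducing the sample dimension.

    ``components`` (n_samples x k) are orthonormal directions over samples;
    ``reduced`` (k x total_features) are the projections of the centered data,
    the working matrix for sparse approximation and ICA. ``feature_means``
    are restored on reconstruction.
    """

    components: np.ndarray
    explained_ratio: np.ndarray
    k: int
    threshold: float
    reduced: np.ndarray
    feature_means: np.ndarray

    def inverse_transform(self, reduced: np.ndarray) -> np.ndarray:
        """Map a k x total_features matrix back to samples x total_features."""
        return self.components @ reduced + self.feature_means[None, :]


def pca_reduce(X: np.ndarray, threshold: float = 0.90,
               max_k: int | None = None) -> PCAResult:
    """Reduce the sample dimension of a samples x total_features matrix.

    Keeps the smallest number of principal components whose cumulative
    explained-variance fraction reaches ``threshold``; ``threshold=1.0`` keeps
    the full numeric rank of the centered matrix. Component signs are fixed by
    making each component's largest-magnitude entry positive.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    means = X.mean(axis=0)
    Xc = X - means[None, :]
    U, sv, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(sv > sv[0] * _RANK_RTOL)) if sv.size and sv[0] > 0 else 0
    if rank == 0:
        raise ValueError("matrix has zero variance after centering")
    var = sv**2
    ratio = var / var.sum()
    if threshold >= 1.0:
        k = rank
    else:
        k = int(np.searchsorted(np.cumsum(ratio), threshold) + 1)
        k = min(k, rank)
    if max_k is not None:
        k = min(k, max_k)
    # deterministic sign: largest-|entry| of each component positive
    comps = U[:, :k].copy()
    scores = (sv[:k, None] * Vt[:k]).copy()
    for j in range(k):
        i = np.argmax(np.abs(comps[:, j]))
        if comps[i, j] < 0:
            comps[:, j] *= -1
            scores[j] *= -1
    return PCAResult(components=comps, explained_ratio=ratio[:k], k=k,
                     threshold=threshold, reduced=scores, feature_means=means)
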