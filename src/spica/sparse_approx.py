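"""Wavelet-packet sparse approximation of the working matrix along features.

The reduced profile matrix (rows = reduced sample dimensions, columns =
concatenated features) is approximated as ``X ~= C_X . Phi`` where ``Phi`` is
an orthonormal wavelet-packet basis chosen by a best-basis search that
maximizes a Gini sparsity criterion, and ``C_X`` keeps only the largest
coefficients needed to retain a target energy fraction ("sparsity quality").

Feature vectors are treated as 1-D signals in their input order; non-dyadic
lengths are symmetrically padded to the next power of two and the padding is
stripped on synthesis. All transforms use periodized orthogonal filters, so
analysis is energy-preserving (Parseval) and exactly invertible.

An ``identity`` dictionary mode (``Phi = I``) is provided so downstream stages
can be exercised independently of wavelet choices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

__all__ = [
    "SparseDictionary",
    "SparseApprox",
    "sparsity_measure",
    "decompose_tree",
    "select_nodes",
    "sparse_approximate",
    "reconstruct_sparse",
]

_MODE = "periodization"  # exact halving + orthogonality on dyadic lengths


def sparsity_measure(v: np.ndarray) -> float:
    """Gini sparsity index of a vector: 0 for constant, (n-1)/n for one-hot.

    Scale-invariant; computed from sorted magnitudes c_(1) <= ... <= c_(N) as
    ``1 - 2 * sum_k (c_(k)/||v||_1) * (N - k + 1/2)/N``.
    """
    v = np.abs(np.asarray(v, dtype=float).ravel())
    l1 = v.sum()
    if l1 == 0:
        raise ValueError("sparsity_measure undefined for all-zero input")
    c = np.sort(v)
    n = c.size
    weights = (n - np.arange(1, n + 1) + 0.5) / n
    return float(1.0 - 2.0 * np.sum(c / l1 * weights))


def _check_family(family: str) -> pywt.Wavelet:
    try:
        w = pywt.Wavelet(family)
    except ValueError:
        raise ValueError(
            f"unsupported wavelet family {family!r}; supported discrete "
            f"families include: {', '.join(pywt.wavelist(kind='discrete')[:20])}, ..."
        ) from None
    return w


def _pad_dyadic(X: np.ndarray) -> tuple[np.ndarray, int, int]:
    """Symmetric-pad columns count to the next power of two."""
    n = X.shape[1]
    padded = 1 << max(0, int(np.ceil(np.log2(n))))
    if padded < n:  # n == 1
        padded = n
    extra = padded - n
    left, right = extra // 2, extra - extra // 2
    if extra:
        X = np.pad(X, ((0, 0), (left, right)), mode="symmetric")
    return X, left, right


def decompose_tree(X: np.ndarray, family: str = "db4",
                   level: int = 4) -> dict[str, np.ndarray]:
    """Full wavelet-packet coefficient tree of each row of a d x n matrix.

    Returns a dict keyed by node address over the alphabet {'a','d'} ('' is
    the root, i.e. the padded input); node at depth l holds a d x (padded_n /
    2^l) coefficient matrix.
    """
    w = _check_family(family)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Xp, _, _ = _pad_dyadic(X)
    max_level = int(np.log2(Xp.shape[1])) if Xp.shape[1] > 1 else 0
    if level < 1 or level > max_level:
        raise ValueError(
            f"level must be in [1, {max_level}] for padded length {Xp.shape[1]}"
        )
    tree: dict[str, np.ndarray] = {"": Xp}
    frontier = [""]
    for _ in range(level):
        nxt = []
        for node in frontier:
            ca, cd = pywt.dwt(tree[node], w, mode=_MODE, axis=1)
            tree[node + "a"], tree[node + "d"] = ca, cd
            nxt += [node + "a", node + "d"]
        frontier = nxt
    return tree


@dataclass
class SparseDictionary:
    """The basis Phi: a pruned wavelet-packet tree (or the identity).

    ``selected_nodes`` are the leaves of an admissible pruning, in left-to-
    right (frequency-path) order; their coefficient supports tile the padded
    signal exactly once, so ``atom_count`` equals the padded length.
    """

    kind: str  # "wavelet_packet" | "identity"
    family: str | None
    level: int
    selected_nodes: list[str]
    atom_count: int
    signal_length: int
    padded_length: int
    pad_left: int = 0
    pad_right: int = 0

    def node_slices(self) -> dict[str, slice]:
        """Column range of each selected node inside the coefficient matrix."""
        out, lo = {}, 0
        for node in self.selected_nodes:
            width = self.padded_length >> len(node)
            out[node] = slice(lo, lo + width)
            lo += width
        return out


@dataclass
class SparseApprox:
    """Sparse coefficients C_X of the working matrix under a dictionary Phi."""

    dictionary: SparseDictionary
    coeffs: np.ndarray  # d x atom_count
    quality: float      # achieved retained-energy fraction
    nnz_fraction: float


def _best_basis(tree: dict[str, np.ndarray], level: int) -> list[str]:
    """Leaves maximizing the summed Gini sparsity over an admissible pruning.

    Additive dynamic program: a node is kept as a leaf when its own sparsity
    is >= the best total achievable by splitting it (ties keep the parent).
    """
    score: dict[str, float] = {}
    keep: dict[str, bool] = {}

    def visit(node: str) -> float:
        coeffs = tree[node]
        own = sparsity_measure(coeffs) if np.any(coeffs) else 0.0
        if len(node) == level:
            score[node] = own
            keep[node] = True
            return own
        split = visit(node + "a") + visit(node + "d")
        if own >= split:
            score[node], keep[node] = own, True
        else:
            score[node], keep[node] = split, False
        return score[node]

    visit("")
    leaves: list[str] = []

    def collect(node: str) -> None:
        if keep[node]:
            leaves.append(node)
        else:
            collect(node + "a")
            collect(node + "d")

    collect("")
    return sorted(leaves)  # 'a' < 'd' gives left-to-right tiling order


def select_nodes(tree: dict[str, np.ndarray], quality: float = 0.95,
                 family: str = "db4", level: int | None = None,
                 signal_length: int | None = None,
                 pad: tuple[int, int] = (0, 0)) -> SparseDictionary:
    """Best-basis pruning of a coefficient tree into a SparseDictionary."""
    if not 0.0 < quality <= 1.0:
        raise ValueError(f"quality must be in (0, 1], got {quality}")
    if level is None:
        level = max(len(k) for k in tree)
    padded = tree[""].shape[1]
    leaves = _best_basis(tree, level)
    if signal_length is None:
        signal_length = padded - pad[0] - pad[1]
    return SparseDictionary(
        kind="wavelet_packet", family=family, level=level,
        selected_nodes=leaves, atom_count=padded,
        signal_length=signal_length, padded_length=padded,
        pad_left=pad[0], pad_right=pad[1],
    )


def _threshold_energy(C: np.ndarray, quality: float) -> tuple[np.ndarray, float, float]:
    """Zero the smallest coefficients while retained energy stays >= quality."""
    flat = C.ravel()
    energy = flat**2
    total = energy.sum()
    if quality >= 1.0 or total == 0:
        nnz = np.count_nonzero(flat) / max(flat.size, 1)
        return C, 1.0, nnz
    order = np.argsort(energy)[::-1]
    cum = np.cumsum(energy[order])
    # smallest m with retained energy >= quality * total
    m = int(np.searchsorted(cum, quality * total) + 1)
    mask = np.zeros(flat.size, dtype=bool)
    mask[order[:m]] = True
    out = np.where(mask, flat, 0.0).reshape(C.shape)
    achieved = float(cum[m - 1] / total)
    return out, achieved, float(mask.sum()) / flat.size


def sparse_approximate(X: np.ndarray, family: str = "db4",
                       level: int | None = None, quality: float = 0.95,
                       kind: str = "wavelet_packet") -> SparseApprox:
    """Compute C_X and Phi with ||X - C_X.Phi||_F / ||X||_F <= sqrt(1-quality).

    ``kind='identity'`` bypasses the wavelet machinery (Phi = I, C_X = X).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[1]
    if kind == "identity":
        d = SparseDictionary(kind="identity", family=None, level=0,
                             selected_nodes=[], atom_count=n,
                             signal_length=n, padded_length=n)
        nnz = np.count_nonzero(X) / max(X.size, 1)
        return SparseApprox(dictionary=d, coeffs=X.copy(), quality=1.0,
                            nnz_fraction=max(nnz, np.finfo(float).tiny))
    if kind != "wavelet_packet":
        raise ValueError(f"unknown dictionary kind {kind!r}")
    if level is None:
        level = min(4, int(np.floor(np.log2(n))))
    Xp, left, right = _pad_dyadic(X)
    tree = decompose_tree(X, family=family, level=level)
    dictionary = select_nodes(tree, quality=quality, family=family,
                              level=level, signal_length=n, pad=(left, right))
    C = np.concatenate([tree[node] for node in dictionary.selected_nodes],
                       axis=1)
    C, achieved, nnz = _threshold_energy(C, quality)
    return SparseApprox(dictionary=dictionary, coeffs=C, quality=achieved,
                        nnz_fraction=nnz)


def reconstruct_sparse(C: np.ndarray, dictionary: SparseDictionary) -> np.ndarray:
    """Synthesize a d x signal_length matrix from coefficients: C . Phi.

    Linear in C; inverse of analysis when no coefficients were zeroed.
    """
    C = np.atleast_2d(np.asarray(C, dtype=float))
    if C.shape[1] != dictionary.atom_count:
        raise ValueError(
            f"coefficient columns {C.shape[1]} != atom_count {dictionary.atom_count}"
        )
    if dictionary.kind == "identity":
        return C.copy()
    w = pywt.Wavelet(dictionary.family)
    slices = dictionary.node_slices()
    parts = {node: C[:, sl] for node, sl in slices.items()}

    def synth(node: str) -> np.ndarray:
        if node in parts:
            return parts[node]
        return pywt.idwt(synth(node + "a"), synth(node + "d"), w,
                         mode=_MODE, axis=1)

    Xp = synth("")
    lo = dictionary.pad_left
    return Xp[:, lo:lo + dictionary.signal_length]
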