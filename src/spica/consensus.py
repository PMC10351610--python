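"""Multi-run consensus: pooled-basis clustering and co-module selection.

A single ICA run is seed-dependent, so the decomposition is repeated (20
times in the reference configuration) and the basis columns of all runs are
pooled (20 x 40 = 800 columns) and clustered with affinity propagation. Each
cluster is a consensus co-module: its member basis columns index module-matrix
rows, which are sign-aligned to the cluster exemplar's row and averaged into
one signature over all features. Signatures are z-scored (jointly across
blocks by default) and features with two-sided normal tail probability below
``alpha`` are selected per block; the final per-block sets combine the
clusters' selections (literal intersection by default, union optionally).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .affinity_propagation import APCResult, apc, similarity_matrix
from .constrained_ica import ICAConfig, ICADecomposition, fit
from .io_model import MultiOmicsSet
from .sparse_approx import SparseApprox

__all__ = ["CoModuleSet", "multi_run", "pool_basis", "aggregate",
           "select_elements"]


@dataclass
class CoModuleSet:
    """Consensus clusters of pooled basis columns and their selections."""

    n_runs: int
    n_components: int
    cluster_labels: np.ndarray                 # per pooled column, exemplar index
    provenance: list[tuple[int, int]]          # pooled column -> (run, component)
    signatures: dict[int, np.ndarray]          # cluster exemplar -> total_features vector
    zscores: dict[int, np.ndarray] = field(default_factory=dict)
    selected: dict[int, dict[str, set[str]]] = field(default_factory=dict)
    final: dict[str, set[str]] = field(default_factory=dict)
    alpha: float | None = None
    zscore_scope: str = "joint"
    combine: str = "intersection"

    @property
    def clusters(self) -> list[int]:
        return sorted(self.signatures)


def multi_run(sa: SparseApprox, cfg: ICAConfig, n_runs: int = 20,
              base_seed: int = 0,
              block_slices: list[tuple[int, int]] | None = None
              ) -> list[ICADecomposition]:
    """Repeat the decomposition with seeds base_seed ... base_seed+n_runs-1.

    Preprocessing (normalization, PCA, sparse approximation) is done once by
    the caller; only the ICA initialization varies across runs.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    decomps = []
    for r in range(n_runs):
        run_cfg = ICAConfig(**{**cfg.__dict__, "seed": base_seed + r})
        decomps.append(fit(sa.coeffs, run_cfg, dictionary=sa.dictionary,
                           block_slices=block_slices))
    return decomps


def pool_basis(decomps: list[ICADecomposition]
               ) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Stack all runs' basis columns: (n_runs*k) x d, with (run, comp) tags."""
    if not decomps:
        raise ValueError("no decompositions to pool")
    d = decomps[0].A.shape[0]
    cols, prov = [], []
    for r, dec in enumerate(decomps):
        if dec.A.shape[0] != d:
            raise ValueError(
                f"run {r}: basis row dimension {dec.A.shape[0]} != {d}"
            )
        for j in range(dec.A.shape[1]):
            cols.append(dec.A[:, j])
            prov.append((r, j))
    return np.asarray(cols), prov


def cluster_basis(columns: np.ndarray, metric: str = "neg_sqeuclid_signfree",
                  preference="median", damping: float = 0.9,
                  max_iter: int = 1000, seed: int = 0) -> APCResult:
    """Affinity propagation over pooled basis columns."""
    S = similarity_matrix(columns, metric=metric)
    return apc(S, preference=preference, damping=damping, max_iter=max_iter,
               seed=seed)


def aggregate(decomps: list[ICADecomposition], apc_result: APCResult,
              provenance: list[tuple[int, int]]) -> CoModuleSet:
    """Average sign-aligned module rows within each cluster into signatures.

    Each pooled basis column (run r, component j) pairs with row j of run r's
    module matrix S. Rows are flipped to correlate positively with the
    cluster exemplar's row before averaging, neutralizing the ICA sign
    indeterminacy.
    """
    labels = apc_result.labels
    n_pooled = len(provenance)
    if labels.shape[0] != n_pooled:
        raise ValueError("cluster labels do not cover all pooled columns")
    signatures: dict[int, np.ndarray] = {}
    for ex in apc_result.exemplars:
        members = np.flatnonzero(labels == ex)
        assert members.size > 0, "affinity propagation produced an empty cluster"
        r_ex, j_ex = provenance[ex]
        ref = decomps[r_ex].S[j_ex]
        rows = []
        for p in members:
            r, j = provenance[p]
            row = decomps[r].S[j]
            c = float(np.dot(row - row.mean(), ref - ref.mean()))
            rows.append(-row if c < 0 else row)
        signatures[int(ex)] = np.mean(rows, axis=0)
    n_runs = len(decomps)
    k = decomps[0].A.shape[1]
    return CoModuleSet(n_runs=n_runs, n_components=k, cluster_labels=labels,
                       provenance=provenance, signatures=signatures)


def select_elements(cms: CoModuleSet, ms: MultiOmicsSet, alpha: float = 0.05,
                    zscore_scope: str = "joint",
                    combine: str = "intersection") -> CoModuleSet:
    """Z-score each signature and keep features in the two-sided alpha tail.

    The 0.05 threshold is a significance level: a feature is selected when
    its standardized signature value satisfies |z| >= Phi^-1(1 - alpha/2)
    (1.960 at alpha = 0.05). Scope ``joint`` standardizes across all blocks
    together; ``per_block`` standardizes each block slice separately. Final
    per-block sets are the intersection (default) or union across clusters.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if zscore_scope not in ("joint", "per_block"):
        raise ValueError(f"unknown zscore_scope {zscore_scope!r}")
    if combine not in ("intersection", "union"):
        raise ValueError(f"unknown combine mode {combine!r}")
    zcut = norm.ppf(1 - alpha / 2)
    cms.alpha = alpha
    cms.zscore_scope = zscore_scope
    cms.combine = combine
    cms.zscores = {}
    cms.selected = {}

    def _z(v: np.ndarray) -> np.ndarray:
        sd = v.std()
        if sd == 0:
            warnings.warn("constant signature: nothing selected",
                          RuntimeWarning, stacklevel=3)
            return np.zeros_like(v)
        return (v - v.mean()) / sd

    for ex, sig in cms.signatures.items():
        if zscore_scope == "joint":
            z = _z(sig)
        else:
            z = np.empty_like(sig)
            for lo, hi in ms.boundaries:
                z[lo:hi] = _z(sig[lo:hi])
        cms.zscores[ex] = z
        per_block: dict[str, set[str]] = {}
        for blk, (lo, hi) in zip(ms.blocks, ms.boundaries):
            hits = np.flatnonzero(np.abs(z[lo:hi]) >= zcut)
            per_block[blk.name] = {blk.feature_ids[i] for i in hits}
        cms.selected[ex] = per_block

    cms.final = {}
    for blk in ms.blocks:
        sets = [cms.selected[ex][blk.name] for ex in cms.clusters]
        if combine == "intersection":
            acc = set(sets[0])
            for s in sets[1:]:
                acc &= s
        else:
            acc = set()
            for s in sets:
                acc |= s
        cms.final[blk.name] = acc
    return cms
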