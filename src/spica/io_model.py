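"""Domain containers and delimited-matrix I/O for multi-block expression data.

An :class:`OmicsBlock` holds one RNA type's expression matrix (features x
samples); a :class:`MultiOmicsSet` holds several blocks restricted to a shared,
ordered sample set, together with the half-open row ranges each block occupies
in the row-concatenated matrix ``X = (X_1; ...; X_K)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OmicsBlock",
    "MultiOmicsSet",
    "read_expression",
    "write_expression",
    "align_samples",
    "concatenate",
    "write_gmt",
]


def _check_unique(ids: list[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} ID: {i!r}")
        seen.add(i)


@dataclass
class OmicsBlock:
    """One RNA type's expression matrix with feature/sample identifiers.

    ``values`` is features x samples; counts or normalized expression.
    """

    name: str
    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"block {self.name!r}: values shape {self.values.shape} does not "
                f"match {len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        _check_unique(self.feature_ids, "feature")
        _check_unique(self.sample_ids, "sample")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"block {self.name!r}: non-finite value at feature "
                f"{self.feature_ids[bad[0]]!r}, sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset_samples(self, sample_ids: list[str]) -> "OmicsBlock":
        """Restrict and reorder columns to ``sample_ids`` (all must exist)."""
        pos = {s: j for j, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return OmicsBlock(self.name, list(self.feature_ids), list(sample_ids),
                          self.values[:, idx])


@dataclass
class MultiOmicsSet:
    """Ordered blocks on one shared sample set, with concatenation boundaries.

    ``boundaries[b] = (lo, hi)`` is the half-open row range of block ``b`` in
    the concatenated feature axis; the ranges partition ``[0, total_features)``.
    """

    blocks: list[OmicsBlock]
    sample_ids: list[str]
    boundaries: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("MultiOmicsSet needs at least one block")
        for b in self.blocks:
            if b.sample_ids != self.sample_ids:
                raise ValueError(
                    f"block {b.name!r} sample order differs from the shared order"
                )
        if not self.boundaries:
            self.boundaries = self._compute_boundaries()
        lo = 0
        for b, (s, e) in zip(self.blocks, self.boundaries):
            if s != lo or e - s != b.n_features:
                raise ValueError("boundaries do not tile the concatenated feature axis")
            lo = e

    def _compute_boundaries(self) -> list[tuple[int, int]]:
        out, lo = [], 0
        for b in self.blocks:
            out.append((lo, lo + b.n_features))
            lo += b.n_features
        return out

    @property
    def total_features(self) -> int:
        return sum(b.n_features for b in self.blocks)

    @property
    def block_names(self) -> list[str]:
        return [b.name for b in self.blocks]

    def feature_ids_concat(self) -> list[str]:
        out: list[str] = []
        for b in self.blocks:
            out.extend(b.feature_ids)
        return out


def read_expression(path, delimiter: str = "\t",
                    orientation: str = "features_in_rows",
                    name: str = "block") -> OmicsBlock:
    """Read a delimited expression matrix into an OmicsBlock.

    The first column holds feature IDs and the header row sample IDs (or the
    transpose when ``orientation='samples_in_rows'``). The returned block is
    always features x samples.
    """
    if orientation not in ("features_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    if orientation == "samples_in_rows":
        df = df.T
    feature_ids = [str(x) for x in df.index]
    sample_ids = [str(x) for x in df.columns]
    _check_unique(feature_ids, "feature")
    _check_unique(sample_ids, "sample")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError:
        for i, fid in enumerate(feature_ids):
            for j, sid in enumerate(sample_ids):
                cell = df.iat[i, j]
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"{path}: non-numeric cell {cell!r} at feature {fid!r}, "
                        f"sample {sid!r}"
                    ) from None
        raise
    return OmicsBlock(name, feature_ids, sample_ids, values)


def write_expression(block: OmicsBlock, path, delimiter: str = "\t") -> None:
    """Write a block back to delimited text (features in rows)."""
    df = pd.DataFrame(block.values, index=block.feature_ids,
                      columns=block.sample_ids)
    df.to_csv(path, sep=delimiter, float_format="%.17g")


def align_samples(blocks: list[OmicsBlock]) -> MultiOmicsSet:
    """Restrict every block to the shared samples, in lexicographic order.

    Raises if the intersection of sample IDs across blocks is empty.
    """
    if not blocks:
        raise ValueError("need at least one block")
    shared = set(blocks[0].sample_ids)
    for b in blocks[1:]:
        shared &= set(b.sample_ids)
    if not shared:
        raise ValueError("blocks share no sample IDs")
    order = sorted(shared)
    return MultiOmicsSet([b.subset_samples(order) for b in blocks], order)


def concatenate(ms: MultiOmicsSet) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Row-stack the aligned blocks into one total_features x samples matrix."""
    X = np.vstack([b.values for b in ms.blocks])
    return X, list(ms.boundaries)


def write_gmt(sets: dict[str, list[str]], path, description: str = "spica") -> None:
    """Write feature sets in GMT-like format: name, description, members."""
    with open(path, "w") as fh:
        for set_name, members in sets.items():
            fh.write("\t".join([set_name, description, *members]) + "\n")
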