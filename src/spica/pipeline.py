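"""End-to-end orchestration: config handling and the full co-module pipeline.

Stage order: normalize -> align/concatenate -> PCA reduction -> wavelet
sparse approximation -> multi-run constrained ICA -> basis pooling -> affinity
propagation -> signature aggregation -> element selection. Every stage's
effective parameters and seeds are recorded in a run log so a run can be
reproduced exactly.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import consensus as cns
from .affinity_propagation import APCResult
from .constrained_ica import ICAConfig, ICADecomposition, reconstruct
from .evaluation import sample_correlations
from .io_model import (MultiOmicsSet, OmicsBlock, align_samples, concatenate,
                       read_expression, write_gmt)
from .preprocess import PCAResult, normalize, pca_reduce
from .sparse_approx import SparseApprox, sparse_approximate

__all__ = ["DEFAULT_CONFIG", "load_config", "run_pipeline", "PipelineResult"]

DEFAULT_CONFIG: dict = {
    "inputs": [],          # [{path, name, delimiter, orientation}]
    "normalize": {"method": "log_cpm"},
    "pca": {"threshold": 0.90, "max_k": None},
    "sparse": {"kind": "wavelet_packet", "family": "db4", "level": None,
               "quality": 0.95},
    "ica": {"n_components": None, "max_iter": 500, "tol": 1e-6, "seed": 0},
    "apc": {"metric": "neg_sqeuclid_signfree", "preference": "median",
            "damping": 0.9, "max_iter": 1000},
    "consensus": {"n_runs": 20, "alpha": 0.05, "zscore_scope": "joint",
                  "combine": "intersection"},
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = val
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Defaults merged with a YAML/JSON config file and explicit overrides."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError(f"config {path} must be a mapping")
        cfg = _merge(cfg, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


@dataclass
class PipelineResult:
    """Everything a pipeline run computed, for programmatic use."""

    ms: MultiOmicsSet
    pca: PCAResult
    sparse: SparseApprox
    decomps: list[ICADecomposition]
    apc: APCResult
    comodules: cns.CoModuleSet
    reconstructions: list[np.ndarray]
    metrics: dict
    config: dict
    seed: int


def load_blocks(cfg: dict) -> list[OmicsBlock]:
    blocks = []
    for spec in cfg["inputs"]:
        path = Path(spec["path"])
        if not path.exists():
            raise FileNotFoundError(f"input matrix not found: {path}")
        blocks.append(read_expression(
            path, delimiter=spec.get("delimiter", "\t"),
            orientation=spec.get("orientation", "features_in_rows"),
            name=spec.get("name", path.stem),
        ))
    return blocks


def run_pipeline(config: dict, blocks: list[OmicsBlock] | None = None,
                 seed: int | None = None, out_dir=None,
                 stage: str = "select") -> PipelineResult:
    """Run the pipeline through ``stage`` in {'decompose','consensus','select'}.

    ``blocks`` may be supplied directly; otherwise they are read from the
    config's ``inputs``. ``seed`` overrides ``ica.seed`` as the base seed of
    the multi-run stage. When ``out_dir`` is given, artifacts (TSV matrices,
    GMT sets, metrics JSON, run log) are written there.
    """
    cfg = _merge(DEFAULT_CONFIG, config)
    if blocks is None:
        blocks = load_blocks(cfg)
    if not blocks:
        raise ValueError("no input blocks provided")
    base_seed = int(cfg["ica"]["seed"] if seed is None else seed)

    blocks = [normalize(b, cfg["normalize"]["method"]) for b in blocks]
    ms = align_samples(blocks)
    X, boundaries = concatenate(ms)

    pca = pca_reduce(X.T, threshold=cfg["pca"]["threshold"],
                     max_k=cfg["pca"]["max_k"])
    sa = sparse_approximate(pca.reduced, family=cfg["sparse"]["family"],
                            level=cfg["sparse"]["level"],
                            quality=cfg["sparse"]["quality"],
                            kind=cfg["sparse"]["kind"])

    ica_cfg = ICAConfig(n_components=cfg["ica"]["n_components"],
                        max_iter=cfg["ica"]["max_iter"],
                        tol=cfg["ica"]["tol"], seed=base_seed)
    n_runs = int(cfg["consensus"]["n_runs"]) if stage != "decompose" else 1
    decomps = cns.multi_run(sa, ica_cfg, n_runs=n_runs, base_seed=base_seed,
                            block_slices=boundaries)

    recons = reconstruct(decomps[0], ms, pca, dictionary=sa.dictionary)
    corr = {}
    for blk, X_hat in zip(ms.blocks, recons):
        _, mean, sd = sample_correlations(blk.values, X_hat)
        corr[blk.name] = {"mean": mean, "sd": sd}

    apc_res = None
    cms = None
    if stage in ("consensus", "select"):
        cols, prov = cns.pool_basis(decomps)
        apc_res = cns.cluster_basis(
            cols, metric=cfg["apc"]["metric"],
            preference=cfg["apc"]["preference"],
            damping=cfg["apc"]["damping"],
            max_iter=cfg["apc"]["max_iter"], seed=base_seed)
        cms = cns.aggregate(decomps, apc_res, prov)
        if stage == "select":
            cms = cns.select_elements(
                cms, ms, alpha=cfg["consensus"]["alpha"],
                zscore_scope=cfg["consensus"]["zscore_scope"],
                combine=cfg["consensus"]["combine"])

    metrics = {
        "n_samples": len(ms.sample_ids),
        "total_features": ms.total_features,
        "pca_k": pca.k,
        "sparse_quality": sa.quality,
        "sparse_nnz_fraction": sa.nnz_fraction,
        "n_runs": len(decomps),
        "n_components": decomps[0].n_components,
        "pooled_columns": len(decomps) * decomps[0].n_components,
        "reconstruction_correlation": corr,
    }
    if apc_res is not None:
        metrics["n_clusters"] = apc_res.n_clusters
        metrics["apc_converged"] = bool(apc_res.converged)
    if cms is not None and cms.final:
        metrics["final_set_sizes"] = {b: len(s) for b, s in cms.final.items()}

    result = PipelineResult(ms=ms, pca=pca, sparse=sa, decomps=decomps,
                            apc=apc_res, comodules=cms,
                            reconstructions=recons, metrics=metrics,
                            config=cfg, seed=base_seed)
    if out_dir is not None:
        _write_artifacts(result, Path(out_dir), stage)
    return result


def _write_artifacts(res: PipelineResult, out: Path, stage: str) -> None:
    out.mkdir(parents=True, exist_ok=True)
    fids = res.ms.feature_ids_concat()
    dec = res.decomps[0]
    comp_ids = [f"IC{j:03d}" for j in range(dec.n_components)]
    dim_ids = [f"dim{j:03d}" for j in range(dec.A.shape[0])]
    pd.DataFrame(dec.W, index=comp_ids, columns=dim_ids).to_csv(
        out / "unmixing_W.tsv", sep="\t", float_format="%.10g")
    pd.DataFrame(dec.A, index=dim_ids, columns=comp_ids).to_csv(
        out / "basis_A.tsv", sep="\t", float_format="%.10g")
    pd.DataFrame(dec.S, index=comp_ids, columns=fids).to_csv(
        out / "modules_S.tsv", sep="\t", float_format="%.10g")

    if res.apc is not None:
        prov = res.comodules.provenance
        lab = pd.DataFrame({
            "run": [r for r, _ in prov],
            "component": [j for _, j in prov],
            "cluster": res.comodules.cluster_labels,
        })
        lab.to_csv(out / "cluster_labels.tsv", sep="\t", index=False)
        sig = pd.DataFrame(
            {f"cluster{ex}": v for ex, v in res.comodules.signatures.items()},
            index=fids)
        sig.to_csv(out / "signatures.tsv", sep="\t", float_format="%.10g")

    cms = res.comodules
    if cms is not None and cms.selected:
        sets = {}
        for ex in cms.clusters:
            for bname, members in cms.selected[ex].items():
                sets[f"cluster{ex}|{bname}"] = sorted(members)
        for bname, members in cms.final.items():
            sets[f"final|{bname}"] = sorted(members)
        write_gmt(sets, out / "comodules.gmt")
        rows = []
        for ex in cms.clusters:
            z = cms.zscores[ex]
            for blk, (lo, hi) in zip(res.ms.blocks, res.ms.boundaries):
                sel = cms.selected[ex][blk.name]
                for i, fid in enumerate(blk.feature_ids):
                    rows.append((fid, blk.name, ex, z[lo + i], fid in sel))
        pd.DataFrame(rows, columns=["feature", "block", "cluster", "zscore",
                                    "selected"]).to_csv(
            out / "selection.tsv", sep="\t", index=False,
            float_format="%.6g")

    with open(out / "metrics.json", "w") as fh:
        json.dump(res.metrics, fh, indent=2)
    log = {"stage": stage, "seed": res.seed, "config": _jsonable(res.config),
           "run_seeds": [d.seed for d in res.decomps]}
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
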