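# spica — sparse ICA for ceRNA co-module discovery

`spica` identifies **co-expression co-modules** — sets of mRNAs, miRNAs and
lncRNAs that share a common latent activation pattern across the same
samples — from sample-matched multi-block expression matrices. Co-modules of
this kind are the natural unit of analysis under the competing-endogenous-RNA
(ceRNA) hypothesis, in which lncRNAs, mRNAs and other transcripts co-regulate
one another by competing for shared miRNA binding sites. The intended users
are computational biologists with two or more expression matrices (features ×
samples, e.g. TCGA-style mRNA/miRNA/lncRNA profiles) over a common sample
set.

## The method

The blocks are row-concatenated into X = (X₁; …; X_K) and modeled as a blind
source separation problem

    X = A · S,    S = (S₁, …, S_K)

where A is a common basis over a reduced sample space and each row of the
module matrix S is one module's loading over all features. The pipeline:

1. **Normalization** per block (log₂ counts-per-million by default) and
   sample alignment; the working matrix is reduced along the sample
   dimension by **PCA** to the smallest number of components reaching 90%
   cumulative explained variance.
2. **Sparse approximation** X ≈ C_X·Φ, with Φ an orthonormal wavelet-packet
   basis chosen by a best-basis search maximizing a Gini sparsity index over
   tree leaves, keeping the largest coefficients up to a target retained
   energy ("sparsity quality", default 0.95). Dominantly expressed genes in
   a module are few, so sparsity matches the structure of the signal and the
   decomposition then runs in coefficient space: C_X ≈ A·C_S.
3. **Constrained ICA**: each unmixing direction w maximizes the negentropy
   approximation J(w) = (E[G(wᵀz)] − E[G(v)])², G = log cosh, v ~ N(0,1),
   subject to the unit-variance equality constraint E[(wᵀz)²] − 1 = 0,
   solved by an augmented-Lagrangian fixed-point iteration with symmetric
   decorrelation on whitened data.
4. **Consensus**: the decomposition is repeated (default 20 runs), all basis
   columns are pooled (20 × 40 = 800 in the reference configuration) and
   clustered by **affinity propagation** (responsibility/availability message
   passing, sign-free similarity). Each cluster's module rows are
   sign-aligned and averaged into a consensus signature.
5. **Selection**: signatures are z-scored and features in the two-sided
   α = 0.05 tail (|z| ≥ 1.96) are selected per block; the per-block final
   sets combine the clusters' selections.

A seeded synthetic generator plants ground-truth co-modules (Laplace
activations × sparse ± loadings + Gaussian noise) so every stage is testable
without any data download, and an evaluation module scores reconstruction
fidelity (per-sample Pearson r), source recovery (Amari index) and set
recovery (precision/recall/F1).

## Worked example

Simulate three coupled blocks (60 samples; 400/80/200 features; 4 planted
co-modules at SNR ≈ 5), run the pipeline, and score against the truth:

```bash
spica simulate --out-dir data --seed 1
cat > cfg.yaml <<'YAML'
inputs:
  - {path: data/mRNA.tsv, name: mRNA}
  - {path: data/miRNA.tsv, name: miRNA}
  - {path: data/lncRNA.tsv, name: lncRNA}
normalize: {method: none}        # generator emits continuous intensities
ica: {n_components: 4}           # matched to the latent dimension
consensus: {n_runs: 5, combine: union}
YAML
spica run --config cfg.yaml --seed 0 --out-dir out
spica evaluate --truth data/truth.json --results out --out scores.json
```

The `run` command prints the run metrics, e.g.

```json
{
  "n_samples": 60,
  "total_features": 680,
  "pca_k": 18,
  "sparse_nnz_fraction": 0.204,
  "pooled_columns": 20,
  "n_clusters": 4,
  "final_set_sizes": {"mRNA": 95, "miRNA": 30, "lncRNA": 59}
}
```

PCA kept 18 sample-space dimensions at the 90% threshold, 20 basis columns
(5 runs × 4 components) were clustered into 4 consensus co-modules — one per
planted module — and the final per-block sets contain 95/30/59 features.
`evaluate` then reports how well those sets match the planted membership:

```json
"pooled": {"precision": 1.0, "recall": 0.958, "f1": 0.979}
```

i.e. every selected feature is truly planted and ~96% of planted features
are recovered. Artifacts written to `out/` include the decomposition
matrices (TSV), cluster labels and signatures, per-cluster and final feature
sets (GMT-like), a per-feature selection table and a run log with all
effective parameters and seeds. The same steps are available from Python via
`spica.generate`, `spica.run_pipeline` and `spica.set_recovery`.

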