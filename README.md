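# epiconv

Batch-aware joint analysis of single-cell ATAC-seq, built on cell–cell
similarities computed directly from binarized accessibility profiles.

## The problem

scATAC-seq data are near-binary and extremely sparse: a cell either yields a
fragment in a peak or it does not. Most integration pipelines first learn a
latent embedding (LSI, topic models, autoencoders) and correct batch effects
there, which couples the correction to whatever the latent model kept — and
discards everything it dropped. `epiconv` instead works on the cell–cell
similarity matrix itself:

1. **Similarity.** For a binarized peak × cell matrix *M*, the similarity is
   the co-accessibility count matrix *S* = *M*ᵀ*M*, normalized by library
   size: *s*ᵢⱼ = log((*S*ᵢⱼ + 1) / (*L*ᵢ·*L*ⱼ)) with *L*ᵢ the number of
   accessible peaks in cell *i*.
2. **Decomposition with residuals.** *S* = *X*Λ*X*ᵀ + *R*, keeping the
   *r* = 30 eigenvalues of largest magnitude (*S* is indefinite; negative
   eigenvalues are eligible). The residual *R* is kept, not discarded.
3. **Correction.** Batch effects are removed by shifting query cells'
   eigenvector rows: cross-batch *k*-nearest-neighbor pairs are filtered by a
   per-reference-cell ±2σ plausibility band in every eigenvector, query cells
   retaining ≥ 5 neighbors become *anchors* whose correction vector is the
   mean displacement toward their neighbors, and all other cells inherit the
   weighted mean of their 10 most similar anchors on a shared-nearest-neighbor
   (SNN) graph. The similarity is rebuilt from the corrected eigenvectors
   **plus the original residuals** — fine structure outside the kept
   eigenspace survives the correction.
4. **Downstream.** The (corrected) similarity becomes an SNN graph (k = 1% of
   cells, Jaccard edge weights), `max(S_snn) − S_snn` feeds UMAP as a
   precomputed distance, and Louvain clusters the UMAP fuzzy graph so that
   embedding and clustering agree. Cluster-specific peaks are called with a
   depth-adjusted hypergeometric test; batch mixing is quantified by LISI
   (the effective number of batches in each cell's neighborhood) and
   clustering accuracy by ARI.

For cohorts too large for a dense *S*, the decomposition is computed on a
cell sample and extended to remaining cells by the least-squares solution of
*S*′ = *X*ₛΛ*X*ᵤᵀ.

Intended users: computational biologists integrating scATAC-seq datasets
across protocols, labs or biological conditions, including multi-omic
(co-assay) experiments where RNA-derived principal components can steer the
correction.

## Worked example

```python
from epiconv import (SimulationConfig, constant_shift_batch, IntegrationConfig,
                     integrate_datasets, reconstruct, build_snn, snn_to_distance,
                     umap_graph, lisi, best_resolution_ari)

# two batches, 3 shared cell types, 200 cells/type/batch; batch 1 has 30%
# of peaks attenuated to 20% accessibility (a strong protocol effect)
mats, truth = constant_shift_batch(SimulationConfig(seed=1), fraction=0.3,
                                   multiplier=0.2)
dec, log = integrate_datasets(mats, IntegrationConfig(seed=1))

emb, G = umap_graph(snn_to_distance(build_snn(reconstruct(dec))), seed=1)
print(lisi(emb, dec.batch_labels, perplexity=30).mean())
ari, res = best_resolution_ari(G, truth["type"].to_numpy(), seed=1)
print(ari, res)
```

prints

```
1.8563378924927898
1.0 0.2
```

Mean LISI of 1.86 (maximum 2 for two batches) says the two batches are
almost perfectly interleaved after correction — before integration the same
measurement gives 1.57 — while an ARI of 1.0 against the planted cell types
says the correction did not blur biology: every cell still clusters with its
own type (best over Louvain resolutions 0.2–2.0, here at 0.2).

The same pipeline is scriptable from the shell (`epiconv simulate`,
`epiconv count`, `epiconv filter`, `epiconv integrate`, `epiconv cluster`,
`epiconv da`, `epiconv eval`, ...); see `epiconv --help`.

`epiconv count` expects a fragment file (BED-like TSV: chrom, start, end,
barcode) and a peak BED. Peak calling itself is out of scope; peaks produced
by MACS2 in cut-site mode (`--nomodel --nolambda --keep-dup all --shift -95
--extsize 200`) on the pooled fragment ends are a good input. Both ends of
each fragment are counted independently against peaks (BED half-open
coordinates; the end cut site is `end − 1`), counts are binarized, and cells
with fewer than 1,000 accessible peaks are dropped by `epiconv filter`.

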