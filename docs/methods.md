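# Methods

## Similarity model

The input is a binarized peak × cell matrix *M* (an entry is 1 iff at least
one fragment end of that cell falls in that peak). The raw similarity
*S* = *M*ᵀ*M* counts co-accessible peaks per cell pair; its diagonal is the
per-cell library size *L*ᵢ (number of accessible peaks). Deeply sequenced
cells co-occur with everything, so the raw count is normalized by the
library-size product with a pseudocount and a log transform:

    s_ij = log((S_ij + c) / (L_i · L_j)),  c = 1 by default.

The log tempers depth-driven scale differences before eigendecomposition;
a linear mode (`log_transform=False`) and the pseudocount are exposed as
configuration and recorded in logs. The diagonal is normalized like any
other entry, keeping *S* a well-defined symmetric matrix. The exact
pseudocount/log-base combination is the least constrained choice in the
model; both switches exist so users can probe sensitivity.

Dense *S* is refused above 20,000 cells. Beyond that, decompose a uniform
seeded cell sample (default min(n, 10,000)) and extend by least squares
(below).

## Eigendecomposition with residual retention

*S* is symmetric but indefinite (the log-normalized values are negative and
the spectrum has large negative tails), so the *r* retained eigenpairs are
those of largest *absolute* eigenvalue, r = 30 by default. The residual
*R* = *S* − *X*Λ*X*ᵀ is stored explicitly and added back at reconstruction.
The kept eigenspace carries the dominant biological and technical axes —
batch correction operates there — while *R* carries everything the 30
dimensions cannot express. On real chromatin data that includes genuine
fine-grained co-accessibility structure, which is why the default pipeline
reconstructs *S* = *X*_corrected Λ *X*_corrected^T + *R* rather than the
rank-r approximation alone.

Numerical conventions: `scipy.linalg.eigh` on the dense matrix; stable sort
by |λ|; each eigenvector's largest-magnitude component is made positive so
results are reproducible across LAPACK drivers.

For unsampled cells, given the normalized cross-similarity *S*′ (sampled ×
unsampled), the least-squares solution of *S*′ = *X*ₛΛ*X*ᵤᵀ under orthonormal
*X*ₛ is *X*ᵤ = *S*′ᵀ*X*ₛΛ⁻¹ (an eigenvalue within 1e-12 of zero is an
error — reduce r). Residuals are representable only where similarity was
actually computed: the sampled block keeps its *R*, the cross block stores
*S*′ − *X*ₛΛ*X*ᵤᵀ, and unsampled × unsampled residuals are set to 0. That
zero block is the approximation's accepted information loss.

## Batch correction

All geometry lives in eigenvector space; neighbor searches use the
eigenvalue-weighted coordinates *X*·diag(|Λ|)^½, since Λ weights each
eigenvector's contribution to the similarity (a plain-*X* mode exists).

For query batch A against reference B:

1. **Cross-batch KNN.** Each query cell finds its k₁ nearest reference
   cells, each reference cell its k₂ nearest query cells. Defaults
   k₁ = k₂ = max(20, round(0.01·|other batch|)) — a scale-free default with
   a floor that keeps the σ estimate below meaningful.
2. **2σ filter.** For each reference cell *b*, u_b and σ_b are the
   per-dimension mean and standard deviation (ddof = 1, hence k₂ ≥ 2) of
   its k₂ query neighbors, over all eigenvectors and, for multi-omic data,
   all supplied RNA PCs. Query cell *a* loses neighbor *b* iff *a* lies
   outside u_b ± 2σ_b in **any** dimension: if cells more similar to *b*
   exist in A and *a* is not among them, *b* is an implausible partner.
   With σ_b = 0 in a dimension the band degenerates to a point — only query
   cells exactly at u_b pass. Per-dimension bands are invariant to the
   |Λ|^½ scaling, so the filter is computed on plain eigenvector
   coordinates. The filter only ever removes links.
3. **Anchors and propagation.** Query cells with ≥ 5 retained neighbors are
   anchors; an anchor's correction vector is the unweighted mean of
   (X_b − X_a) over its retained neighbors (a distance-weighted mean was
   considered and rejected to keep the estimator simple and unbiased at
   small k). Every other query cell takes the SNN-edge-weighted mean of its
   10 highest-SNN-weight anchors (ties broken by cell index); the SNN graph
   over query cells is built from their own eigenvector coordinates, or
   from RNA PCs when provided (transcriptome neighborhoods are typically
   cleaner in shallow co-assay data). A cell with zero SNN weight to every
   anchor falls back to the global anchor mean (logged).
4. **Apply.** Query rows of X are shifted; reference rows are bitwise
   untouched; the pre-correction residual is carried over. Correcting an
   already-corrected decomposition is refused — vectors are estimated
   against the uncorrected geometry and do not compose.

Multiple datasets integrate sequentially: batch 0 is the fixed frame; each
further batch sees a union similarity whose already-integrated block keeps
its corrected values, is decomposed afresh, and is corrected toward the
growing reference. A provenance log records per step the anchor count,
kept/initial neighbor links, k₁/k₂ and r.

## Graph, embedding, clustering

The (reconstructed) similarity becomes an SNN graph: each cell keeps its
k = max(5, round(0.01·n)) most similar cells (the floor keeps tiny inputs
usable; 1% of 100 cells would be a single neighbor); the edge weight between
two cells is the Jaccard overlap of their neighbor sets (self excluded).
`max(S_snn) − S_snn` with a zeroed diagonal is passed to UMAP as a
precomputed distance; Louvain (igraph multilevel, resolution-parameterized)
runs on UMAP's symmetrized fuzzy graph so the embedding and the clustering
share one topology. UMAP and the igraph RNG are seeded (default 1); Leiden
is available behind a flag. The recommended resolution range is 0.2–2.0;
quantitative comparisons report the best ARI over that sweep.

## Differential accessibility and signatures

Per peak and cluster, a one-tailed hypergeometric test with

* N = total cells,
* n = round(cluster library-size sum / mean library size), clamped to
  [1, N] — an effective, depth-adjusted cluster size (rounded half-up:
  hypergeometric support must be integral),
* K = cells with the peak accessible, k = such cells in the cluster,
* p = P(X ≥ k), inclusive upper tail.

Peaks accessible in fewer than 1% of cells are untested. Calling uses raw
p < 0.01 — deliberately no multiple-testing correction by default, to keep
the calling rule identical across datasets being compared (BH-FDR is a
flag). A peak significant in several clusters is assigned to the one with
the highest normalized count k/n (k/n rather than k over cluster size, for
consistency with the test's own sample-size definition; ties go to the
lowest cluster id).

Per-cell signatures are (# accessible markers)/(# accessible peaks),
normalized as x_norm = (x − x₀.₀₁)/(x₀.₉₉ − x₀.₀₁) with type-7 (linear)
percentile interpolation; values outside [0, 1] are kept unless clipping is
requested, and a degenerate spread (equal percentiles) is an error. The
`annotate_cells` pipeline composes DA → signatures → normalization → argmax
for supervised annotation. Peak-to-promoter links take the same-chromosome
promoter of minimal edge distance (0 when overlapping, book-ended intervals
at distance 1; midpoint mode optional; ties go to the lower start
coordinate). Marker/expression agreement is summarized by the enrichment
fold change N_common/(N_ATAC·N_RNA)·N_total, equal to 1 under independence.

## Metrics

LISI follows the perplexity-calibrated Gaussian-kernel construction: per
cell, the 3·perplexity nearest neighbors (self excluded), kernel bandwidth
found by bisection to match entropy log(perplexity) (tolerance 1e-5, 50
iterations), batch probabilities from the normalized weights, and
LISI = 1/Σ p_b². Values lie in [1, B] by construction. Default perplexity
30; computed on the 2-D embedding by default, with a precomputed-distance
option (the choice is recorded — graph-derived distance matrices carry many
exact ties, which make neighbor selection order-dependent, so the embedding
is the more stable default). Over-fit counting applies a strict
LISI > 1.1 threshold over an evaluation mask — e.g. cells of a
query-unique type, where any mixing with reference cells means the
correction invented correspondence that does not exist. ARI is the standard
pair-counting form (scikit-learn), cross-checked in the test suite against
an independent Hubert–Arabie pair-concordance oracle.

## Synthetic data generator

The generator emulates the statistical skeleton of a multi-batch scATAC
experiment: cell types with disjoint marker-peak blocks (accessibility q_in
inside the owning type, q_out elsewhere), a lognormal per-cell library
scale s_c (σ = 0.35), and per-batch technical effects that multiply the
accessibility of a random peak fraction f by m. Each entry is an
independent Bernoulli draw of probability clip(s_c·q·b, 0, 1); all
randomness descends from one seed via SeedSequence spawning, so identical
configs are bit-identical. Optionally one extra type is planted in a single
batch (the over-fitting control).

Defaults: 3,000 peaks, 3 types × 200 cells × 2 batches, 150 markers/type,
q_in = 0.5, q_out = 0.1. These put cells at a 10–13% accessible fraction
(≈ 300–400 peaks of 3,000), the desk-scale analogue of cells passing the
≥ 1,000-accessible-peaks quality filter: the fixture compresses the peak
space ~50×, and what must be preserved for the method to operate in its
intended regime is the signal-to-noise of pairwise co-accessibility counts,
not the raw peak count. Markedly sparser settings (e.g. q_out = 0.02 at
2,000 peaks, ~90 accessible peaks/cell) describe cells that the quality
filter exists to remove, and there similarity estimates are Poisson-noise
dominated for every variant of the method.

What the generator does *not* emulate — and what passing tests therefore do
not show about real data:

* **Co-accessibility correlation.** Peaks are independent given the type,
  so the planted structure is exactly low-rank and the decomposition
  residuals contain only sampling noise. The residual-retention comparison
  on this generator is consequently a tie within seed noise (both variants
  reach ARI 1.0; mean LISI differs by ~0.02 with sign varying across
  seeds). The benefit of retaining residuals is expected from fine-grained
  co-accessibility structure shared across batches in real chromatin data,
  which an independent-Bernoulli model cannot represent by construction. A
  block-correlated mode (a shared latent factor per type) is the natural
  stress-test extension.
* Fragment-level features: fragment lengths, TSS enrichment, duplicate
  structure, doublets.
* Batch effects beyond peak-wise multiplicative attenuation (no chemistry-
  specific fragment-length biases, no cell-composition shifts other than
  the explicit unique-type option).

## Problem sizes and numerical choices in the test suite

End-to-end checks run at 1,200–1,350 cells and 2,000–3,000 peaks — large
enough that the SNN graph (k = 12–13) and LISI (perplexity 30) operate
meaningfully, small enough for interactive runs. Null calibration uses 200
label permutations on 240 cells × 800 peaks and compares the significant-
call rate to the nominal 0.01 within 3 binomial standard errors of the
200-permutation mean; the hypergeometric test is discrete, so the true
rate sits slightly below nominal (≈ 0.006 measured). Oracle-equivalence
checks are exact (dot products, integer tail enumeration) or at 1e-8
(eigensolver agreement, rank-r reconstruction).

## Known limitations

* Dense n × n similarity and residual storage: memory is O(n²); the
  sampling path bounds the eigensolve but reconstruction of the full
  corrected similarity still materializes n × n.
* The 2σ filter tests every kept eigenvector, including noise-dominated
  ones when r exceeds the data's intrinsic dimensionality; with r = 30 on
  simple data this makes anchors scarcer (the multivariate pass rate of a
  band test falls with dimension). Anchor counts are in the provenance log;
  inspecting per-eigenvector batch separation before choosing r is the
  intended workflow.
* Correction is a single linear shift per cell in eigenvector space;
  nonlinear batch distortions are out of scope.
* LISI on tie-heavy precomputed distances depends on neighbor tie-breaking;
  use the embedding default for comparisons.
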