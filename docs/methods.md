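# Methods

This note documents the model, the defaults and why they are set where they
are, what the synthetic generator does and does not emulate, and the
numerical choices a maintainer would want written down.

## Model and assumptions

The method is transductive and full-graph: all $N$ spots of one section are
embedded and clustered jointly, with no train/test split. It assumes the two
omics modalities and the coordinates describe the *same* spots of the *same*
section (enforced by an inner join on spot IDs with logged drop counts), and
that spatial domains are regions that are simultaneously spatially compact
and molecularly distinct — the two graph families (spatial kNN, embedding
top-correlation) encode exactly those two notions of neighborhood, and the
attention sites learn, per spot, how much each view should contribute.

The language-model embedding is consumed through a provider interface and
never computed here: an external file (one row per aligned spot), an
all-zeros matrix (the ablation), or a seeded mock (a random linear projection
of the normalized expression, optionally with Gaussian noise — informative by
construction because linear projections preserve cluster geometry). The
package is therefore fully executable and testable without any pretrained
weights, and the ablation path is the same code path with a different input.

Vocabulary matching (`match_vocabulary`) is exact symbol equality after an
explicit case policy (case-sensitive by default); unmatched genes are only
excluded from what an external embedding run would see, never from the omics
branches.

## Parameters that matter

| parameter | default | units / range | rationale |
| --- | --- | --- | --- |
| `k1` | 3 | neighbors | spatial graph degree; small keeps domains' borders sharp |
| `k2` | 20 | neighbors | correlation-graph degree; larger because molecular similarity is noisier |
| `pca_dim` | 50 | components | standard input width for kNN graphs over expression |
| `latent_dim` | 64 | dimensions | width of every latent entering attention |
| `hidden_dims` | (256, 64) | dimensions | encoder widths input→256→64→64; decoders mirror them |
| `epochs` | 200 | — | Adam, full-graph; loss typically plateaus well before this |
| `learning_rate` | 1e-3 | — | Adam default for this scale |
| α₁…α₄, β₁, β₂ | 1.0 | — | equal weighting; a grid search helper can sweep them |
| `attention_epsilon` | 1e-8 | — | numerical-stability constant; provably weight-neutral (softmax shift invariance, asserted in tests) |
| GMM restarts | 10 | — | seeded k-means initializations, best by likelihood |

Layer rule: $Z^{(l+1)} = \mathrm{ReLU}(\hat A Z^{(l)} W^{(l)})$ for the first
two layers, linear for the third; decoders mirror widths with a linear final
layer. Layers carry no bias terms by default (`use_bias` switches them on).

## Open design points, and how they were resolved

* **Graph operator.** The convolution uses the symmetrically normalized
  adjacency with self loops, $\hat A = D^{-1/2}(A+I)D^{-1/2}$ (standard
  graph-convolution practice; spectral radius ≤ 1 keeps three stacked
  products well-scaled). `use_normalized_adjacency=False` switches to the
  raw binary adjacency for literal fidelity to the propagation formula.
* **Symmetrization** is logical OR; **ties** in kNN and top-correlation
  selection break toward the lower spot index (stable argsort), making every
  graph byte-reproducible.
* **Shared encoder for the language-model branch.** One weight stack encodes
  the embedding through both the spatial and the correlation graph. Sharing
  is the weaker assumption capacity-wise and matches the naming of a single
  encoder used twice.
* **Correspondence-cycle graph.** The decode→re-encode cycle runs on the
  spatial graph for both directions: spatial structure is the one view the
  modalities share by construction.
* **Attention parameters** are independent per fusion site (five sites, each
  with its own $W_\omega, \mu_\omega$); sharing them across sites would
  couple views with different semantics.
* **Initialization** is Glorot-uniform from a seeded generator; training is
  single-threaded numpy and bit-reproducible for a fixed seed.
* **Clustering covariance model.** Components share one full covariance
  (mclust's EEE analog, sklearn `covariance_type="tied"`); the test suite
  cross-checks against R's mclust (EEE) on a blob fixture. `reg_covar=1e-6`
  provides the diagonal jitter that absorbs singular covariances. The number
  of domains is user-supplied, matching how annotated sections are evaluated.
* **Metric normalizations** are fixed: NMI uses the arithmetic mean of the
  entropies; AMI uses the max. Both are documented because different defaults
  circulate.
* **PCA sign convention:** each component is flipped so its
  largest-magnitude loading is positive, which makes embeddings identical
  across BLAS builds.
* **Autodiff.** The training objective is differentiated by a small
  tape-based reverse-mode engine written for this package (the exact op set
  the model needs: sparse-dense products, dense products, ReLU/tanh,
  row-softmax, row-scaling, MSE). Its gradients are verified against central
  finite differences in the test suite, and Adam is implemented on top.

## Synthetic data: what it emulates, what it does not

`SyntheticSpec` defaults describe the reference section used throughout the
tests: a 20×20 lattice (400 spots), four rectangular block domains (compact
contiguous regions, like annotated anatomy), 120 RNA features as
negative-binomial counts (dispersion 0.5, var = m + 0.5 m²) with independent
Bernoulli dropout (rate 0.2), and 40 ADT features as continuous log-normal
abundances (ATAC mode instead draws sparse binarized accessibility). Layouts
`stripes` and `voronoi` are available for less regular geometry.

**Effect-size calibration.** `effect_size` is the between-domain shift of a
feature's (log-)mean in units of its within-domain noise SD. For the NB
modality that SD is taken on the log1p scale via the delta method,
$\mathrm{SD}(\log(1+X)) \approx \sqrt{m + 0.5m^2}/(1+m)$, per feature; for
ADT the log-normal σ = 0.5 plays that role; for ATAC the shift is applied in
logit units. `effect_size=0` is an exact null (domain means identical by
construction). `mod2_effect_size` can zero the second modality independently,
which is how the ablation contrast is constructed: domain signal that the
second modality lacks, carried instead by the informative embedding
(per-domain anchor vectors plus Gaussian noise).

What the generator does **not** model: spot bleed-over and segmentation
error, library-size gradients across the section, batch effects between
sections, mRNA–protein correlation structure within a spot, or images.
Passing tests therefore demonstrate that the implementation recovers planted
structure under a clean noise model at desk scale — not performance on real
tissue, which additionally depends on the external embedding quality and on
annotation granularity.

Observed behavior worth recording: with *all* omics effects zeroed, the
informative embedding alone does not rescue clustering — the reconstruction
targets are the omics PCA embeddings, so the final latent cannot ignore them.
The embedding is supplementary by design, consistent with its role as a
booster of sensitivity rather than a replacement for the data. At the default
effect size both the informative and the zero-embedding runs saturate
(ARI = 1.0); the contrast becomes strict at weaker RNA effects (≈0.5 SD).

## Problem sizes and runtimes

All tests and the acceptance script run on one CPU: encoder/decoder oracle
checks on graphs with N ≤ 20 (100 cases), training contracts on N = 15–40,
and the end-to-end runs on the 400-spot reference section (a full 200-epoch
fit plus clustering takes ~20 s; the whole acceptance script a few minutes).
These sizes were chosen so the complete evidence chain — unit oracle,
property suite, end-to-end recovery, ablation — reruns quickly and
deterministically.

## Known limitations

* Full-graph dense training: memory and time scale with N²-ish graph
  products; comfortable to ~10⁴ spots, not beyond.
* No image-based modality, histology alignment, or deconvolution.
* Exactly two omics modalities per run (the fusion topology is fixed).
* `import_embedding` trusts row order; it can only check the row count.
* UMAP export is for visualization only and is the one non-deterministic-
  across-library-versions component (seeded within a version).
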