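# Methods

## Model

`pare` treats confounder removal as a linear model in the space of
principal coordinates.  Given samples `y_1, …, y_n` and a dissimilarity
function `d`, the matrix `A = (−d_ij²/2)` is doubly centered with the Gower
centering matrix `J = I − (1/n)11ᵀ` to give `G = J A J`; for Euclidean `d`
this equals `Y_c Y_cᵀ` of the column-centered data, and the positive part of
its eigendecomposition gives coordinates `Z = UΛ^{1/2}` that reproduce all
pairwise distances exactly.  (Some presentations write the centering matrix
as `I − 11ᵀ`; only the `1/n` form has the projection property that makes
`G = Y_c Y_cᵀ`, and that is what is implemented.)

The nuisance design `X` contains an intercept, one-hot-coded categorical
covariates with the lexicographically first level dropped, and mean-centered
continuous covariates.  The adjustment is ordinary least-squares
residualization of every coordinate column: `E = (I − H) Z` with
`H = X(XᵀX)⁻¹Xᵀ` (computed via QR for stability).  The intercept column is
algebraically inert here — PCoA coordinates are exactly centered — but is
kept so `H` is the textbook hat matrix and continuous covariates behave as
in OLS.  The assumptions inherited from this model: nuisance effects are
*additive* in coordinate space and shared across samples within a covariate
level; there is no group × batch interaction; covariates are exactly
observed.  When the biology is partially collinear with a confounder
(unbalanced designs), residualization removes the shared part too — that is
a property of the estimand, not a bug.

The adjusted Gram matrix `Δ = EEᵀ = (I−H)G(I−H)` is the second, equivalent
route; `tests` verify the identity to 1e−10.  For a non-Euclidean input the
coordinates route is unavailable without repair, so the general path
converts `Δ` back to genuine distances, `d̃_ij = (Δ_ii + Δ_jj − 2Δ_ij)^{1/2}`,
which are exactly the Euclidean distances among the rows of `E`.

One published formulation plugs the Gram entries `δ_ij` of `Δ` directly
into the UMAP exponential kernel.  Gram entries are inner products — they
can be negative and have a nonzero diagonal — so they are not
dissimilarities, and the canonical path here always converts to distances
first.  The literal Gram-entry kernel remains available as
`adjusted_umap_affinities(..., mode="gram")` for users who want that exact
form; the two coincide in intent (both are monotone in adjusted closeness)
but not numerically, and no default behavior depends on the literal form.

## Affinity kernels

* t-SNE: conditional probabilities `p_{j|i} ∝ exp(−d_ij²/2σ_i²)` with `σ_i`
  found by bisection so each conditional's entropy is `log2(perplexity)`
  (tolerance 1e−11, ≤ 400 iterations — tight enough that affinities and
  LISI are invariant to uniform rescaling at 1e−8); symmetrization
  `p_ij = (p_{j|i}+p_{i|j})/2n` sums to 1.
* UMAP: directed memberships `v_{j|i} = exp[−(d_ij − ρ_i)/τ_i]` restricted
  to the `n_neighbors` nearest neighbors; `ρ_i` is the distance to the
  nearest neighbor (ties broken by index order), so that neighbor's
  membership is exactly 1, and `τ_i` is bisected so the membership sum over
  the neighbor set equals `log2(n_neighbors)` — the smooth-kNN calibration
  of the reference UMAP implementation, which names the normalizing factors
  without printing the formula.  Symmetrization is the fuzzy union
  `v_ij = v_{j|i} + v_{i|j} − v_{j|i}v_{i|j}`.
* These exact constructors exist for testing and inspection; the production
  embedders (scikit-learn t-SNE, umap-learn) use their own internal
  equivalents.  The package's contract deliberately covers the *inputs*
  handed to an embedder (adjusted coordinates or distances, seed, spec),
  not the stochastic optimizer output.

## Defaults and parameters

| parameter | default | rationale |
|---|---|---|
| t-SNE perplexity | 10 | standard choice for datasets of hundreds to thousands of samples; the value used in all evaluation here |
| UMAP n_neighbors | 15 | umap-learn's default neighborhood size |
| output_dim | 2 | visualization target |
| seed | 0 | all embedder randomness flows from the spec seed |
| LISI perplexity | 30 | a mid-sized neighborhood; a sweep mode exposes the dependence on neighborhood size |
| eigenvalue cutoff | max(n,1)·eps·λ_max | relative rank tolerance; avoids promoting numerical noise into coordinates |
| non-Euclidean correction | Cailliez (on d), Lingoes (on d²) selectable | both realize the additive-constant idea; the constant applied is logged |

Eigenvector signs are fixed so each column's largest-magnitude entry is
positive, making output reproducible across linear-algebra backends; tied
eigenvalues still permit arbitrary rotations within their eigenspace, so
tests compare distance matrices or Procrustes-aligned subspaces, never raw
coordinate values.

`n_coords` truncation keeps the top-k columns of `E` ordered by the source
eigenvalues of `Z`, i.e. truncation happens *after* adjustment by default
(a `truncate_before_adjust` flag gives the other order).  Note the ordering
caveat: after adjustment the top unadjusted eigendirections may carry
little residual variance, so the top-2 *adjusted view* is obtained by
eigendecomposing `Δ` (what the `pcoa` embedder does), not by taking the
first two columns of `E`.

## Synthetic data

The generator emulates a multi-batch study:
`y_i = μ_group(i) + γ_batch(i) + β·c_i + ε_i`, with group means and batch
shifts drawn once per level from isotropic Gaussians scaled by
`group_effect` and `batch_effect`, an optional standard-normal continuous
confounder `c_i` with loading scale `β`, and isotropic noise.  Defaults —
5 groups × 4 batches × 30 samples (n = 600), 50 features, group_effect 1,
batch_effect 3, noise SD 0.5 — describe a study in which the batch shift is
three times the biological separation, the regime where an unadjusted
embedding is dominated by batch; at these scales the expected between-group
distance (≈ `group_effect·√(2m)` ≈ 10) comfortably exceeds the noise floor
(≈ `noise_sd·√(2m)` ≈ 5), so the biology is recoverable once batch is
removed.  A Poisson-log-normal variant mirrors the category structure of a
pooled single-cell RNA-seq resource (13 cell types, 4 studies) and emits
both dense CSV and MatrixMarket forms to exercise both readers.

What the generator does **not** emulate: dropout and overdispersion beyond
Poisson-log-normal, library-size variation, nonlinear batch effects,
group × batch interactions (off by default; a dial exists to probe
misspecification), or unbalanced designs.  Passing tests therefore
demonstrate correctness of the adjustment algebra and the qualitative
deconfounding phenomenon under an additive linear batch model — the model
the method assumes — not robustness to real single-cell noise.

## Metrics

LISI is computed exactly on all n−1 neighbors (no kNN approximation):
Gaussian weights calibrated to the target perplexity by the same bisection
contract as the t-SNE conditionals, summed per category with self excluded
(self-inclusion would floor the index above 1 artificially), then inverted
through the Simpson index.  Values lie in `[1, n_categories]`.  Silhouette
uses Euclidean distance in whatever coordinate space is supplied (the 2-D
embedding in all shipped workflows; the choice is recorded by the caller),
with the singleton convention `s_i = 0`; the implementation delegates to
scikit-learn and is checked against a brute-force textbook oracle in the
tests.  Reports carry an explicit direction tag: labels that *should* mix
(batch, study, scanner) are better with higher LISI / lower ASW; labels
that should separate (cell type, diagnosis, subject) are better with lower
LISI / higher ASW.

## Numerical and design choices

* Rank-deficient designs (e.g. donor nested in batch) are rejected with the
  offending column pair named, never silently pseudo-inverted — a nested
  specification is a modeling error the user must resolve.  A constant
  covariate centers to the zero column and is rejected the same way.
* Negative values under the square root in `adjusted_distances` (possible
  for non-PSD input beyond tolerance) are clamped to zero with a warning.
* Duplicate points make some perplexities infeasible; the offending sample
  is named in the error.
* Degenerate geometry (all eigenvalues non-positive, i.e. constant data)
  yields an empty coordinate set with a warning rather than an exception.
* Determinism: both bundled embedders are run single-threaded with a fixed
  `random_state`; identical config + seed reproduces embedding CSVs byte
  for byte, and the run manifest records seed, spec, eigen-spectrum summary
  and software versions.

## Problem sizes

The shipped test-suite and acceptance runs use n between 8 and 600 with up
to 50 features — large enough that the deconfounding phenomenon (batch
silhouette ≈ 0.9 before adjustment, ≈ 0 after, with group silhouette
retained) is stable across seeds, small enough that exact `n × n`
eigendecompositions and all-neighbor LISI are instantaneous.  The
algorithms are `O(n³)` in the eigendecomposition and `O(n²)` per LISI
sample; for much larger studies the `n_coords` cap bounds the embedder
input dimension.

## Known limitations

* Only linear residualization: longitudinal (mixed-model) or smooth
  (additive-model) nuisance structure is out of scope.
* Partial embeddings are for exploratory visualization; the adjusted
  coordinates are not a harmonized dataset and should not replace the
  original data in downstream inference.
* No out-of-sample projection of new samples onto an existing embedding.
* The exact affinity constructors are dense (`O(n²)` memory) and intended
  for desk-scale analysis and testing.
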