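# Methods

## Problem setting and model

Two samples from the same tissue: a spatial reference
`{(x_st_j, y_st_j)}` of m spots with coordinates, and a dissociated
query `{x_sc_i}` of M cells without. Both measure expression on a
common gene panel after preprocessing. The goal is a map
`f : expression → R²` trained on the reference and applied to the
query.

The obstacle is covariate shift: dissociation, capture efficiency and
sampling make the query's latent-expression distribution `p_sc(z)`
differ from the reference's `p_st(z)`, while the biological link
between latent expression and position is assumed shared,
`p_sc(y|z) = p_st(y|z)`. Under that assumption the query-risk of any
regressor g equals a reference-risk weighted by the density ratio
`w(z) = p_sc(z)/p_st(z)`, which yields the training objective

    (1/m) Σ_j w(z_st_j) ‖g(z_st_j) − y_st_j‖² + Ω(g).

The package factors this into four stages, each usable on its own.

### Preprocessing (`io_prep`)

Counts are library-size normalized and log-transformed,
`x_ij = ln(s·d_ij/Σ_k d_kj + 1)` with `s = 10 000` by default, then
z-scored per gene. Each dataset is standardized with its own per-gene
mean and standard deviation; zero-variance genes are dropped and
recorded (the standardization is undefined for them). Highly variable
genes are ranked by scanpy's Seurat-style binned normalized dispersion
with lexicographic tie-breaks, selected per dataset, and intersected.
The binned statistic is designed for transcriptome-scale panels; on
panels of a few dozen same-mean genes the bins degenerate and the
ranking is not meaningful — pipelines at that scale should keep all
genes (the default when `n_hvg` is unset).

A reversible polar transform `(x, y) → (r̄·θ, r)` about a chosen center
(centroid by default) is provided for annular tissues, so a ring
unrolls into a band whose horizontal scale matches arc length at the
mean radius. The inverse recovers `r̄` as the mean of the r column; the
θ = 0/2π seam is the one place angular continuity is lost.

### Co-embedding (`coembed`)

`h` is a principal-axes basis fitted by SVD on the concatenated,
already-standardized reference expression only; the query is projected
through the same matrix. Fitting on the reference alone keeps the
"reference-based" semantics (adding query cells can never change the
basis) and makes the projection strictly linear — no re-centering at
apply time, which the z-scoring has already done. The sign of each
loading column is fixed by making its largest-magnitude entry positive,
so the basis is deterministic. Defaults: `K = min(50, H, m − 1)`; when
`H ≤ K` (e.g. a 10-gene panel) the basis is the identity. Anchor-based
methods (CCA/MNN) would slot behind the same interface but are out of
scope.

### Density-ratio estimation (`density_ratio`)

KLIEP models the ratio as a non-negative combination of unnormalized
Gaussian kernels centered on a seeded subsample of the *numerator*
(query) embedding (`k = min(100, M)` by default) and maximizes the
numerator log-likelihood subject to the normalization
`(1/m) Σ_j ŵ(z_st_j) = 1`, which makes `ŵ·p_st` a proper density.

The optimizer is projected gradient ascent with two safeguards chosen
for the package's invariants:

* the ascent direction is the gradient projected onto the constraint's
  tangent space *restricted to the active set* (coordinates pinned at
  zero with outward gradients are excluded, iteratively, until the
  direction respects the bounds). Without this reduction the later
  clip-to-nonnegative step can turn an ascent step into descent and
  the optimizer stalls well short of the optimum (verified against an
  SLSQP solution of the same constrained problem);
* backtracking line search on the step size, so the logged objective J
  is non-decreasing by construction. Convergence: ΔJ < 1e-6 or 2000
  iterations.

Bandwidth defaults to the median pairwise distance of the numerator
sample; `select_bandwidth` performs the likelihood cross-validation the
original procedure prescribes (held-out mean log ŵ over folds of the
numerator). The pooled slice-weighting fit selects its bandwidth by CV
over {0.1, 0.25, 0.5, 1, 2} × median automatically, because in a
~50-dimensional embedding the raw median heuristic oversmooths and the
fitted ratio collapses toward 1 everywhere, hiding real composition
shifts. Known limitation: with local Gaussian bases the estimate decays
beyond the outermost centers, so in far tails where the true ratio
grows the fit undershoots; tail-sensitive summaries (e.g. grid
correlations extending past the data) inherit sampling variability
from this.

### Weighted regression (`mapper`)

With several reference slices, one KLIEP model is fitted against the
pooled spots of all slices and each slice's weight is the mean ratio
over its own spots, normalized to sum to one (a slice resembling the
query composition gets more say; identical slices split evenly; a
single slice gets weight 1 by the constraint). A per-slice fit would
pin every slice's mean at exactly 1 and carry no information — this is
why the pooled denominator is used. The training loss is
`Σ_s slice_weight_s · (1/m_s) Σ_j w_js ‖g(z_js) − y_js‖²`, which
reduces to the single-slice objective above for one slice.

Per-spot weights are clipped at the 99.5th percentile (bounding the
variance a few extreme ratios would inject) and normalized to mean 1
within each slice, so weighting changes emphasis, not loss scale —
doubling all weights provably leaves the optimum unchanged.
Coordinates are min-max scaled to the unit square per slice before
training (heterologous physical frames become commensurable) and
inverted to the first slice's frame at prediction.

The regressor is a dense network `K → 256 → 64 → 2`, tanh hidden
units, inverted dropout 0.2, Adam (lr 1e-3), weight decay 1e-4 as
Ω(g), 10% validation split with early stopping (patience 20, best
weights restored), at most 500 epochs, batch size 64. One integer seed
drives initialization, batching, dropout and the split. tanh is the
default because the gene-scoring step differentiates the network: a
smooth activation gives smooth, low-variance Jacobians and
finite-difference agreement near machine precision; ReLU is available
via `MapperConfig(activation="relu")` and reproduces all headline
results. If the validation split happens to carry zero loss mass
(degenerate weighting), validation-based selection is disabled rather
than letting it freeze the initial network.

### Gene scores, knockout, velocity (`downstream`)

The SOG index is computed from the exact analytic Jacobian of the full
composition (coordinate scaler ∘ network ∘ loadings);
`method="finite_diff"` cross-checks with central differences. Units
matter: the network consumes z-scored genes, so the raw chain-rule
Jacobian is "displacement per standard deviation of the gene". When a
`PreprocessModel` is supplied, the gradient is divided per gene by
σ_g, giving "displacement per unit of expression as supplied" — the
scale on which genes of very different variance are comparable. On the
toy model this choice is decisive: the smoothed fields have σ ≈ 3–7
versus ≈ 0.6 for the organizing genes, and they acquire chance global
correlations with the coordinates (|r| up to ~0.6 at n = 500), so on
the standardized scale some field gene edges out the weakest organizing
gene for any well-fit regressor — an independent kernel-ridge oracle
tuned on held-out MSE shows the same inversion. Per unit of expression
the four organizing genes dominate robustly (margins +0.13 to +0.32
across seeds and architectures).

Knockout replaces a gene's scaled value with `(0 − μ_g)/σ_g` — the
image of a zero raw count — and re-predicts with the unchanged model.
This measures the *fixed* mapping's reliance on the gene, which is the
quantity a damage-vs-knockout-count curve needs; retraining without
the gene answers a different (and far costlier) question and is
intentionally not the default.

SpaRNA velocity is literally `f(x + v_RNA) − f(x)`; both terms share
one code path, so zero velocity gives exactly zero displacement. The
velocity must live in the network's input space; `raw_velocity_to_scaled`
divides a raw-space velocity by σ_g per gene for tools that emit raw
units.

### Evaluation (`evaluation`)

`accuracy = max(0, 1 − MSE/MSE_null)` with the null from 200 seeded
random permutations of the true positions: 1 for exact reconstruction,
~0 for a random guess, monotone in isotropic noise, and exactly
invariant to a rigid transform applied to both point sets. The four
layer indicators are operational definitions chosen to be bounded in
[0, 1] and equal to 1 at perfect reconstruction: S_C (fraction of k=30
nearest predicted neighbors sharing the cell's label — at pred = truth
this is limited only by genuine boundary mixing), ρ_C (one minus the
total-variation distance between predicted and true binned densities,
20×20 bins over the joint frame), A_C and P_C (min/max ratios of
convex-hull areas and perimeters per layer; layers under 3 cells are
reported missing and excluded from means). Moran's I uses
row-normalized k-nearest-neighbor weights (k = 6), computed directly
from its definition.

## Synthetic data (`simulation`)

The generators define the study conditions; their defaults are the
conditions under which every result in the test suite is measured.

* **Toy model** (n = 500 default): genes 1–4 ~ U(0, 2) i.i.d.;
  coordinates `y₁ = 2 sin X₁ + 1.5 X₂² + N(0, R)`,
  `y₂ = −e^{−X₃} + 2.5 cos X₄ + N(0, R)` with R = 0.1; genes 5–10 are
  `b + W_mat ε_g` with `W_mat[i,j] = exp(−d_ij/W)` over coordinate
  distances, W = 0.6, one standard-normal n-vector per gene, b = 1.
  The matrix-times-vector reading of the smoothing is the only one
  that produces spatial clustering. The toy values are continuous and
  can be negative; they enter the pipeline at the log-normalized stage
  (z-scoring only). Note the fields are functions of the *noisy*
  coordinates, so they carry real positional signal; heavy overfitting
  can siphon sensitivity onto them, which is visible in the SOG
  margins if regularization is removed.
* **Coarse-graining**: uniform grid from the bounding-box minimum
  corner, spot radius = spacing/4, spot expression = sum over cells
  within the radius, empty spots dropped. Checked exactly against a
  brute-force membership scan.
* **Gene-wise noise**: `X' = max(X + N(0, σ·Var(X_j)), 0)` with
  population variance (ddof = 0); σ = 0 returns the input unchanged.
* **Laminar fixture**: 5 horizontal bands in the unit square, 200
  cells each; counts are Poisson with a lognormal(0, 0.2) cell-size
  factor; baseline rate 0.4 per gene (≈60% zeros, the sparsity regime
  of droplet/Visium data — and a regime where a zero count, the
  knockout value, is an ordinary observation rather than an outlier);
  each layer elevates a 6-gene marker block by e^strength; the
  remaining genes are morphogen-like gradients
  `rate ∝ exp(strength · ± (t − ½))` along x and y, without which the
  within-layer x position would not be encoded in expression at all
  and no method could place cells along it. A query population is
  drawn from the same per-layer distributions with configurable layer
  proportions to create genuine covariate shift. The fixture emulates
  laminar structure, sparsity and composition shift; it does not
  emulate batch effects, doublets, ambient RNA, or platform-specific
  noise, so passing tests bound what the pipeline can do under clean
  shift, not under every real-data pathology.

## Problem sizes and determinism

Test-suite and acceptance runs use the sizes above (toy n = 500,
laminar 5 × 200 + matched query, KLIEP n = 1000); a full pipeline fit
takes a few seconds on one CPU and the entire acceptance script about
half a minute. All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; repeated runs are bit-identical.

## Known limitations

* The co-embedding is a linear basis; strongly nonlinear batch
  structure between query and reference is only partially absorbed by
  the density-ratio weighting.
* KLIEP's Gaussian bases undershoot ratios in far tails (above).
* The knockout perturbs inputs outside the training manifold when a
  gene is never near zero in the data; interpret damage curves for
  such genes with care.
* Accuracy's permutation null assumes exchangeable cells; heavily
  clustered ground truth makes the null easier and accuracy
  correspondingly more generous.
* The polar transform assumes a roughly annular geometry with a
  sensible center; it is not a general conformal flattening.
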