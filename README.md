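# scplacer

Place dissociated single cells back into tissue space.

Single-cell RNA sequencing (scRNA-seq) measures whole transcriptomes but
destroys spatial context; spatial transcriptomics (ST) keeps coordinates
but with fewer cells, lower depth, or multi-cell spots. `scplacer` is a
transfer-learning toolkit for people who have both: it learns a mapping
from expression to 2-D tissue coordinates on one or more ST reference
slices and applies it to scRNA-seq cells, correcting for the different
cell-type compositions of the two assays. On top of the fitted mapping
it ranks **spatial-organizing genes** (SOGs), runs **in-silico
knockouts**, and projects RNA velocity into tissue coordinates
(**SpaRNA velocity**).

## The model

Write `x ∈ R^H` for preprocessed expression on the common highly
variable genes, `z = h(x)` for a reference-fitted co-embedding, and
`y ∈ R^2` for tissue coordinates. The placement map is `f = g ∘ h`,
where the regressor `g` is trained on the reference spots
`(z_st_j, y_st_j)` by minimizing the importance-weighted loss

    argmin_g  (1/m) Σ_j w_j ‖g(z_st_j) − y_st_j‖² + Ω(g),

with `w_j = ŵ(z_st_j)` estimating the density ratio
`w(z) = p_sc(z) / p_st(z)`. The weights re-balance the reference so the
loss approximates an expectation under the *query* distribution — the
covariate-shift correction that makes the transfer valid when the two
populations have different compositions. The ratio is fitted by KLIEP:

    ŵ(z) = Σ_i a_i exp(−‖z − c_i‖² / 2σ_b²),   a_i ≥ 0,
    max_a (1/M) Σ_j ln ŵ(z_sc_j)   s.t.  (1/m) Σ_j ŵ(z_st_j) = 1.

Downstream quantities:

* **SOG index** — `I_g = E[ ½ (|∂y₁/∂x_g| + |∂y₂/∂x_g|) ]`, the mean
  absolute Jacobian of `f` with respect to gene `g`, averaged over
  cells. Genes with top `I_g` drive the reconstructed organization;
  this is distinct from spatially *variable* genes (high Moran's I).
* **In-silico knockout** — a gene's input is set to the value a zero
  raw count maps to under the stored preprocessing, and positions are
  re-predicted with the unchanged model.
* **SpaRNA velocity** — `v_st = f(x + v_RNA) − f(x)`, the tissue-space
  displacement induced by a gene-space RNA-velocity step (velocities
  come from external tools and are consumed as input).

The regressor is a small dense network (default `K → 256 → 64 → 2`,
tanh, dropout, Adam, early stopping) with analytic input-Jacobians, so
the SOG index is exact rather than approximated.

## Worked example

The 10-gene simulated tissue separates the two gene notions: genes 1–4
determine the coordinates (`y₁ = 2 sin X₁ + 1.5 X₂² + ε`,
`y₂ = −e^{−X₃} + 2.5 cos X₄ + ε`), while genes 5–10 are spatially
smoothed noise with *higher* spatial autocorrelation but no causal
role. Train the mapper with the tissue as its own reference and score
both ways (`python examples/01_toy_sog_ranking.py`):

```
gene     Moran I   SOG index                  role
g01        0.203       0.545     determines coords
g02        0.848       1.561     determines coords
g03        0.090       0.405     determines coords
g04        0.858       0.935     determines coords
g05        0.938       0.079        smoothed field
...
top-4 by SOG index: g02, g04, g01, g03
```

Every smoothed gene beats every organizing gene on Moran's I (0.94+ vs
≤ 0.86), yet the SOG index — sensitivity of the *fitted mapping* —
puts the four causal genes on top with a wide margin (0.40 vs 0.09).

The other examples cover layered-tissue placement with accuracy and
per-layer indicators (`02`), density-ratio estimation under a known
1-D shift and under a composition-shifted query (`03`), and knockout
curves plus velocity projection (`04`). On the laminar fixture the
pipeline reaches accuracy 0.83 against a permutation-calibrated scale
(1 = exact, 0 = random guess), and silencing 0/5/10/20 top-ranked genes
degrades reconstruction MSE monotonically (0.051 → 0.063 → 0.082 →
0.106).

## Command line

A thin CLI wraps the same pipeline for shell use:

```bash
scplacer simulate --layers --seed 0 --out data/
scplacer train --st-expr data/st_expression.csv --st-coords data/st_coords.csv \
               --sc-expr data/sc_expression.csv --seed 0 --out run/
scplacer sog --model run/ --expr data/sc_expression.csv --out run/
scplacer evaluate --pred run/predictions.csv --truth data/sc_truth_coords.csv --out run/
```

`train` also accepts a sectioned YAML config (`--config run.yaml`) with
every preprocessing, co-embedding, KLIEP and network setting; each run
writes a `run_log.json` with the seed, the effective configuration and
a summary of the fitted density-ratio weights.

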