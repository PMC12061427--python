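"""In-silico knockouts and velocity projection on a fitted mapping.

Trains the laminar pipeline, then (a) silences increasing numbers of
top-ranked genes — each knocked gene's input is set to the value a zero
raw count takes after preprocessing — and tracks how reconstruction
degrades, and (b) projects a gene-space velocity step into tissue
coordinates (the displacement f(x + v) - f(x)).
"""

import numpy as np

from scplacer import (
    knockout_predict,
    run_pipeline,
    simulate_layers,
    sog_index,
    spa_rna_velocity,
)

data = simulate_layers(n_layers=5, cells_per_layer=200, marker_strength=2.0, seed=0)
res = run_pipeline([data.st], data.sc_expr, seed=0)
sog = sog_index(res.mapper, res.sc_scaled, prep=res.prep_sc)

print("knockout of top-ranked genes (MSE vs true positions):")
for size in (0, 5, 10, 20):
    ko = knockout_predict(res.mapper, res.prep_sc, res.sc_scaled, sog.top(size))
    mse = float(np.mean(np.sum((ko - data.sc_coords) ** 2, axis=1)))
    print(f"  {size:>2} genes silenced -> MSE {mse:.4f}")

# velocity: a step along the expression gradient that encodes the x axis
X = res.sc_scaled.values
x = data.sc_coords[:, 0]
slope = np.array([np.polyfit(x, X[:, j], 1)[0] for j in range(X.shape[1])])
v = 0.1 * np.tile(slope, (X.shape[0], 1))
field = spa_rna_velocity(res.mapper, res.sc_scaled, v)
norms = np.linalg.norm(field.v_st, axis=1).clip(1e-12)
print(f"\nvelocity projection: mean cosine with +x axis "
      f"{np.mean(field.v_st[:, 0] / norms):.3f}")
print(
    "\nRising knockout MSE shows the mapping leans on its top-ranked genes;"
    "\nthe velocity cosine near 1 shows a transcriptional step along the"
    "\nx-encoding gradient moves cells rightward in tissue space."
)
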