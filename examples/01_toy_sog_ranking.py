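"""Separate spatial-ORGANIZING genes from spatially-VARIABLE genes.

Generates the 10-gene toy tissue (genes 1-4 determine the coordinates,
genes 5-10 are spatially smoothed noise), trains the coordinate mapper
with the tissue as its own reference, and prints two rankings: Moran's I
(spatial autocorrelation, the classic SVG score) and the gradient-based
SOG index. The smoothed genes win on Moran's I, yet the mapper's
Jacobian correctly puts the four coordinate-determining genes on top.
"""

import numpy as np

from scplacer import (
    MapperConfig,
    morans_i,
    run_pipeline,
    simulate_toy,
    sog_index,
)

toy = simulate_toy(n=500, R=0.1, W=0.6, seed=1)
res = run_pipeline(
    [toy.slice()], toy.expression(), do_lognorm=False, seed=1,
    config=MapperConfig(seed=1),
)
sog = sog_index(res.mapper, res.sc_scaled, prep=res.prep_sc)

print(f"{'gene':<6}{'Moran I':>10}{'SOG index':>12}{'role':>22}")
for g, gene in enumerate(toy.gene_ids):
    role = "determines coords" if g in toy.sog_truth else "smoothed field"
    mi = morans_i(toy.X[:, g], toy.coords, k_neighbors=6)
    print(f"{gene:<6}{mi:>10.3f}{sog.I[g]:>12.3f}{role:>22}")

print("\ntop-4 by SOG index:", ", ".join(sog.top(4)))
print("expected          :", ", ".join(toy.gene_ids[i] for i in toy.sog_truth))
print(
    "\nA high Moran's I marks a gene as spatially patterned; a high SOG index"
    "\nmarks a gene the position mapping actually depends on. The two"
    "\nrankings disagree by construction here, and the SOG index recovers"
    "\nthe causal genes."
)
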