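"""Synthetic data generators: coarse spots, noise, the 10-gene toy, layers.

These generators define the study conditions the rest of the package is
exercised under:

* ``coarse_grain`` degrades single-cell-resolution spatial data to
  spot resolution (Visium-like): a uniform grid is laid over the
  tissue, each grid intersection becomes a spot of radius spacing/4,
  a spot's expression is the sum over the cells inside its radius, and
  spots with zero total expression are dropped.
* ``add_noise`` injects gene-wise Gaussian noise N(0, sigma * Var(X_j))
  clipped at zero, emulating measurement noise proportional to each
  gene's intrinsic variability.
* ``simulate_toy`` builds the 10-gene dataset that separates
  spatial-ORGANIZING from spatially-VARIABLE genes: genes 1-4 ~ U(0,2)
  determine the coordinates through

      y1 = 2 sin(X1) + 1.5 X2^2 + N(0, R)
      y2 = -exp(-X3) + 2.5 cos(X4) + N(0, R)

  (R = 0.1 by default), while genes 5-10 are spatially smoothed noise,
  X_g = b + W_mat @ N(0, I) with W_mat[i, j] = exp(-d_ij / W) over
  coordinate distances (W = 0.6), giving them high spatial
  autocorrelation but no causal role in the coordinates.
* ``simulate_layers`` is a laminar-cortex-like fixture: horizontal
  bands in the unit square with layer-specific marker genes, plus a
  matched dissociated query population whose layer proportions can be
  shifted to exercise the covariate-shift correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial.distance import cdist

from .io_prep import GeneMatrix, SpatialSlice

__all__ = [
    "ToyDataset",
    "LayeredDataset",
    "coarse_grain",
    "add_noise",
    "simulate_toy",
    "simulate_layers",
]


@dataclass
class ToyDataset:
    """The 10-gene toy instance with known ground truth.

    ``sog_truth`` holds the coordinate-determining genes (columns 0-3),
    ``svg_truth`` the spatially autocorrelated ones (columns 4-9).
    """

    X: np.ndarray
    coords: np.ndarray
    params: dict
    sog_truth: list[int]
    svg_truth: list[int]
    gene_ids: list[str]

    def expression(self) -> GeneMatrix:
        """As a GeneMatrix; the toy values can be negative, so the
        matrix enters the pipeline at the lognorm stage (z-score next)."""
        cells = [f"cell{i}" for i in range(self.X.shape[0])]
        return GeneMatrix(self.X, cells, list(self.gene_ids), "lognorm")

    def slice(self) -> SpatialSlice:
        return SpatialSlice(self.expression(), self.coords, slice_id="toy")


@dataclass
class LayeredDataset:
    """Laminar fixture: spatial reference + matched dissociated query."""

    st: SpatialSlice
    sc_expr: GeneMatrix
    sc_coords: np.ndarray  # ground truth, withheld from the pipeline
    sc_labels: list[str]


def coarse_grain(slice_: SpatialSlice, spacing: float) -> SpatialSlice:
    """Aggregate single cells into grid spots of radius spacing/4.

    Grid lines start at the bounding-box minimum corner; a cell is
    captured by a spot if its distance to the spot center is at most
    the radius. Spots capturing no expression are dropped.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if slice_.expr.stage != "raw":
        raise ValueError("coarse_grain expects raw-stage expression")
    coords = slice_.coords
    lo = coords.min(axis=0)
    hi = coords.max(axis=0)
    if np.any(hi - lo < 0):
        raise ValueError("degenerate bounding box")
    nx = int(np.floor((hi[0] - lo[0]) / spacing)) + 1
    ny = int(np.floor((hi[1] - lo[1]) / spacing)) + 1
    if nx * ny <= 1 and spacing > max(hi - lo):
        raise ValueError("spacing larger than the tissue bounding box")
    gx = lo[0] + spacing * np.arange(nx)
    gy = lo[1] + spacing * np.arange(ny)
    centers = np.array([(x, y) for x in gx for y in gy])
    radius = spacing / 4.0
    d = cdist(centers, coords)
    member = d <= radius
    expr = member.astype(float) @ slice_.expr.values
    keep = expr.sum(axis=1) > 0
    spot_ids = [f"spot{i}" for i in range(int(keep.sum()))]
    gm = GeneMatrix(expr[keep], spot_ids, list(slice_.expr.gene_ids), "raw")
    return SpatialSlice(
        gm, centers[keep], slice_id=f"{slice_.slice_id}_coarse"
    )


def add_noise(gm: GeneMatrix, sigma: float, seed: int = 0) -> GeneMatrix:
    """Gene-wise Gaussian noise: X'_ij = max(X_ij + N(0, sigma*Var(X_j)), 0).

    Variance is the population variance across cells (ddof=0); constant
    genes are untouched at any sigma, and sigma=0 returns the input
    values unchanged.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return GeneMatrix(
            gm.values.copy(), list(gm.cell_ids), list(gm.gene_ids), gm.stage
        )
    rng = np.random.default_rng(seed)
    var = gm.values.var(axis=0)
    noise = rng.normal(0.0, 1.0, size=gm.values.shape) * np.sqrt(sigma * var)
    vals = np.maximum(gm.values + noise, 0.0)
    return GeneMatrix(vals, list(gm.cell_ids), list(gm.gene_ids), gm.stage)


def simulate_toy(
    n: int = 500,
    R: float = 0.1,
    W: float = 0.6,
    b: float = 1.0,
    seed: int = 0,
) -> ToyDataset:
    """Generate the 10-gene toy dataset (4 organizing + 6 smoothed genes)."""
    if n < 10:
        raise ValueError("n must be >= 10")
    if R < 0:
        raise ValueError("R must be non-negative")
    if W <= 0:
        raise ValueError("W must be positive")
    rng = np.random.default_rng(seed)
    X = np.zeros((n, 10))
    X[:, :4] = rng.uniform(0.0, 2.0, size=(n, 4))
    noise_sd = np.sqrt(R)
    y1 = 2.0 * np.sin(X[:, 0]) + 1.5 * X[:, 1] ** 2 + rng.normal(0, noise_sd, n)
    y2 = -np.exp(-X[:, 2]) + 2.5 * np.cos(X[:, 3]) + rng.normal(0, noise_sd, n)
    coords = np.column_stack([y1, y2])
    d = cdist(coords, coords)
    w_mat = np.exp(-d / W)
    for g in range(4, 10):
        X[:, g] = b + w_mat @ rng.normal(0.0, 1.0, n)
    return ToyDataset(
        X=X,
        coords=coords,
        params={"n": n, "R": R, "W": W, "b": b, "seed": seed},
        sog_truth=[0, 1, 2, 3],
        svg_truth=[4, 5, 6, 7, 8, 9],
        gene_ids=[f"g{i + 1:02d}" for i in range(10)],
    )


def simulate_layers(
    n_layers: int = 5,
    cells_per_layer: int = 200,
    n_genes: int = 60,
    marker_strength: float = 2.0,
    sc_cells_per_layer: Optional[list[int]] = None,
    seed: int = 0,
) -> LayeredDataset:
    """Laminar tissue fixture with layer-specific marker genes.

    Horizontal bands tile the unit square; each layer elevates its own
    block of markers by ``marker_strength`` on the log scale over a
    baseline Poisson rate. The query ("scRNA-seq") population is drawn
    from the same per-layer distributions, optionally with shifted
    layer proportions to create covariate shift against the reference.
    """
    if n_layers < 2:
        raise ValueError("need at least 2 layers")
    rng = np.random.default_rng(seed)
    markers_per_layer = max(1, n_genes // (2 * n_layers))
    n_marker = markers_per_layer * n_layers
    base_rate = 0.4
    # remaining genes: smooth morphogen-like gradients along x and y with
    # alternating direction, same effect scale as the layer markers — without
    # them the within-layer x position would be unidentifiable from expression
    n_grad = n_genes - n_marker
    grad_axis = np.tile([0, 1], (n_grad + 1) // 2)[:n_grad]
    grad_sign = np.tile([1.0, 1.0, -1.0, -1.0], (n_grad + 3) // 4)[:n_grad]

    def rates(layer: int, pos: np.ndarray) -> np.ndarray:
        out = np.full((pos.shape[0], n_genes), base_rate)
        start = layer * markers_per_layer
        out[:, start : start + markers_per_layer] *= np.exp(marker_strength)
        t = pos[:, grad_axis] - 0.5
        out[:, n_marker:] *= np.exp(marker_strength * grad_sign * t)
        return out

    def draw(layer: int, pos: np.ndarray) -> np.ndarray:
        lib = rng.lognormal(0.0, 0.2, size=pos.shape[0])  # cell-size variation
        return rng.poisson(lib[:, None] * rates(layer, pos)).astype(float)

    gene_ids = [f"gene{i:03d}" for i in range(n_genes)]
    band = 1.0 / n_layers

    def draw_population(per_layer: list[int], prefix: str):
        counts, coords, labels = [], [], []
        for layer, n_cells in enumerate(per_layer):
            if n_cells == 0:
                continue
            x = rng.uniform(0.0, 1.0, n_cells)
            y = rng.uniform(layer * band, (layer + 1) * band, n_cells)
            pos = np.column_stack([x, y])
            counts.append(draw(layer, pos))
            coords.append(pos)
            labels += [f"L{layer + 1}"] * n_cells
        gm = GeneMatrix(
            np.vstack(counts),
            [f"{prefix}{i}" for i in range(sum(per_layer))],
            gene_ids,
            "raw",
        )
        return gm, np.vstack(coords), labels

    st_expr, st_coords, st_labels = draw_population(
        [cells_per_layer] * n_layers, "spot"
    )
    st = SpatialSlice(st_expr, st_coords, labels=st_labels, slice_id="laminar")

    if sc_cells_per_layer is None:
        sc_cells_per_layer = [cells_per_layer] * n_layers
    if len(sc_cells_per_layer) != n_layers:
        raise ValueError("sc_cells_per_layer length must equal n_layers")
    sc_expr, sc_coords, sc_labels = draw_population(sc_cells_per_layer, "cell")
    return LayeredDataset(
        st=st, sc_expr=sc_expr, sc_coords=sc_coords, sc_labels=sc_labels
    )
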