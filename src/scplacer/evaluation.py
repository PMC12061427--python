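"""Reconstruction-quality metrics and spatial autocorrelation.

``mse_accuracy`` anchors the scale of a reconstruction error: accuracy
is 1 for an exact reconstruction and ~0 for a random guess, using a
seeded permutation null for the random-guess baseline.

``layer_indicators`` scores a labeled (layered) reconstruction with
four complementary indicators, each in [0, 1] and equal to 1 at perfect
reconstruction:

* S_C — intra-layer similarity: fraction of each cell's k nearest
  predicted neighbors sharing its label;
* rho_C — normalized density overlap: 1 - total-variation distance
  between the binned 2-D densities of predicted and true positions per
  layer;
* A_C — aggregative volume: min/max ratio of predicted vs true
  convex-hull areas per layer;
* P_C — aggregative perimeter: same for hull perimeters.

``morans_i`` is global Moran's I over a row-normalized k-nearest-
neighbor spatial graph, the standard spatial-autocorrelation statistic
used to call spatially variable genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from sklearn.neighbors import NearestNeighbors

__all__ = ["EvalReport", "mse_accuracy", "layer_indicators", "morans_i"]


@dataclass
class EvalReport:
    """Aggregate reconstruction metrics (accuracy reported as a fraction)."""

    mse: float
    accuracy: float
    per_layer: Optional[pd.DataFrame] = None

    @property
    def mean_indicators(self) -> Optional[pd.Series]:
        if self.per_layer is None:
            return None
        return self.per_layer[["S_C", "rho_C", "A_C", "P_C"]].mean()

    def to_json_dict(self) -> dict:
        out = {"mse": self.mse, "accuracy": self.accuracy}
        if self.per_layer is not None:
            out["per_layer"] = self.per_layer.to_dict(orient="records")
            out["mean_indicators"] = self.mean_indicators.to_dict()
        return out


def mse_accuracy(
    pred: np.ndarray,
    truth: np.ndarray,
    n_null: int = 200,
    seed: int = 0,
) -> tuple[float, float]:
    """Mean squared error plus a permutation-calibrated accuracy.

    accuracy = max(0, 1 - mse / mse_null), with mse_null the mean MSE
    over ``n_null`` seeded random permutations of the true positions;
    an exact reconstruction scores 1, a random guess scores ~0.
    """
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape or pred.ndim != 2:
        raise ValueError("pred and truth must be matched m x 2 arrays")
    m = pred.shape[0]
    if m < 2:
        raise ValueError("need at least 2 points")
    if n_null < 100:
        raise ValueError("n_null must be >= 100")
    mse = float(np.mean(np.sum((pred - truth) ** 2, axis=1)))
    if mse == 0.0:
        return 0.0, 1.0
    rng = np.random.default_rng(seed)
    null = np.empty(n_null)
    for i in range(n_null):
        perm = rng.permutation(m)
        null[i] = np.mean(np.sum((pred - truth[perm]) ** 2, axis=1))
    mse_null = float(null.mean())
    accuracy = max(0.0, 1.0 - mse / mse_null) if mse_null > 0 else 0.0
    return mse, accuracy


def _hull_measures(points: np.ndarray) -> tuple[float, float]:
    """Convex-hull (area, perimeter); zero for degenerate point sets."""
    try:
        hull = ConvexHull(points)
    except QhullError:
        return 0.0, 0.0
    # in 2-D scipy reports area -> perimeter, volume -> area
    return float(hull.volume), float(hull.area)


def layer_indicators(
    pred: np.ndarray,
    truth: np.ndarray,
    labels: Sequence[str],
    k: int = 30,
    bins: int = 20,
) -> pd.DataFrame:
    """Per-layer S_C, rho_C, A_C, P_C table (+ a final mean row).

    Layers with fewer than 3 cells have degenerate hulls; they are
    reported as NaN and excluded from the mean row.
    """
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    labels = np.asarray([str(x) for x in labels])
    m = pred.shape[0]
    if pred.shape != truth.shape:
        raise ValueError("pred/truth shape mismatch")
    uniq = sorted(set(labels))
    if len(uniq) < 2:
        raise ValueError("need at least 2 distinct labels")
    if k >= m:
        raise ValueError("k must be smaller than the cell count")

    nn = NearestNeighbors(n_neighbors=k + 1).fit(pred)
    _, idx = nn.kneighbors(pred)
    neighbor_labels = labels[idx[:, 1:]]  # drop self
    same = neighbor_labels == labels[:, None]
    s_per_cell = same.mean(axis=1)

    # common histogram frame spanning both point sets
    allpts = np.vstack([pred, truth])
    lo = allpts.min(axis=0)
    hi = allpts.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    xedges = np.linspace(lo[0], lo[0] + span[0], bins + 1)
    yedges = np.linspace(lo[1], lo[1] + span[1], bins + 1)

    rows = []
    for lab in uniq:
        sel = labels == lab
        n_lab = int(sel.sum())
        S = float(s_per_cell[sel].mean())
        hp, _, _ = np.histogram2d(
            pred[sel, 0], pred[sel, 1], bins=[xedges, yedges]
        )
        ht, _, _ = np.histogram2d(
            truth[sel, 0], truth[sel, 1], bins=[xedges, yedges]
        )
        hp = hp / hp.sum() if hp.sum() else hp
        ht = ht / ht.sum() if ht.sum() else ht
        rho = float(1.0 - 0.5 * np.abs(hp - ht).sum())
        if n_lab < 3:
            A = P = float("nan")
        else:
            area_p, per_p = _hull_measures(pred[sel])
            area_t, per_t = _hull_measures(truth[sel])
            A = (
                min(area_p, area_t) / max(area_p, area_t)
                if max(area_p, area_t) > 0
                else 0.0
            )
            P = (
                min(per_p, per_t) / max(per_p, per_t)
                if max(per_p, per_t) > 0
                else 0.0
            )
        rows.append(
            {"layer": lab, "n": n_lab, "S_C": S, "rho_C": rho, "A_C": A, "P_C": P}
        )
    df = pd.DataFrame(rows)
    mean_row = {
        "layer": "mean",
        "n": int(df["n"].sum()),
        **{c: float(df[c].mean(skipna=True)) for c in ("S_C", "rho_C", "A_C", "P_C")},
    }
    return pd.concat([df, pd.DataFrame([mean_row])], ignore_index=True)


def morans_i(
    values: np.ndarray,
    coords: np.ndarray,
    k_neighbors: int = 6,
) -> float:
    """Global Moran's I with row-normalized k-nearest-neighbor weights.

    I = (m / sum W) * sum_ij w_ij (v_i - vbar)(v_j - vbar) / sum_i (v_i - vbar)^2
    """
    values = np.asarray(values, dtype=float)
    coords = np.asarray(coords, dtype=float)
    m = values.shape[0]
    if m < 10:
        raise ValueError("need at least 10 samples")
    if coords.shape[0] != m:
        raise ValueError("values/coords length mismatch")
    dev = values - values.mean()
    denom = float(np.sum(dev**2))
    if denom == 0:
        raise ValueError("Moran's I undefined for constant values")
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(coords)
    _, idx = nn.kneighbors(coords)
    idx = idx[:, 1:]  # drop self
    w = 1.0 / k_neighbors  # row-normalized weights; sum W = m
    num = float(np.sum(dev[:, None] * dev[idx]) * w)
    return (m / float(m)) * num / denom
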