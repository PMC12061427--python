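"""Importance-weighted neural regression from latent expression to space.

The mapping f = g ∘ h is learned by minimizing the density-ratio
weighted loss over the reference spots,

    argmin_g (1/m) sum_j w_j * |g(z_st_j) - y_st_j|^2 + Omega(g),

where w_j = w_hat(z_st_j) corrects the covariate shift between the
scRNA-seq query and the spatial reference, and Omega is L2 weight
decay. With several reference slices each slice additionally carries a
weight proportional to its mean density ratio (how well its composition
matches the query), and the per-slice weighted losses are combined;
with one slice this reduces exactly to the expression above.

Coordinates are min-max scaled to the unit square per slice before
training so heterologous physical frames are commensurable; predictions
are returned in the frame of a chosen slice (the first by default).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .coembed import CoembedModel, Embedding, embed
from .density_ratio import (
    DensityRatioModel,
    fit_kliep,
    median_bandwidth,
    ratio,
    select_bandwidth,
)
from .io_prep import GeneMatrix, SpatialSlice
from .nn import MLP

__all__ = [
    "MapperConfig",
    "MapperModel",
    "estimate_slice_weights",
    "fit_mapper",
    "predict_locations",
]


@dataclass
class MapperConfig:
    """Training hyper-parameters for the coordinate regressor."""

    hidden: tuple[int, ...] = (256, 64)
    activation: str = "tanh"
    dropout: float = 0.2
    lr: float = 1e-3
    weight_decay: float = 1e-4
    max_epochs: int = 500
    patience: int = 20
    val_fraction: float = 0.1
    batch_size: int = 64
    clip_percentile: float = 99.5  # density-ratio clipping before training
    seed: int = 0


@dataclass
class MapperModel:
    """Fitted regressor g plus the co-embedding h and coordinate frame."""

    coembed: CoembedModel
    net: MLP
    config: MapperConfig
    coord_scaler: np.ndarray  # 2 x 2: row 0 = per-axis min, row 1 = per-axis range
    slice_weights: np.ndarray
    train_log: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coord_scaler = np.asarray(self.coord_scaler, dtype=float)
        if np.any(self.coord_scaler[1] <= 0):
            raise ValueError("coordinate scaler ranges must be positive")
        if self.train_log and self.train_log[-1] > self.train_log[0]:
            raise ValueError("training loss increased overall")

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.coembed.save(directory)
        params = self.net.get_params()
        np.savez(directory / "net_params.npz", **params)
        meta = {
            "dims": list(self.net.dims),
            "activation": self.net.activation,
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.config.__dict__.items()
            },
            "coord_scaler": self.coord_scaler.tolist(),
            "slice_weights": self.slice_weights.tolist(),
            "train_log": self.train_log,
        }
        (directory / "mapper.json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, directory: str | Path) -> "MapperModel":
        directory = Path(directory)
        meta = json.loads((directory / "mapper.json").read_text())
        cfg_d = dict(meta["config"])
        cfg_d["hidden"] = tuple(cfg_d["hidden"])
        config = MapperConfig(**cfg_d)
        net = MLP(
            meta["dims"],
            np.random.default_rng(0),
            activation=meta.get("activation", "tanh"),
        )
        with np.load(directory / "net_params.npz") as data:
            net.set_params({k: data[k] for k in data.files})
        return cls(
            coembed=CoembedModel.load(directory),
            net=net,
            config=config,
            coord_scaler=np.asarray(meta["coord_scaler"]),
            slice_weights=np.asarray(meta["slice_weights"]),
            train_log=list(meta["train_log"]),
        )


def estimate_slice_weights(
    z_sc: Embedding,
    slice_embeddings: Sequence[Embedding],
    k: int = 100,
    bandwidth: float | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, DensityRatioModel]:
    """Per-slice weights from a pooled-reference density-ratio fit.

    One KLIEP model is fitted with the scRNA embedding as numerator and
    the pooled spots of all slices as denominator; each slice's weight
    is proportional to the mean ratio over its own spots (how much of
    the query's probability mass that slice covers), normalized to sum
    to one. A single slice gets weight 1 by the pooled constraint.

    When ``bandwidth`` is None it is chosen by likelihood
    cross-validation over a grid of multiples of the median pairwise
    distance — in higher-dimensional embeddings the raw median
    heuristic oversmooths and washes the composition shift out of the
    fitted ratio.
    """
    if not slice_embeddings:
        raise ValueError("need at least one slice")
    pooled = np.vstack([e.z for e in slice_embeddings])
    if bandwidth is None:
        med = median_bandwidth(z_sc.z, seed=seed)
        candidates = [med * f for f in (0.1, 0.25, 0.5, 1.0, 2.0)]
        bandwidth = select_bandwidth(
            z_sc.z, pooled, candidates, folds=3, k=k, seed=seed
        )
    try:
        model = fit_kliep(z_sc, pooled, k=k, bandwidth=bandwidth, seed=seed)
    except RuntimeError as exc:
        raise RuntimeError(f"pooled KLIEP fit failed: {exc}") from exc
    weights = []
    for e in slice_embeddings:
        w = ratio(model, e.z)
        if not np.all(np.isfinite(w)):
            raise RuntimeError(f"KLIEP weights non-finite for slice {e.source!r}")
        weights.append(float(np.mean(w)))
    weights = np.asarray(weights)
    if weights.sum() <= 0:
        raise RuntimeError("all slice weights are zero")
    return weights / weights.sum(), model


def _scale_coords(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lo = coords.min(axis=0)
    rng_ = coords.max(axis=0) - lo
    rng_ = np.where(rng_ > 0, rng_, 1.0)
    scaler = np.vstack([lo, rng_])
    return (coords - lo) / rng_, scaler


def fit_mapper(
    slices: Sequence[SpatialSlice],
    coembed_model: CoembedModel,
    ratios: Optional[Sequence[np.ndarray]] = None,
    slice_weights: Optional[np.ndarray] = None,
    config: Optional[MapperConfig] = None,
) -> MapperModel:
    """Train the regressor g on density-ratio-weighted reference spots.

    ``ratios`` holds one non-negative weight vector per slice (uniform
    when omitted); weights are clipped at ``config.clip_percentile`` to
    bound loss variance and normalized to mean 1 within each slice so
    that the weighting changes emphasis, not the loss scale. Training is
    fully reproducible given ``config.seed``.
    """
    if not slices:
        raise ValueError("no reference slices")
    config = config or MapperConfig()
    rng = np.random.default_rng(config.seed)

    Zs, Ys, Ws, scalers = [], [], [], []
    for idx, sl in enumerate(slices):
        if sl.n_spots == 0:
            raise ValueError(f"slice {sl.slice_id!r} is empty")
        z = embed(coembed_model, sl.expr, source="st").z
        y, scaler = _scale_coords(sl.coords)
        if ratios is None:
            w = np.ones(sl.n_spots)
        else:
            w = np.asarray(ratios[idx], dtype=float)
            if w.shape != (sl.n_spots,):
                raise ValueError(f"ratio vector shape mismatch for slice {idx}")
            if np.any(w < 0):
                raise ValueError("negative spot weights")
            if config.clip_percentile < 100:
                cap = np.percentile(w, config.clip_percentile)
                if cap > 0:
                    w = np.minimum(w, cap)
        if w.mean() > 0:
            w = w / w.mean()
        Zs.append(z)
        Ys.append(y)
        Ws.append(w)
        scalers.append(scaler)

    if slice_weights is None:
        slice_weights = np.full(len(slices), 1.0 / len(slices))
    else:
        slice_weights = np.asarray(slice_weights, dtype=float)
        if np.any(slice_weights < 0) or slice_weights.sum() <= 0:
            raise ValueError("invalid slice weights")
        slice_weights = slice_weights / slice_weights.sum()

    # combined per-spot weights: slice weight spreads over the slice spots
    Z = np.vstack(Zs)
    Y = np.vstack(Ys)
    W = np.concatenate(
        [sw * len(slices) * w for sw, w in zip(slice_weights, Ws)]
    )

    n = Z.shape[0]
    n_val = max(1, int(round(config.val_fraction * n))) if n >= 10 else 0
    perm = rng.permutation(n)
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    Zt, Yt, Wt = Z[train_idx], Y[train_idx], W[train_idx]
    Zv, Yv, Wv = Z[val_idx], Y[val_idx], W[val_idx]
    if n_val and Wv.sum() == 0:
        # validation carries no loss mass (degenerate weighting): early
        # stopping would compare zeros forever and freeze the initial net
        n_val = 0
        Zt, Yt, Wt = Z, Y, W

    net = MLP((Z.shape[1], *config.hidden, 2), rng, activation=config.activation)

    def eval_loss(Xe, Ye, We) -> float:
        pred = net.predict(Xe)
        return float(np.mean(We * np.sum((pred - Ye) ** 2, axis=1)))

    best_params = net.get_params()
    best_val = eval_loss(Zv, Yv, Wv) if n_val else np.inf
    train_log: list[float] = []
    stall = 0
    for _ in range(config.max_epochs):
        order = rng.permutation(Zt.shape[0])
        for start in range(0, Zt.shape[0], config.batch_size):
            sel = order[start : start + config.batch_size]
            loss, gW, gb = net.loss_and_grads(
                Zt[sel], Yt[sel], Wt[sel], dropout=config.dropout, rng=rng
            )
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss (epoch {len(train_log)})"
                )
            net.adam_step(gW, gb, lr=config.lr, weight_decay=config.weight_decay)
        train_log.append(eval_loss(Zt, Yt, Wt))
        if n_val:
            val = eval_loss(Zv, Yv, Wv)
            if val < best_val - 1e-9:
                best_val = val
                best_params = net.get_params()
                stall = 0
            else:
                stall += 1
                if stall >= config.patience:
                    break
    if n_val:
        net.set_params(best_params)
    train_log.append(eval_loss(Zt, Yt, Wt))

    return MapperModel(
        coembed=coembed_model,
        net=net,
        config=config,
        coord_scaler=scalers[0],
        slice_weights=slice_weights,
        train_log=train_log,
    )


def predict_locations(model: MapperModel, gm: GeneMatrix) -> np.ndarray:
    """Predict tissue coordinates y = g(h(x)) in the reference frame.

    Dropout is disabled at inference; the unit-square outputs are mapped
    back through the stored coordinate scaler.
    """
    if gm.stage != "scaled":
        raise ValueError(f"predict_locations expects stage=scaled, got {gm.stage}")
    z = embed(model.coembed, gm).z
    pred = model.net.predict(z)
    out = pred * model.coord_scaler[1] + model.coord_scaler[0]
    if not np.all(np.isfinite(out)):
        raise RuntimeError("non-finite predicted coordinates")
    return out
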