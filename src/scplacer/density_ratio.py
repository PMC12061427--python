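"""Density-ratio estimation by KLIEP for covariate shift correction.

The query (scRNA-seq) and reference (spatial) populations usually have
different cell-type compositions, so their latent densities differ:
p_sc(z) != p_st(z). The importance weight

    w(z) = p_sc(z) / p_st(z)

reweights reference spots so that a loss averaged over the reference
approximates the expectation under the query distribution. KLIEP
(Kullback-Leibler Importance Estimation Procedure) models the ratio as
a non-negative combination of Gaussian basis functions,

    w_hat(z) = sum_i a_i * phi_i(z),   phi_i(z) = exp(-|z - c_i|^2 / (2 sigma_b^2)),

and maximizes the numerator log-likelihood

    J = (1/M) sum_j ln w_hat(z_sc_j)

subject to a_i >= 0 and the normalization (1/m) sum_j w_hat(z_st_j) = 1,
which makes w_hat(z) p_st(z) a proper density. Optimization is projected
gradient ascent with backtracking, so the logged objective never
decreases.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .coembed import Embedding

__all__ = [
    "DensityRatioModel",
    "fit_kliep",
    "ratio",
    "select_bandwidth",
    "median_bandwidth",
]


@dataclass
class DensityRatioModel:
    """Fitted KLIEP model: basis centers, bandwidth, coefficients."""

    centers: np.ndarray  # k x K
    bandwidth: float
    a: np.ndarray  # k non-negative coefficients
    fit_log: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        if np.any(self.a < 0):
            raise ValueError("KLIEP coefficients must be non-negative")
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")

    @property
    def k(self) -> int:
        return self.centers.shape[0]

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        df = pd.DataFrame(
            self.centers, columns=[f"z{i + 1}" for i in range(self.centers.shape[1])]
        )
        df["a"] = self.a
        df.to_csv(directory / "kliep_basis.csv", index=False)
        (directory / "kliep.json").write_text(
            json.dumps({"bandwidth": self.bandwidth, "k": self.k})
        )

    @classmethod
    def load(cls, directory: str | Path) -> "DensityRatioModel":
        directory = Path(directory)
        meta = json.loads((directory / "kliep.json").read_text())
        df = pd.read_csv(directory / "kliep_basis.csv")
        a = df.pop("a").to_numpy(dtype=float)
        return cls(centers=df.to_numpy(dtype=float), bandwidth=meta["bandwidth"], a=a)


def _as_matrix(z) -> np.ndarray:
    if isinstance(z, Embedding):
        return z.z
    z = np.asarray(z, dtype=float)
    return z[:, None] if z.ndim == 1 else z


def _phi(z: np.ndarray, centers: np.ndarray, bandwidth: float) -> np.ndarray:
    """Gaussian basis design matrix, samples x centers (unnormalized)."""
    d2 = (
        np.sum(z**2, axis=1)[:, None]
        - 2.0 * z @ centers.T
        + np.sum(centers**2, axis=1)[None, :]
    )
    return np.exp(-np.maximum(d2, 0.0) / (2.0 * bandwidth**2))


def median_bandwidth(z: np.ndarray | Embedding, max_samples: int = 1000, seed: int = 0) -> float:
    """Median pairwise distance heuristic for the Gaussian basis width."""
    z = _as_matrix(z)
    if z.shape[0] > max_samples:
        rng = np.random.default_rng(seed)
        z = z[rng.choice(z.shape[0], max_samples, replace=False)]
    from scipy.spatial.distance import pdist

    d = pdist(z)
    med = float(np.median(d[d > 0])) if np.any(d > 0) else 1.0
    return med if med > 0 else 1.0


def _project(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a = np.maximum(a, 0.0)
    denom = float(b @ a)
    if denom <= 0:
        raise RuntimeError(
            "normalization constraint degenerate; increase the bandwidth"
        )
    return a / denom


def fit_kliep(
    z_sc: np.ndarray | Embedding,
    z_st: np.ndarray | Embedding,
    k: int = 100,
    bandwidth: float | None = None,
    max_iter: int = 2000,
    tol: float = 1e-6,
    seed: int = 0,
) -> DensityRatioModel:
    """Fit w_hat(z) = p_sc(z)/p_st(z) by KLIEP.

    Basis centers are ``k`` points subsampled (seeded) from the
    numerator (scRNA) embedding; ``bandwidth`` defaults to the median
    pairwise-distance heuristic. Ascent steps that would lower the
    objective are shrunk (backtracking), so ``fit_log`` is
    non-decreasing; convergence when the objective improves by < tol.
    """
    zn = _as_matrix(z_sc)
    zd = _as_matrix(z_st)
    if zn.shape[1] != zd.shape[1]:
        raise ValueError("embedding dimensions differ")
    M = zn.shape[0]
    if k > M:
        k = M
    rng = np.random.default_rng(seed)
    centers = zn[rng.choice(M, size=k, replace=False)]
    if bandwidth is None:
        bandwidth = median_bandwidth(zn, seed=seed)

    A = _phi(zn, centers, bandwidth)  # M x k
    b = _phi(zd, centers, bandwidth).mean(axis=0)  # k

    if np.any(A.sum(axis=1) == 0):
        raise RuntimeError(
            "some scRNA samples receive zero basis mass; increase the bandwidth"
        )
    if np.all(b == 0):
        raise RuntimeError(
            "no basis mass on the reference; increase the bandwidth"
        )

    a = _project(np.ones(k), b)

    def objective(a_: np.ndarray) -> float:
        wa = A @ a_
        if np.any(wa <= 0):
            return -np.inf
        return float(np.mean(np.log(wa)))

    J = objective(a)
    fit_log = [J]
    step = 1.0
    for _ in range(max_iter):
        grad = A.T @ (1.0 / (A @ a)) / M
        # active-set projected ascent: restrict to coordinates free to move
        # (a_i > 0, or pinned at zero with inward direction), then remove the
        # component along the normalization normal b (renormalization cancels
        # it anyway). Re-reduce until the direction respects the bounds, so
        # the subsequent clipping never flips an ascent step into descent.
        free = (a > 0) | (grad > 0)
        direction = np.zeros_like(a)
        for _ in range(k):
            g_free = grad * free
            b_free = b * free
            bb = float(b_free @ b_free)
            if bb <= 0:
                break
            direction = (g_free - (float(b_free @ g_free) / bb) * b_free) * free
            blocked = (a == 0) & (direction < 0)
            if not np.any(blocked):
                break
            free = free & ~blocked
        if not np.any(direction):
            break
        grad = direction
        accepted = False
        for _ in range(30):
            cand = _project(a + step * grad, b)
            J_new = objective(cand)
            if J_new >= J:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
        improved = J_new - J
        a, J = cand, J_new
        fit_log.append(J)
        step *= 1.5
        if improved < tol:
            break

    return DensityRatioModel(centers=centers, bandwidth=bandwidth, a=a, fit_log=fit_log)


def ratio(model: DensityRatioModel, z: np.ndarray | Embedding) -> np.ndarray:
    """Evaluate w_hat(z) = sum_i a_i phi_i(z) (non-negative)."""
    z = _as_matrix(z)
    if z.shape[1] != model.centers.shape[1]:
        raise ValueError(
            f"dimension {z.shape[1]} does not match centers "
            f"({model.centers.shape[1]})"
        )
    return _phi(z, model.centers, model.bandwidth) @ model.a


def select_bandwidth(
    z_sc: np.ndarray | Embedding,
    z_st: np.ndarray | Embedding,
    candidates: Sequence[float],
    folds: int = 5,
    k: int = 100,
    seed: int = 0,
) -> float:
    """Likelihood cross-validation over bandwidth candidates.

    Folds split the numerator samples; the winner maximizes the held-out
    objective (1/|fold|) sum ln w_hat averaged over folds.
    """
    zn = _as_matrix(z_sc)
    zd = _as_matrix(z_st)
    if len(candidates) == 0:
        raise ValueError("no candidates")
    if len(candidates) == 1:
        return float(candidates[0])
    if folds < 2:
        raise ValueError("folds must be >= 2")
    M = zn.shape[0]
    if folds > M:
        raise ValueError(f"folds={folds} exceeds numerator sample count {M}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(M)
    fold_idx = np.array_split(perm, folds)

    best, best_score = None, -np.inf
    for bw in candidates:
        scores = []
        try:
            for held in fold_idx:
                train = np.setdiff1d(perm, held, assume_unique=False)
                model = fit_kliep(
                    zn[train], zd, k=min(k, train.size), bandwidth=float(bw), seed=seed
                )
                w = ratio(model, zn[held])
                if np.any(w <= 0):
                    scores.append(-np.inf)
                else:
                    scores.append(float(np.mean(np.log(w))))
        except RuntimeError:
            continue
        mean_score = float(np.mean(scores))
        if mean_score > best_score:
            best, best_score = float(bw), mean_score
    if best is None:
        raise RuntimeError("every bandwidth candidate failed to fit")
    return best
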