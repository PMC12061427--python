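"""Shared latent co-embedding of spatial references and scRNA-seq query.

The co-embedding h is a principal-axes projection fitted on the
reference slice(s) alone; the query is projected through the same basis.
Fitting on the reference only preserves the reference-based semantics
(adding query cells never changes the basis) and makes the transfer
premise p_st(y | z) = p_sc(y | z) operative: query and reference pass
through an identical h, so cells with similar latent features land near
similar spatial coordinates.

Because the inputs are z-scored, the per-gene means of the reference are
already zero, so the basis is taken from a plain SVD and the projection
is strictly linear: z = x @ loadings, no centering step.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_prep import GeneMatrix, SpatialSlice

__all__ = ["CoembedModel", "Embedding", "fit_coembed", "embed"]


@dataclass
class CoembedModel:
    """Orthonormal gene-space basis shared by reference and query."""

    gene_ids: list[str]
    loadings: np.ndarray  # H x K, orthonormal columns
    K: int
    fitted_on: list[str]

    def __post_init__(self) -> None:
        self.loadings = np.asarray(self.loadings, dtype=float)
        H = len(self.gene_ids)
        if self.loadings.shape != (H, self.K):
            raise ValueError(
                f"loadings shape {self.loadings.shape} != ({H}, {self.K})"
            )
        gram = self.loadings.T @ self.loadings
        if not np.allclose(gram, np.eye(self.K), atol=1e-6):
            raise ValueError("loadings columns are not orthonormal")

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            self.loadings,
            index=self.gene_ids,
            columns=[f"PC{i + 1}" for i in range(self.K)],
        ).to_csv(directory / "loadings.csv")
        meta = {"gene_ids": self.gene_ids, "K": self.K, "fitted_on": self.fitted_on}
        (directory / "coembed.json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, directory: str | Path) -> "CoembedModel":
        directory = Path(directory)
        meta = json.loads((directory / "coembed.json").read_text())
        loadings = pd.read_csv(
            directory / "loadings.csv", index_col=0
        ).to_numpy(dtype=float)
        return cls(loadings=loadings, **meta)


@dataclass
class Embedding:
    """Latent coordinates z for a batch of samples."""

    z: np.ndarray
    sample_ids: list[str]
    source: str = "sc"

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.z.ndim != 2:
            raise ValueError("z must be 2-D")
        if self.z.shape[0] != len(self.sample_ids):
            raise ValueError("row count does not match sample ids")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("non-finite embedding entries")

    @property
    def K(self) -> int:
        return self.z.shape[1]


def _fix_signs(loadings: np.ndarray) -> np.ndarray:
    # deterministic basis: largest-magnitude entry of each column positive
    idx = np.abs(loadings).argmax(axis=0)
    flips = np.sign(loadings[idx, np.arange(loadings.shape[1])])
    flips[flips == 0] = 1.0
    return loadings * flips


def fit_coembed(
    references: Sequence[SpatialSlice], K: int | None = None
) -> CoembedModel:
    """Fit the principal-axes basis on concatenated reference expression.

    Default K = min(50, H, total_spots - 1). When H <= K the basis is
    the identity on the scaled genes (e.g. a 10-gene toy dataset needs
    no reduction).
    """
    if not references:
        raise ValueError("need at least one reference slice")
    gene_ids = references[0].expr.gene_ids
    for ref in references[1:]:
        if ref.expr.gene_ids != gene_ids:
            raise ValueError(
                f"gene lists differ between slices "
                f"{references[0].slice_id!r} and {ref.slice_id!r}"
            )
    for ref in references:
        if ref.expr.stage != "scaled":
            raise ValueError("references must be stage=scaled")
    X = np.vstack([ref.expr.values for ref in references])
    H = len(gene_ids)
    if K is None:
        K = min(50, H, X.shape[0] - 1)
    if K > H:
        raise ValueError(f"K={K} exceeds gene count H={H}")
    if K > X.shape[0]:
        raise ValueError(f"K={K} exceeds total reference spots {X.shape[0]}")
    fitted_on = [ref.slice_id for ref in references]
    if H <= K:
        return CoembedModel(
            gene_ids=list(gene_ids), loadings=np.eye(H), K=H, fitted_on=fitted_on
        )
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    loadings = _fix_signs(vt[:K].T)
    return CoembedModel(
        gene_ids=list(gene_ids), loadings=loadings, K=K, fitted_on=fitted_on
    )


def embed(model: CoembedModel, gm: GeneMatrix, source: str = "sc") -> Embedding:
    """Project scaled expression through the fitted basis: z = x @ loadings."""
    if gm.stage != "scaled":
        raise ValueError(f"embed expects stage=scaled, got {gm.stage}")
    missing = [g for g in model.gene_ids if g not in set(gm.gene_ids)]
    if missing:
        raise KeyError(f"matrix lacks model genes: {missing}")
    sub = gm.subset_genes(model.gene_ids)
    z = sub.values @ model.loadings
    return Embedding(z=z, sample_ids=list(gm.cell_ids), source=source)
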