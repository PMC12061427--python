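"""Expression/coordinate I/O and preprocessing.

Counts are library-size normalized and log-transformed,

    x_ij = ln(s * d_ij / sum_k d_kj + 1),

with scaling factor ``s`` (default 10 000), then z-scored per gene,

    x_ij <- (x_ij - mu_i) / sigma_i.

Highly variable genes (HVGs) are ranked by Seurat-style normalized
dispersion; references and query keep the common HVG subset. A reversible
polar transform is provided for annular tissues (e.g. artery cross
sections) so that a ring unrolls into a band before mapping.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GeneMatrix",
    "PreprocessModel",
    "SpatialSlice",
    "read_gene_matrix",
    "read_spatial_slice",
    "lognormalize",
    "zscore",
    "select_hvgs",
    "intersect_genes",
    "polar_transform",
]


@dataclass
class GeneMatrix:
    """Cells/spots x genes expression with identifiers.

    ``stage`` tracks where the matrix sits in the preprocessing chain:
    ``raw`` (non-negative counts), ``lognorm`` or ``scaled``.
    """

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    stage: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n_cells, n_genes = self.values.shape
        if len(self.cell_ids) != n_cells:
            raise ValueError(
                f"{len(self.cell_ids)} cell ids for {n_cells} rows"
            )
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {n_genes} columns"
            )
        if len(set(self.cell_ids)) != n_cells:
            raise ValueError("duplicate cell ids")
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("duplicate gene ids")
        if self.stage not in ("raw", "lognorm", "scaled"):
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.stage == "raw" and np.any(self.values < 0):
            raise ValueError("negative raw count in stage=raw matrix")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, gene_ids: Sequence[str]) -> "GeneMatrix":
        """Return a copy restricted to ``gene_ids`` in the given order."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing}")
        cols = [index[g] for g in gene_ids]
        return GeneMatrix(
            self.values[:, cols], list(self.cell_ids), list(gene_ids), self.stage
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.cell_ids, columns=self.gene_ids
        )


@dataclass
class PreprocessModel:
    """Frozen preprocessing state: scaling factor, per-gene mu/sigma, HVGs.

    ``dropped`` lists zero-variance genes removed at z-score time (the
    per-gene standardization is undefined for sigma = 0).
    """

    s: float = 10_000.0
    mu: Optional[np.ndarray] = None
    sigma: Optional[np.ndarray] = None
    hvg: list[str] = field(default_factory=list)
    dropped: list[str] = field(default_factory=list)

    def gene_index(self, gene: str) -> int:
        try:
            return self.hvg.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in preprocessing model") from None


@dataclass
class SpatialSlice:
    """A spatial-transcriptomics slice: expression + 2-D coordinates."""

    expr: GeneMatrix
    coords: np.ndarray
    labels: Optional[list[str]] = None
    slice_id: str = "slice0"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be an m x 2 matrix")
        if self.coords.shape[0] != self.expr.n_cells:
            raise ValueError(
                f"{self.coords.shape[0]} coordinate rows for "
                f"{self.expr.n_cells} expression rows"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if self.labels is not None:
            self.labels = [str(x) for x in self.labels]
            if len(self.labels) != self.expr.n_cells:
                raise ValueError("label count does not match cell count")

    @property
    def n_spots(self) -> int:
        return self.expr.n_cells


def read_gene_matrix(
    path: str | Path, format: str = "csv", stage: str = "raw"
) -> GeneMatrix:
    """Read an expression matrix from CSV or MatrixMarket MTX.

    CSV: cells as rows, header of gene names, first column of cell ids.
    MTX: genes x cells coordinate MatrixMarket (CellRanger convention)
    with companion ``genes.tsv`` and ``barcodes.tsv`` in the same
    directory; the returned matrix is transposed to cells x genes.

    ``stage`` declares where the file sits in the preprocessing chain;
    negative values are rejected only for raw counts.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "csv":
        sep = "\t" if path.suffix in (".tsv", ".txt") else ","
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(sep)[1:]
        if len(set(header)) != len(header):
            dupes = sorted({g for g in header if header.count(g) > 1})
            raise ValueError(f"duplicate gene ids in header: {dupes}")
        df = pd.read_csv(path, sep=sep, index_col=0)
        if df.index.duplicated().any():
            dupes = df.index[df.index.duplicated()].tolist()
            raise ValueError(f"duplicate cell ids: {dupes}")
        values = df.to_numpy(dtype=float)
        if stage == "raw" and np.any(values < 0):
            r, c = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative raw count at cell {df.index[r]!r}, "
                f"gene {df.columns[c]!r}"
            )
        return GeneMatrix(values, df.index.tolist(), df.columns.tolist(), stage)
    if format == "mtx":
        from scipy.io import mmread

        mat = mmread(path).toarray().astype(float)
        genes_path = path.parent / "genes.tsv"
        barcodes_path = path.parent / "barcodes.tsv"
        gene_ids = [
            line.split("\t")[0]
            for line in genes_path.read_text().strip().splitlines()
        ]
        cell_ids = [
            line.split("\t")[0]
            for line in barcodes_path.read_text().strip().splitlines()
        ]
        if mat.shape != (len(gene_ids), len(cell_ids)):
            raise ValueError(
                f"MTX shape {mat.shape} does not match "
                f"{len(gene_ids)} genes x {len(cell_ids)} barcodes"
            )
        if stage == "raw" and np.any(mat < 0):
            raise ValueError("negative raw count in MTX file")
        return GeneMatrix(mat.T, cell_ids, gene_ids, stage)
    raise ValueError(f"unknown format {format!r}")


def read_spatial_slice(
    expr_path: str | Path,
    coords_path: str | Path,
    labels_path: Optional[str | Path] = None,
    format: str = "csv",
    slice_id: Optional[str] = None,
    stage: str = "raw",
) -> SpatialSlice:
    """Read expression + coordinates (+ optional labels), aligned by id.

    The coordinate CSV has columns ``id,x,y``; its id set must equal the
    expression cell ids. Label rows with ids absent from the expression
    are ignored with a warning.
    """
    gm = read_gene_matrix(expr_path, format=format, stage=stage)
    coords_df = pd.read_csv(coords_path)
    coords_df = coords_df.set_index(coords_df.columns[0])
    missing = sorted(set(gm.cell_ids) - set(coords_df.index.astype(str)))
    if missing:
        raise ValueError(f"coordinates missing for ids: {missing}")
    coords_df.index = coords_df.index.astype(str)
    coords = coords_df.loc[gm.cell_ids].iloc[:, :2].to_numpy(dtype=float)

    labels = None
    if labels_path is not None:
        lab_df = pd.read_csv(labels_path)
        lab_df = lab_df.set_index(lab_df.columns[0])
        lab_df.index = lab_df.index.astype(str)
        extra = sorted(set(lab_df.index) - set(gm.cell_ids))
        if extra:
            logger.warning("ignoring %d label ids absent from expression", len(extra))
        missing_lab = sorted(set(gm.cell_ids) - set(lab_df.index))
        if missing_lab:
            raise ValueError(f"labels missing for ids: {missing_lab}")
        labels = lab_df.loc[gm.cell_ids].iloc[:, 0].astype(str).tolist()

    return SpatialSlice(
        gm, coords, labels, slice_id or Path(expr_path).stem
    )


def lognormalize(gm: GeneMatrix, s: float = 10_000.0) -> GeneMatrix:
    """Library-size normalize and log-transform raw counts.

    x_ij = ln(s * d_ij / total_j + 1) where total_j is the count sum of
    cell j. Every cell must have a positive total.
    """
    if gm.stage != "raw":
        raise ValueError(f"lognormalize expects stage=raw, got {gm.stage}")
    if s <= 0:
        raise ValueError("scaling factor s must be positive")
    totals = gm.values.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(
            f"zero library size for cells: {[gm.cell_ids[i] for i in zero]}"
        )
    x = np.log1p(s * gm.values / totals[:, None])
    return GeneMatrix(x, list(gm.cell_ids), list(gm.gene_ids), "lognorm")


def zscore(
    gm: GeneMatrix, model: Optional[PreprocessModel] = None
) -> tuple[GeneMatrix, PreprocessModel]:
    """Per-gene standardization, fitting or applying a PreprocessModel.

    Fit mode (``model is None``): mu/sigma computed on ``gm`` (population
    sd, ddof=0); zero-variance genes are dropped and recorded. Apply mode
    reuses the stored mu/sigma on the model's gene list.
    """
    if model is None:
        mu = gm.values.mean(axis=0)
        sigma = gm.values.std(axis=0)
        keep = sigma > 0
        dropped = [g for g, k in zip(gm.gene_ids, keep) if not k]
        if dropped:
            logger.warning("dropping %d zero-variance genes", len(dropped))
        genes = [g for g, k in zip(gm.gene_ids, keep) if k]
        out = PreprocessModel(
            mu=mu[keep], sigma=sigma[keep], hvg=genes, dropped=dropped
        )
        vals = (gm.values[:, keep] - out.mu) / out.sigma
        return GeneMatrix(vals, list(gm.cell_ids), genes, "scaled"), out

    missing = [g for g in model.hvg if g not in set(gm.gene_ids)]
    if missing:
        raise KeyError(f"genes in model absent from matrix: {missing}")
    sub = gm.subset_genes(model.hvg)
    vals = (sub.values - model.mu) / model.sigma
    return GeneMatrix(vals, list(gm.cell_ids), list(model.hvg), "scaled"), model


def select_hvgs(gm: GeneMatrix, n_top: int) -> list[str]:
    """Top ``n_top`` genes by Seurat-style normalized dispersion.

    Dispersion is computed on log-normalized expression after binning by
    mean (scanpy's seurat flavor); ties broken by lexicographic gene id
    so the ranking is deterministic.
    """
    if n_top <= 0:
        raise ValueError("n_top must be positive")
    if n_top > gm.n_genes:
        raise ValueError(f"n_top={n_top} exceeds gene count {gm.n_genes}")
    if n_top == gm.n_genes:
        return list(gm.gene_ids)
    import anndata as ad
    import scanpy as sc

    if gm.stage == "raw":
        gm = lognormalize(gm)
    adata = ad.AnnData(
        X=gm.values.copy(),
        obs=pd.DataFrame(index=gm.cell_ids),
        var=pd.DataFrame(index=gm.gene_ids),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.pp.highly_variable_genes(adata, flavor="seurat", n_top_genes=n_top)
    disp = adata.var["dispersions_norm"].to_numpy(dtype=float)
    disp = np.nan_to_num(disp, nan=-np.inf)
    order = sorted(
        range(gm.n_genes), key=lambda i: (-disp[i], gm.gene_ids[i])
    )
    return [gm.gene_ids[i] for i in order[:n_top]]


def intersect_genes(*lists: Sequence[str]) -> list[str]:
    """Common genes across lists, ordered by the first list."""
    if len(lists) < 2:
        raise ValueError("need at least two gene lists")
    if any(len(lst) == 0 for lst in lists):
        raise ValueError("empty gene list")
    common = set(lists[0])
    for lst in lists[1:]:
        common &= set(lst)
    out = [g for g in lists[0] if g in common]
    if not out:
        logger.warning("gene lists have an empty intersection")
    return out


def polar_transform(
    coords: np.ndarray,
    center: Optional[np.ndarray] = None,
    inverse: bool = False,
) -> np.ndarray:
    """Reversible polar unrolling for annular tissues.

    Forward maps (x, y) -> (r_bar * theta, r) about ``center`` (default:
    the centroid), with theta in [0, 2*pi) and r_bar the mean radius, so
    a ring unrolls into a horizontal band whose x-scale matches arc
    length at the mean radius. Inverse maps (u, r) back; r_bar is
    recovered as the mean of the r column, which equals the forward
    r_bar by construction. To round-trip, pass the same ``center`` to
    both calls (the centroid default is computed from the forward input
    and is not recoverable from the band). Points on the theta = 0 / 2*pi
    seam are mapped to theta = 0; the transform is exact away from
    reconstructing angular continuity across that seam.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coords must be m x 2")
    if inverse:
        c = np.zeros(2) if center is None else np.asarray(center, dtype=float)
        u, r = coords[:, 0], coords[:, 1]
        r_bar = r.mean()
        theta = u / r_bar
        return np.column_stack(
            [c[0] + r * np.cos(theta), c[1] + r * np.sin(theta)]
        )
    c = coords.mean(axis=0) if center is None else np.asarray(center, dtype=float)
    d = coords - c
    r = np.hypot(d[:, 0], d[:, 1])
    if np.any(r == 0):
        raise ValueError("a point coincides with the transform center")
    theta = np.mod(np.arctan2(d[:, 1], d[:, 0]), 2 * np.pi)
    r_bar = r.mean()
    return np.column_stack([r_bar * theta, r])
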