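"""End-to-end convenience pipeline.

Chains the full method: per-dataset normalization and gene selection,
reference-fitted co-embedding, density-ratio estimation between query
and reference, importance-weighted training of the coordinate
regressor, and query placement. Each stage remains individually
accessible through its own module; this wrapper only fixes the glue
(common-gene intersection, per-dataset z-scoring, seed threading).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .coembed import CoembedModel, Embedding, embed, fit_coembed
from .density_ratio import DensityRatioModel, ratio
from .io_prep import (
    GeneMatrix,
    PreprocessModel,
    SpatialSlice,
    intersect_genes,
    lognormalize,
    select_hvgs,
    zscore,
)
from .mapper import (
    MapperConfig,
    MapperModel,
    estimate_slice_weights,
    fit_mapper,
    predict_locations,
)

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    """Everything a run produces, for inspection and downstream analyses."""

    mapper: MapperModel
    prep_sc: PreprocessModel
    prep_st: list[PreprocessModel]
    sc_scaled: GeneMatrix
    st_scaled: list[SpatialSlice]
    ratio_model: DensityRatioModel
    spot_weights: list[np.ndarray]
    slice_weights: np.ndarray
    predictions: np.ndarray
    common_genes: list[str]


def _prepare(
    gm: GeneMatrix, do_lognorm: bool, s: float
) -> GeneMatrix:
    if gm.stage == "raw" and do_lognorm:
        return lognormalize(gm, s=s)
    return gm


def run_pipeline(
    st_slices: Sequence[SpatialSlice],
    sc: GeneMatrix,
    n_hvg: Optional[int] = None,
    K: Optional[int] = None,
    kliep_k: int = 100,
    bandwidth: Optional[float] = None,
    config: Optional[MapperConfig] = None,
    do_lognorm: bool = True,
    s: float = 10_000.0,
    seed: int = 0,
    use_ratio_weights: bool = True,
) -> PipelineResult:
    """Fit the full expression-to-space mapping and place the query cells.

    ``n_hvg`` selects highly variable genes per dataset before taking
    the common subset (all genes when None). ``use_ratio_weights=False``
    trains an unweighted regression (useful as an ablation baseline).
    Each dataset is z-scored with its own per-gene statistics; genes
    without variance in every dataset are excluded up front so the gene
    panel is identical everywhere.
    """
    if not st_slices:
        raise ValueError("need at least one reference slice")
    config = config or MapperConfig(seed=seed)

    st_ln = [
        SpatialSlice(
            _prepare(sl.expr, do_lognorm, s), sl.coords, sl.labels, sl.slice_id
        )
        for sl in st_slices
    ]
    sc_ln = _prepare(sc, do_lognorm, s)

    # gene panel: per-dataset HVGs intersected, restricted to genes with
    # variance everywhere (z-score is undefined otherwise)
    if n_hvg is not None:
        lists = [select_hvgs(sl.expr, min(n_hvg, sl.expr.n_genes)) for sl in st_ln]
        lists.append(select_hvgs(sc_ln, min(n_hvg, sc_ln.n_genes)))
        common = intersect_genes(*lists) if len(lists) > 1 else lists[0]
    else:
        common = list(sc_ln.gene_ids)
        for sl in st_ln:
            common = intersect_genes(common, sl.expr.gene_ids)
    if not common:
        raise ValueError("no common genes between query and reference")

    def variable(gm: GeneMatrix) -> np.ndarray:
        return gm.subset_genes(common).values.std(axis=0) > 0

    keep = variable(sc_ln)
    for sl in st_ln:
        keep &= variable(sl.expr)
    common = [g for g, k in zip(common, keep) if k]
    if not common:
        raise ValueError("no informative common genes")

    prep_st: list[PreprocessModel] = []
    st_scaled: list[SpatialSlice] = []
    for sl in st_ln:
        scaled, model = zscore(sl.expr.subset_genes(common))
        prep_st.append(model)
        st_scaled.append(SpatialSlice(scaled, sl.coords, sl.labels, sl.slice_id))
    sc_scaled, prep_sc = zscore(sc_ln.subset_genes(common))

    coembed_model = fit_coembed(st_scaled, K=K)
    z_sc = embed(coembed_model, sc_scaled, source="sc")
    z_slices = [
        Embedding(
            embed(coembed_model, sl.expr, source="st").z,
            sl.expr.cell_ids,
            source=sl.slice_id,
        )
        for sl in st_scaled
    ]

    slice_weights, ratio_model = estimate_slice_weights(
        z_sc, z_slices, k=kliep_k, bandwidth=bandwidth, seed=seed
    )
    spot_weights = [ratio(ratio_model, e.z) for e in z_slices]

    mapper = fit_mapper(
        st_scaled,
        coembed_model,
        ratios=spot_weights if use_ratio_weights else None,
        slice_weights=slice_weights,
        config=config,
    )
    predictions = predict_locations(mapper, sc_scaled)
    return PipelineResult(
        mapper=mapper,
        prep_sc=prep_sc,
        prep_st=prep_st,
        sc_scaled=sc_scaled,
        st_scaled=st_scaled,
        ratio_model=ratio_model,
        spot_weights=spot_weights,
        slice_weights=slice_weights,
        predictions=predictions,
        common_genes=common,
    )
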