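"""End-to-end statistical pipeline for one viewpoint.

Order of operations (matching the intended analysis workflow):

1. size factors from the full count matrix;
2. low-count filter (median across samples >= ``min_median``);
3. viewpoint-zone masking by the first-signal-increase heuristic,
   walking outward over the kept fragments;
4. VST parameters fitted on the remaining (tested) fragments;
5. monotone decay fit on the transformed counts of tested cis fragments;
6. residuals, MAD-scaled z-scores, one-sided P-values, per-sample BH;
7. per-condition interaction calls;
8. (optionally) normalization factors, dispersion shrinkage and the
   NB-GLM Wald test for a condition contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import calling, decay, differential, vst
from .fragments import Viewpoint


@dataclass
class AnalysisConfig:
    min_median: float = 40.0
    z_thresh: float = 3.0
    padj_thresh: float = 0.01
    fit_mode: str = "symmetric"
    lam: float = 1.0
    max_mask_per_side: int = 20
    min_fragments_scale: int = 20


@dataclass
class AnalysisResult:
    config: AnalysisConfig
    size_factors: np.ndarray
    kept: pd.Index
    masked: set
    tested: pd.Index
    vst_params: vst.VSTParams
    v_matrix: pd.DataFrame
    fit: decay.DecayFit
    residuals: pd.DataFrame
    z: pd.DataFrame
    sigma: pd.Series
    p: pd.DataFrame
    padj: pd.DataFrame
    calls: pd.DataFrame
    distances: pd.Series
    conditions: pd.Series


def analyze_viewpoint(
    counts: pd.DataFrame,
    fragments: pd.DataFrame,
    viewpoint: Viewpoint,
    sample_table: pd.DataFrame,
    distances: pd.Series | None = None,
    config: AnalysisConfig | None = None,
) -> AnalysisResult:
    """Run the interaction-calling pipeline for one viewpoint.

    ``counts`` is the fragments x samples matrix restricted to valid
    fragments; ``sample_table`` must carry ``condition`` indexed by
    sample id matching the count columns.
    """
    cfg = config or AnalysisConfig()
    conditions = sample_table.loc[counts.columns, "condition"]
    if distances is None:
        from .fragments import fragment_distances

        distances = fragment_distances(fragments, viewpoint)
    d = distances.reindex(counts.index)

    s = vst.size_factors(counts)

    kept = calling.filter_low_counts(counts, cfg.min_median)

    # per-fragment signal for the masking walk: mean normalized count
    signal = (counts / s[None, :]).mean(axis=1)
    on_vp_chrom = fragments.loc[counts.index, "chrom"] == viewpoint.chrom
    walk_ids = counts.index[on_vp_chrom & (counts.index.isin(kept)
                                           | (counts.index == viewpoint.fragment_index))]
    order = fragments.loc[walk_ids].sort_values("start").index
    if viewpoint.fragment_index in set(order):
        masked = calling.mask_viewpoint_zone(
            signal, order, viewpoint.fragment_index, cfg.max_mask_per_side
        )
    else:
        masked = {viewpoint.fragment_index}

    tested = kept[~kept.isin(masked)]
    if len(tested) < cfg.min_fragments_scale:
        raise ValueError(
            f"only {len(tested)} fragments remain after filtering and masking"
        )

    params = vst.fit_vst(counts.loc[tested], s)
    v_matrix = vst.transform_matrix(counts.loc[tested], params)

    fit = decay.fit_decay(v_matrix, d.loc[tested], mode=cfg.fit_mode, lam=cfg.lam)
    residuals = decay.residual_matrix(v_matrix, fit, d.loc[tested])

    zs = calling.z_scores(residuals, min_fragments=cfg.min_fragments_scale)
    p, padj = calling.p_values(zs.z)
    calls = calling.call_interactions(
        zs.z, padj, conditions, z_thresh=cfg.z_thresh, padj_thresh=cfg.padj_thresh
    )
    return AnalysisResult(
        config=cfg,
        size_factors=s,
        kept=kept,
        masked=masked,
        tested=tested,
        vst_params=params,
        v_matrix=v_matrix,
        fit=fit,
        residuals=residuals,
        z=zs.z,
        sigma=zs.sigma,
        p=p,
        padj=padj,
        calls=calls,
        distances=d,
        conditions=conditions,
    )


def differential_analysis(
    counts: pd.DataFrame,
    result: AnalysisResult,
    contrast: tuple[str, str],
    padj_thresh: float | None = None,
) -> tuple[differential.DifferentialResult, pd.DataFrame]:
    """NB-GLM Wald test on the tested fragments of an analysis run."""
    n = differential.normalization_factors(
        result.fit, result.distances.loc[result.tested], result.vst_params,
        index=result.tested,
    )
    sub = counts.loc[result.tested]
    disp = differential.estimate_dispersions(sub, n, result.conditions)
    res = differential.nb_wald_test(sub, n, result.conditions, contrast, dispersions=disp)
    flags = differential.call_differential(
        res,
        padj_thresh=padj_thresh if padj_thresh is not None else result.config.padj_thresh,
        interaction_calls=result.calls,
    )
    return res, flags
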