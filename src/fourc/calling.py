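"""Interaction calling from decay-fit residuals.

Fragments whose transformed signal stands out above the fitted distance
decay are candidate specific interactions.  The workflow is:

1. drop fragments with a low median count across samples (noise floor);
2. mask the viewpoint-proximal zone, where ligation frequencies are so
   high that they obscure specific signal — walking outward from the
   viewpoint, the zone ends at the first fragment where the signal
   increases between successive fragments;
3. z_ij = r_ij / sigma_j, with sigma_j the median absolute deviation of
   the residuals scaled by 1.4826 so that z is standard normal for
   normally distributed null residuals;
4. one-sided P-values p = 1 - Phi(z), Benjamini-Hochberg adjusted per
   sample;
5. a fragment is called for a condition when z exceeds the z threshold
   in all replicates and the adjusted P-value passes in at least one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

MAD_SCALE = 1.4826  # normal-consistency constant


def filter_low_counts(counts: pd.DataFrame, min_median: float = 40) -> pd.Index:
    """Fragments whose median count across samples is >= ``min_median``."""
    med = counts.median(axis=1)
    return counts.index[med >= min_median]


def mask_viewpoint_zone(
    signal: pd.Series,
    order: pd.Index,
    viewpoint_id,
    max_mask_per_side: int = 20,
) -> set:
    """Identify the viewpoint-proximal fragments to set aside.

    ``order`` lists fragment ids on the viewpoint chromosome sorted by
    genomic position (typically the count-filtered fragments plus the
    viewpoint fragment itself); ``signal`` gives a per-fragment summary
    (e.g. mean normalized count — the rule only compares neighbours, so
    any strictly monotone transform of it gives the same mask).

    Walking outward from the viewpoint on each side, the masked zone
    ends just before the first fragment whose signal increases relative
    to its inward neighbour.  The viewpoint fragment is always masked;
    ``max_mask_per_side`` caps the zone.
    """
    order = list(order)
    if viewpoint_id not in order:
        raise ValueError("viewpoint fragment not in the ordered fragment list")
    vp = order.index(viewpoint_id)
    masked = {viewpoint_id}
    for step in (1, -1):
        ids = order[vp + 1 :] if step == 1 else order[:vp][::-1]
        vals = signal.reindex(ids).to_numpy(dtype=float)
        t = len(vals)
        for i in range(1, len(vals)):
            if vals[i] > vals[i - 1]:
                t = i
                break
        if t == len(vals) and len(vals) > max_mask_per_side:
            warnings.warn(
                "signal monotone decreasing to the chromosome end; "
                f"masking capped at {max_mask_per_side} fragments",
                stacklevel=2,
            )
        t = min(t, max_mask_per_side)
        masked.update(ids[:t])
    return masked


@dataclass(frozen=True)
class ZScores:
    z: pd.DataFrame
    sigma: pd.Series  # per-sample residual scale


def z_scores(residuals: pd.DataFrame, min_fragments: int = 20,
             sigma_floor: float = 0.0) -> ZScores:
    """Residual z-scores with MAD-based per-sample scale.

    sigma_j = 1.4826 * median_i |r_ij - median_i(r_ij)|; z_ij = r_ij / sigma_j.
    The MAD is centred at the residual median for robustness to fit
    offset; the residual itself is not re-centred, so the z-score keeps
    its interpretability as (signal - trend) in scale units.
    """
    if len(residuals) < min_fragments:
        raise ValueError(f"need >= {min_fragments} fragments to estimate the residual scale")
    med = residuals.median(axis=0)
    sigma = MAD_SCALE * (residuals - med).abs().median(axis=0)
    if sigma_floor > 0:
        sigma = sigma.clip(lower=sigma_floor)
    if (sigma <= 0).any():
        bad = sigma.index[sigma <= 0].tolist()
        raise ValueError(f"degenerate residual scale (sigma = 0) for samples {bad}")
    return ZScores(z=residuals / sigma, sigma=sigma)


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def p_values(z: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One-sided normal P-values and per-sample BH adjustment.

    The tested family of each sample is the set of fragments in ``z``
    (count-filtered, viewpoint-masked fragments of one viewpoint).
    """
    p = pd.DataFrame(norm.sf(z.to_numpy()), index=z.index, columns=z.columns)
    padj = p.apply(lambda col: pd.Series(benjamini_hochberg(col.to_numpy()), index=col.index))
    return p, padj


def call_interactions(
    z: pd.DataFrame,
    padj: pd.DataFrame,
    conditions: pd.Series,
    z_thresh: float = 3.0,
    padj_thresh: float = 0.01,
) -> pd.DataFrame:
    """Per-condition interaction calls.

    ``conditions`` maps sample -> condition label.  A fragment is called
    for a condition iff z > z_thresh in *all* replicates of that
    condition and adjusted P < padj_thresh in *at least one* replicate.
    With a single replicate both clauses apply to the same sample.
    """
    conditions = pd.Series(conditions)
    calls = {}
    for cond in conditions.unique():
        reps = conditions.index[conditions == cond]
        if len(reps) == 1:
            warnings.warn(
                f"condition {cond!r} has a single replicate; "
                "the calling rule degenerates to one sample",
                stacklevel=2,
            )
        z_ok = (z[reps] > z_thresh).all(axis=1)
        p_ok = (padj[reps] < padj_thresh).any(axis=1)
        calls[cond] = z_ok & p_ok
    return pd.DataFrame(calls, index=z.index)


def results_table(
    fragments: pd.DataFrame,
    d: pd.Series,
    z: pd.DataFrame,
    p: pd.DataFrame,
    padj: pd.DataFrame,
    calls: pd.DataFrame,
) -> pd.DataFrame:
    """Flat per-fragment results for export."""
    out = fragments.loc[z.index, ["chrom", "start", "end"]].copy()
    out["distance"] = d.reindex(z.index)
    for s in z.columns:
        out[f"z.{s}"] = z[s]
        out[f"p.{s}"] = p[s]
        out[f"padj.{s}"] = padj[s]
    for c in calls.columns:
        out[f"called.{c}"] = calls[c]
    return out
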