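"""Variance-stabilizing transformation (VST) for NB-distributed 4C counts.

Fragment counts span several orders of magnitude between the viewpoint
neighbourhood and the far background.  On the raw scale the standard
deviation grows with the mean; on the log scale it blows up at low
counts.  Either way a distance-decay fit would be dominated by one end
of the profile.  We therefore model the dispersion of normalized counts
as a two-parameter trend

    alpha(mu) = a / mu + b        (a >= 0: extra-Poisson low-count term,
                                   b > 0: asymptotic squared CV)

so that Var(K) = (1 + a) mu + b mu^2, and apply the closed-form
antiderivative of 1 / sqrt(Var(mu)) scaled to be log2-like for large
counts:

    v(k) = log2( (1 + a + 2 b q + 2 sqrt(b q (1 + a + b q))) / (4 b) ),
    q = k / s_j.

This transform is strictly increasing, finite at k = 0, satisfies
v(2q) - v(q) -> 1 for large q, and stabilizes the standard deviation of
v(K) at sqrt(b) / ln 2 across the whole dynamic range.  The exact
algebraic inverse is provided for back-transforming fitted trend values
to the raw-count scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

_B_FLOOR = 1e-8


def size_factors(counts) -> np.ndarray:
    """Median-of-ratios library size factors, rescaled to unit geometric mean.

    For each fragment with all-positive counts, the ratio of each
    sample's count to the fragment's geometric mean across samples is
    formed; the per-sample median of these ratios is the size factor.
    Falls back to total-count ratios (with a warning) if no fragment has
    all-positive counts.
    """
    k = np.asarray(counts, dtype=float)
    if k.ndim != 2:
        raise ValueError("counts must be a fragments x samples matrix")
    pos = (k > 0).all(axis=1)
    if pos.any():
        logk = np.log(k[pos])
        log_geo = logk.mean(axis=1, keepdims=True)
        s = np.exp(np.median(logk - log_geo, axis=0))
    else:
        warnings.warn("no fragment with all-positive counts; using total-count ratios",
                      stacklevel=2)
        totals = k.sum(axis=0)
        if (totals <= 0).any():
            raise ValueError("a sample has zero total counts")
        s = totals
    s = s / np.exp(np.mean(np.log(s)))
    return s


@dataclass(frozen=True)
class VSTParams:
    """Parameters of the variance-stabilizing transformation.

    a: extra-Poisson coefficient (>= 0) of the dispersion trend a/mu + b.
    b: asymptotic dispersion (> 0; clamped to a small floor if the trend
       fit returns a non-positive value).
    size_factors: per-sample normalization s_j with unit geometric mean.
    """

    a: float
    b: float
    size_factors: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "size_factors", np.asarray(self.size_factors, dtype=float))
        if self.a < 0:
            raise ValueError("a must be >= 0")
        if self.b <= 0:
            raise ValueError("b must be > 0")
        if (self.size_factors <= 0).any():
            raise ValueError("size factors must be positive")

    def v0(self) -> float:
        """Transform value at k = 0 (lower end of the range of v)."""
        return float(np.log2((1.0 + self.a) / (4.0 * self.b)))


def fit_dispersion_trend(counts, s: np.ndarray, min_fragments: int = 50,
                         max_iter: int = 10, tol: float = 1e-6,
                         outlier_sd: float = 4.0) -> tuple[float, float]:
    """Fit the dispersion trend alpha(mu) = a/mu + b by robust IRLS.

    Method-of-moments per-fragment dispersions from size-factor
    normalized counts are regressed on (1/mu, 1) by iteratively
    reweighted least squares with inverse-variance weights, excluding
    points whose standardized residual exceeds ``outlier_sd`` at each
    iteration (this rejects fragments with genuine signal spikes while
    leaving the bulk sampling noise, which is strongly right-skewed for
    few replicates, untrimmed and hence unbiased).  The fit uses the
    raw (unclipped) moment estimates: clipping negative values at zero
    before averaging would bias the trend upward at the Poisson
    boundary, where roughly half the per-fragment estimates fall below
    zero by sampling noise.  The returned parameters are clamped to
    a >= 0 and b >= 1e-8.
    """
    k = np.asarray(counts, dtype=float)
    q = k / np.asarray(s, dtype=float)[None, :]
    mu = q.mean(axis=1)
    use = mu > 0
    if use.sum() < min_fragments:
        raise ValueError(
            f"only {int(use.sum())} fragments with positive mean "
            f"(need >= {min_fragments}); consider fitting across viewpoints"
        )
    var = q[use].var(axis=1, ddof=1)
    mu = mu[use]
    alpha_hat = (var - mu) / mu**2
    X = np.column_stack([1.0 / mu, np.ones_like(mu)])
    keep = np.ones(len(mu), dtype=bool)
    coef = np.array([1.0, max(float(np.median(alpha_hat)), 1e-4)])
    for _ in range(max_iter):
        # inverse-variance weights: the SD of the moment estimator scales
        # with the squared total CV, (1+a)/mu + alpha
        scale = np.maximum((1.0 + max(coef[0], 0.0)) / mu + np.maximum(X @ coef, 0.0), 1e-8)
        w = 1.0 / scale**2
        sw = np.sqrt(w[keep])
        new, *_ = np.linalg.lstsq(X[keep] * sw[:, None], alpha_hat[keep] * sw, rcond=None)
        # exclude gross outliers (spiked fragments) by standardized residual;
        # a quantile trim would bias the fit low, since the sampling noise of
        # a variance estimate from few replicates is strongly right-skewed
        resid = (alpha_hat - X @ new) * np.sqrt(w)
        keep = np.abs(resid) <= outlier_sd
        if np.max(np.abs(new - coef)) < tol:
            coef = new
            break
        coef = new
    a = float(max(coef[0], 0.0))
    b = float(max(coef[1], _B_FLOOR))
    return a, b


def _check_sample_index(params: VSTParams, j) -> np.ndarray:
    s = params.size_factors
    if j is None:
        return s[None, :]
    return np.asarray(s[j], dtype=float)


def vst(k, params: VSTParams, j=None):
    """Apply the variance-stabilizing transformation to counts.

    ``j`` selects the sample whose size factor applies; ``j=None``
    treats ``k`` as a fragments x samples matrix and broadcasts all size
    factors column-wise.
    """
    k = np.asarray(k, dtype=float)
    if (k < 0).any():
        raise ValueError("counts must be non-negative")
    q = k / _check_sample_index(params, j)
    a, b = params.a, params.b
    return np.log2((1.0 + a + 2.0 * b * q + 2.0 * np.sqrt(b * q * (1.0 + a + b * q)))
                   / (4.0 * b))


def inverse_vst(u, params: VSTParams, j=None):
    """Exact inverse of :func:`vst`, on the raw-count scale.

    Solving v(q) = u for q gives q = (y - 1 - a)^2 / (4 b y) with
    y = 4 b 2^u; the result is rescaled by the sample's size factor.
    Values below v(0) are outside the range of the transform.
    """
    u = np.asarray(u, dtype=float)
    a, b = params.a, params.b
    if (u < params.v0() - 1e-9).any():
        raise ValueError("value below transform range v(0)")
    y = 4.0 * b * np.exp2(u)
    w = np.maximum(y - 1.0 - a, 0.0)
    q = w**2 / (4.0 * b * y)
    return q * _check_sample_index(params, j)


def fit_vst(counts, s: np.ndarray | None = None, **trend_kwargs) -> VSTParams:
    """Convenience: size factors (unless given) + dispersion trend fit."""
    if s is None:
        s = size_factors(counts)
    a, b = fit_dispersion_trend(counts, s, **trend_kwargs)
    return VSTParams(a=a, b=b, size_factors=s)


def transform_matrix(counts: pd.DataFrame, params: VSTParams) -> pd.DataFrame:
    """VST a fragments x samples DataFrame, preserving index/columns."""
    v = vst(counts.to_numpy(), params, j=None)
    return pd.DataFrame(v, index=counts.index, columns=counts.columns)
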