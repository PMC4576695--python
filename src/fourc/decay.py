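"""Smooth monotone fit of the 4C distance-decay trend.

The expected (transformed) 4C signal decreases monotonically with
genomic distance from the viewpoint and flattens into background.  Per
sample we regress the variance-stabilized counts v(k_ij) on
x = log10 |d_i| with a monotone non-increasing smooth:

    f(x) = intercept + sum_m c_m I_m(x),   c_m <= 0,

where the I_m are monotone non-decreasing I-spline basis functions,
built as reversed cumulative sums of a clamped cubic B-spline basis with
interior knots at the deciles of x.  The coefficients are found by
bounded least squares with a second-difference roughness penalty on the
spline coefficients (lambda, default 1.0).  Outside the fitted distance
range the curve extrapolates as a constant (plateau).

Fitting is either *symmetric* (both sides of the viewpoint pooled on
|d|, so f(d) = f(-d) exactly) or *per-side* (independent monotone fits
left and right of the viewpoint, useful at domain boundaries).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.optimize import lsq_linear

MODES = ("symmetric", "per_side")
_DEGREE = 3  # cubic I-spline pieces: C2-smooth monotone curve


def _knot_vector(x: np.ndarray, n_interior: int = 9) -> np.ndarray:
    """Clamped knot vector with interior knots at the deciles of x."""
    lo, hi = float(x.min()), float(x.max())
    if hi <= lo:
        hi = lo + 1e-6
    qs = np.quantile(x, np.linspace(0, 1, n_interior + 2)[1:-1])
    interior = np.unique(qs[(qs > lo) & (qs < hi)])
    return np.concatenate([[lo] * (_DEGREE + 1), interior, [hi] * (_DEGREE + 1)])


def _ispline_design(x: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Monotone (I-spline) design matrix on knot vector ``t``.

    Column m is sum_{l >= m} B_l(x); by the telescoping of the B-spline
    derivative formula each column is non-decreasing in x, rising from 0
    to 1.  The first cumulative sum is identically 1 (partition of
    unity) and is dropped in favour of the free intercept.
    """
    lo, hi = t[0], t[-1]
    xc = np.clip(x, lo, hi)
    B = BSpline.design_matrix(xc, t, _DEGREE, extrapolate=False).toarray()
    I = np.cumsum(B[:, ::-1], axis=1)[:, ::-1]
    return I[:, 1:]


@dataclass
class _SideFit:
    t: np.ndarray
    coef: np.ndarray  # non-positive spline coefficients
    intercept: float
    x_min: float
    x_max: float

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        D = _ispline_design(np.clip(x, self.x_min, self.x_max), self.t)
        return self.intercept + D @ self.coef

    def plateau(self) -> float:
        """Curve value at the largest fitted distance (background level)."""
        return float(self.predict(np.array([self.x_max]))[0])


def _fit_side(x: np.ndarray, y: np.ndarray, lam: float) -> _SideFit:
    t = _knot_vector(x)
    D = _ispline_design(x, t)
    n_obs, m = D.shape
    A = np.column_stack([np.ones(n_obs), D])
    if m >= 3 and lam > 0:
        # second differences of the monotone-basis coefficients; scaled by
        # sqrt(n) so the data/penalty balance is independent of sample size
        # (and a mirrored-data symmetric fit equals the per-side fits)
        P = np.zeros((m - 2, m + 1))
        for r in range(m - 2):
            P[r, r + 1 : r + 4] = (1.0, -2.0, 1.0)
        A = np.vstack([A, np.sqrt(lam * n_obs) * P])
        y_aug = np.concatenate([y, np.zeros(m - 2)])
    else:
        y_aug = y
    lo = np.full(m + 1, -np.inf)
    hi = np.concatenate([[np.inf], np.zeros(m)])  # spline coefs <= 0
    sol = lsq_linear(A, y_aug, bounds=(lo, hi), tol=1e-12)
    return _SideFit(
        t=t,
        coef=sol.x[1:],
        intercept=float(sol.x[0]),
        x_min=float(x.min()),
        x_max=float(x.max()),
    )


@dataclass
class DecayFit:
    """Fitted distance-decay trend f_j(d) for every sample.

    ``sides[sample]`` maps side label ("both" in symmetric mode, "left"/
    "right" in per-side mode) to the underlying spline fit.  ``fitted``
    caches f_j(d_i) for the fragments used in fitting.
    """

    mode: str
    samples: list
    sides: dict = field(default_factory=dict)
    fitted: pd.DataFrame | None = None
    lam: float = 1.0

    def evaluate(self, sample, d) -> np.ndarray:
        """Evaluate f_sample at signed distance(s) d (nt).

        d = 0 is the viewpoint fragment, which is always masked from the
        analysis, hence an error.  Distances beyond the fitted range
        evaluate to the boundary (plateau) value.
        """
        d = np.atleast_1d(np.asarray(d, dtype=float))
        if np.any(d == 0):
            raise ValueError("f(0) undefined: the viewpoint fragment is masked")
        if np.any(np.isnan(d)):
            raise ValueError("distance is NaN (trans fragment); use plateau()")
        x = np.log10(np.maximum(np.abs(d), 1.0))
        fits = self.sides[sample]
        if self.mode == "symmetric":
            return fits["both"].predict(x)
        out = np.empty_like(x)
        left = d < 0
        if left.any():
            out[left] = fits["left"].predict(x[left])
        if (~left).any():
            out[~left] = fits["right"].predict(x[~left])
        return out

    def plateau(self, sample) -> float:
        """Background level: fitted value at the largest distance.

        In per-side mode the two sides' plateaus are averaged; this is
        the reference value used for trans-chromosomal fragments, which
        have no defined genomic distance.
        """
        fits = self.sides[sample]
        return float(np.mean([f.plateau() for f in fits.values()]))


def fit_decay(
    v_matrix: pd.DataFrame,
    d: pd.Series,
    mode: str = "symmetric",
    lam: float = 1.0,
    min_side: int = 30,
) -> DecayFit:
    """Fit the monotone decay trend per sample.

    ``v_matrix`` holds transformed counts for the fragments entering the
    fit (count-filtered, viewpoint-masked already applied); ``d`` their
    signed distances (NaN = trans, excluded).  Symmetric mode pools both
    sides on |d|; per-side mode fits each side independently, falling
    back to symmetric with a warning when a side has fewer than
    ``min_side`` fragments.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    d = d.reindex(v_matrix.index)
    cis = d.notna() & (d != 0)
    if mode == "per_side":
        n_left = int((d[cis] < 0).sum())
        n_right = int((d[cis] > 0).sum())
        if min(n_left, n_right) < min_side:
            warnings.warn(
                f"per-side fit needs >= {min_side} fragments per side "
                f"(got {n_left} left, {n_right} right); falling back to symmetric",
                stacklevel=2,
            )
            mode = "symmetric"
    if int(cis.sum()) < min_side:
        raise ValueError(f"need >= {min_side} cis fragments to fit the decay trend")

    dv = d[cis].to_numpy()
    x = np.log10(np.maximum(np.abs(dv), 1.0))
    fit = DecayFit(mode=mode, samples=list(v_matrix.columns), lam=lam)
    fitted = pd.DataFrame(np.nan, index=v_matrix.index, columns=v_matrix.columns)
    for sample in v_matrix.columns:
        y = v_matrix.loc[cis, sample].to_numpy()
        if mode == "symmetric":
            fit.sides[sample] = {"both": _fit_side(x, y, lam)}
        else:
            fit.sides[sample] = {
                "left": _fit_side(x[dv < 0], y[dv < 0], lam),
                "right": _fit_side(x[dv > 0], y[dv > 0], lam),
            }
        fitted.loc[cis, sample] = fit.evaluate(sample, dv)
        fitted.loc[d.isna(), sample] = fit.plateau(sample)
    fit.fitted = fitted
    return fit


def residual_matrix(v_matrix: pd.DataFrame, fit: DecayFit, d: pd.Series) -> pd.DataFrame:
    """Residuals r_ij = v(k_ij) - f_j(d_i).

    Trans fragments (NaN distance) are compared against the per-sample
    plateau, i.e. the fitted background level at the largest distance.
    """
    d = d.reindex(v_matrix.index)
    cis = d.notna() & (d != 0)
    resid = pd.DataFrame(np.nan, index=v_matrix.index, columns=v_matrix.columns)
    for sample in v_matrix.columns:
        if cis.any():
            resid.loc[cis, sample] = (
                v_matrix.loc[cis, sample].to_numpy()
                - fit.evaluate(sample, d[cis].to_numpy())
            )
        trans = d.isna()
        if trans.any():
            resid.loc[trans, sample] = v_matrix.loc[trans, sample] - fit.plateau(sample)
    return resid


def export_fit_grid(fit: DecayFit, d_min: float, d_max: float, n: int = 200) -> pd.DataFrame:
    """Tabulate the fitted curves on a log-spaced distance grid (both signs)."""
    grid = np.geomspace(max(d_min, 1.0), d_max, n)
    rows = []
    for sample in fit.samples:
        for sign in (-1, 1):
            vals = fit.evaluate(sample, sign * grid)
            for dd, vv in zip(sign * grid, vals):
                rows.append((sample, dd, vv))
    return pd.DataFrame(rows, columns=["sample", "distance", "fitted"])
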