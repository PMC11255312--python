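"""Continuous two-segment least-squares fitting and linear-vs-segmented
model selection.

The estimator profiles the residual sum of squares over a candidate
breakpoint grid (the remaining coefficients solved exactly by least squares
at each candidate) and refines the grid minimizer by golden-section search.
This is global and derivative-free; no iterative relinearization.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, stats as sps


@dataclass(frozen=True)
class SegmentedFit:
    breakpoint: float
    intercept: float
    left_slope: float
    slope_change: float  # right slope minus left slope
    rss_segmented: float
    rss_linear: float
    n: int
    statistic: float | None = None
    p_value: float | None = None
    delta_bic: float | None = None
    chosen_model: str | None = None

    @property
    def right_slope(self) -> float:
        return self.left_slope + self.slope_change


def _profile_rss(x: np.ndarray, y: np.ndarray, psis: np.ndarray) -> np.ndarray:
    """RSS of y ~ 1 + x + max(0, x - psi) for each candidate psi (batched)."""
    hinge = np.maximum(0.0, x[None, :] - psis[:, None])  # (P, n)
    ones = np.ones_like(x)
    # design per psi: columns [1, x, hinge]; solve 3x3 normal equations
    A = np.empty((len(psis), 3, 3))
    b = np.empty((len(psis), 3))
    cols = [ones, x]
    for i, ci in enumerate(cols):
        for j, cj in enumerate(cols):
            A[:, i, j] = ci @ cj
        A[:, i, 2] = hinge @ ci
        A[:, 2, i] = A[:, i, 2]
        b[:, i] = ci @ y
    A[:, 2, 2] = np.einsum("pn,pn->p", hinge, hinge)
    b[:, 2] = hinge @ y
    yy = y @ y
    rss = np.empty(len(psis))
    for i in range(len(psis)):
        beta, *_ = np.linalg.lstsq(A[i], b[i], rcond=None)
        rss[i] = yy - beta @ b[i]
    return np.maximum(rss, 0.0)


def _rss_at(x: np.ndarray, y: np.ndarray, psi: float) -> float:
    return float(_profile_rss(x, y, np.array([psi]))[0])


def _coeffs_at(x: np.ndarray, y: np.ndarray, psi: float) -> np.ndarray:
    X = np.column_stack([np.ones_like(x), x, np.maximum(0.0, x - psi)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta


def fit_segmented(x, y, grid_points: int = 201) -> SegmentedFit:
    """Fit y = b0 + b1*x + b2*max(0, x - psi); psi by profiled-RSS grid
    search over [2nd smallest, 2nd largest] distinct x, then golden-section
    refinement between the grid minimizer's neighbors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be aligned")
    n = len(x)
    if n < 6:
        raise ValueError(f"need >= 6 points, got {n}")
    distinct = np.unique(x)
    if len(distinct) < 4:
        raise ValueError("need >= 4 distinct x values")
    lo, hi = distinct[1], distinct[-2]
    psis = np.linspace(lo, hi, grid_points)
    rss = _profile_rss(x, y, psis)
    k = int(np.argmin(rss))
    a = psis[max(k - 1, 0)]
    b = psis[min(k + 1, len(psis) - 1)]
    if b > a:
        res = optimize.minimize_scalar(
            lambda p: _rss_at(x, y, p), bounds=(a, b), method="bounded",
            options={"xatol": 1e-8},
        )
        psi_hat = float(res.x)
        rss_hat = float(res.fun)
        if rss[k] < rss_hat:  # refinement must never lose to the grid
            psi_hat, rss_hat = float(psis[k]), float(rss[k])
    else:
        psi_hat, rss_hat = float(psis[k]), float(rss[k])

    beta = _coeffs_at(x, y, psi_hat)
    lin = np.polynomial.polynomial.polyfit(x, y, 1)
    resid = y - (lin[0] + lin[1] * x)
    rss_linear = float(resid @ resid)
    return SegmentedFit(
        breakpoint=psi_hat,
        intercept=float(beta[0]),
        left_slope=float(beta[1]),
        slope_change=float(beta[2]),
        rss_segmented=rss_hat,
        rss_linear=rss_linear,
        n=n,
    )


def select_model(
    fit: SegmentedFit, alpha: float = 0.05, criterion: str = "f_test"
) -> SegmentedFit:
    """Compare segmented (4 params incl. psi) vs linear (2 params).

    f_test: F = ((rss_lin - rss_seg)/2) / (rss_seg/(n-4)), p from F(2, n-4).
    The breakpoint is estimated from the same data, so the test is
    anti-conservative; treat p as a heuristic screen.
    """
    n = fit.n
    if n <= 4:
        raise ValueError(f"model selection needs n > 4, got n={n}")
    rss_seg = max(fit.rss_segmented, 0.0)
    rss_lin = max(fit.rss_linear, rss_seg)
    if criterion == "f_test":
        if rss_seg == 0:
            stat, p = np.inf, 0.0
        else:
            stat = ((rss_lin - rss_seg) / 2.0) / (rss_seg / (n - 4))
            p = float(sps.f.sf(stat, 2, n - 4))
        chosen = "segmented" if p < alpha else "linear"
        return replace(fit, statistic=float(stat), p_value=p,
                       chosen_model=chosen)
    if criterion == "bic":
        def bic(rss, k):
            if rss <= 0:
                return -np.inf
            return n * np.log(rss / n) + k * np.log(n)
        d = bic(fit.rss_linear, 2) - bic(rss_seg, 4)
        chosen = "segmented" if d > 0 else "linear"
        return replace(fit, delta_bic=float(d), chosen_model=chosen)
    raise ValueError(f"unknown criterion: {criterion}")
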