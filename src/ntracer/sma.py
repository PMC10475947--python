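"""Standardized major axis (SMA) line fitting and between-group comparison.

SMA (reduced major axis) fits a symmetric bivariate line: the slope is
sign(r)·sd(y)/sd(x) and the line passes through the centroid.  It is the
standard choice for allometric scaling relationships where neither variable
is a predictor of the other.

Group comparison follows the standard SMA inference methodology:

1. *Common slope* — a likelihood-ratio test built on the correlation between
   the residual axis (y − Bx) and the fitted axis (y + Bx) within each
   group; at a group's own SMA slope this correlation is exactly zero, so
   the statistic is −Σᵢ wᵢ·ln(1 − r²ᵢ(B̂)) minimized over the common slope
   B̂, asymptotically χ² with g − 1 degrees of freedom.  Weights use the
   small-sample correction wᵢ = nᵢ − 5/2.
2. *Elevation* — if slopes are homogeneous, a Wald test on the group
   intercepts at the common slope.
3. *Shift* — a Wald test on group means of the fitted-axis scores y + B̂x,
   i.e. displacement of the groups along the common line.

Elevation and shift are only meaningful when the common-slope test does not
reject; the comparison object enforces that gate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy import stats as sps

__all__ = ["SmaFit", "SmaComparison", "sma_fit", "common_slope", "sma_compare"]


@dataclass
class SmaFit:
    """A fitted SMA line for one group."""

    slope: float
    intercept: float
    r2: float
    n: int
    label: str = ""
    fitted_scores: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)

    @property
    def significant(self) -> bool:
        """Correlation test of the underlying association (H0: r = 0)."""
        return self.correlation_p < 0.05

    @property
    def correlation_p(self) -> float:
        r = np.sqrt(self.r2)
        if self.n < 3 or r >= 1.0:
            return 0.0 if r >= 1.0 else 1.0
        t = r * np.sqrt((self.n - 2) / (1 - self.r2))
        return float(2 * sps.t.sf(abs(t), self.n - 2))


@dataclass
class SmaComparison:
    """Common-slope, elevation and shift inference across groups."""

    slopes: dict
    common_slope_stat: float
    common_slope_df: int
    common_slope_p: float
    common_slope_estimate: float
    alpha: float = 0.05
    elevation_stat: float | None = None
    elevation_p: float | None = None
    shift_stat: float | None = None
    shift_p: float | None = None
    intercepts_at_common: dict | None = None

    @property
    def slopes_homogeneous(self) -> bool:
        return self.common_slope_p >= self.alpha


def _moments(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float, float]:
    return (
        float(np.mean(x)),
        float(np.mean(y)),
        float(np.var(x, ddof=1)),
        float(np.var(y, ddof=1)),
        float(np.cov(x, y, ddof=1)[0, 1]),
    )


def sma_fit(x, y, label: str = "") -> SmaFit:
    """Fit an SMA line: slope = sign(r)·sd(y)/sd(x), through the centroid."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("SMA needs n >= 3")
    xbar, ybar, sx2, sy2, sxy = _moments(x, y)
    if sx2 <= 0 or sy2 <= 0:
        raise ValueError("SMA requires positive variance in both x and y")
    r = sxy / np.sqrt(sx2 * sy2)
    slope = np.copysign(np.sqrt(sy2 / sx2), r if r != 0 else 1.0)
    intercept = ybar - slope * xbar
    return SmaFit(
        slope=float(slope),
        intercept=float(intercept),
        r2=float(r**2),
        n=len(x),
        label=label,
        fitted_scores=y + slope * x,
    )


def _res_fit_corr2(b: float, sx2: float, sy2: float, sxy: float) -> float:
    """Squared correlation between residual (y−bx) and fitted (y+bx) axes."""
    num = (sy2 - b * b * sx2) ** 2
    den = (sy2 - 2 * b * sxy + b * b * sx2) * (sy2 + 2 * b * sxy + b * b * sx2)
    if den <= 0:
        return 1.0
    return min(num / den, 1.0 - 1e-15)


def common_slope(groups: dict) -> tuple[float, float]:
    """Estimate the common SMA slope across groups and the LR statistic at it.

    Returns ``(b_hat, lr_stat)`` where ``lr_stat = −Σ (nᵢ − 2.5)·ln(1 − r²ᵢ(b̂))``.
    """
    moments = []
    slopes = []
    signs = 0.0
    for lab, (x, y) in groups.items():
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        xbar, ybar, sx2, sy2, sxy = _moments(x, y)
        n = len(x)
        moments.append((n, sx2, sy2, sxy))
        slopes.append(np.sqrt(sy2 / sx2))
        signs += n * sxy / np.sqrt(sx2 * sy2)
    sign = 1.0 if signs >= 0 else -1.0

    def objective(log_b: float) -> float:
        b = sign * np.exp(log_b)
        return -sum((n - 2.5) * np.log(1.0 - _res_fit_corr2(b, sx2, sy2, sxy))
                    for n, sx2, sy2, sxy in moments)

    lo = np.log(min(slopes)) - 3.0
    hi = np.log(max(slopes)) + 3.0
    res = optimize.minimize_scalar(objective, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-10})
    return float(sign * np.exp(res.x)), float(res.fun)


def _slope_variance(fit_moments: tuple[int, float, float, float], b: float) -> float:
    """Approximate sampling variance of a group's SMA slope, b²(1−r²)/(n−2)."""
    n, sx2, sy2, sxy = fit_moments
    r2 = sxy**2 / (sx2 * sy2)
    return b * b * (1.0 - r2) / max(n - 2, 1)


def sma_compare(groups: dict, alpha: float = 0.05) -> SmaComparison:
    """Compare SMA lines across ≥ 2 groups: common slope, then elevation and shift.

    Parameters
    ----------
    groups : dict
        ``{label: (x, y)}``, each group meeting the :func:`sma_fit`
        preconditions.
    alpha : float
        Significance level gating the elevation/shift stage.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    fits = {lab: sma_fit(x, y, label=str(lab)) for lab, (x, y) in groups.items()}

    b_hat, lr = common_slope(groups)
    df = len(groups) - 1
    p_slope = float(sps.chi2.sf(lr, df))
    comp = SmaComparison(
        slopes={lab: f.slope for lab, f in fits.items()},
        common_slope_stat=lr,
        common_slope_df=df,
        common_slope_p=p_slope,
        common_slope_estimate=b_hat,
        alpha=alpha,
    )
    if p_slope < alpha:
        return comp  # heterogeneous slopes: elevation/shift not reported

    # Elevation: Wald on intercepts at the common slope.
    var_b = 1.0 / sum(
        1.0 / _slope_variance((len(np.asarray(x)), *_moments(np.asarray(x, float), np.asarray(y, float))[2:]), b_hat)
        for x, y in groups.values()
    )
    a_vals, a_vars = [], []
    s_means, s_vars = [], []
    for x, y in groups.values():
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        n = len(x)
        resid = y - b_hat * x
        scores = y + b_hat * x
        a_vals.append(float(np.mean(resid)))
        a_vars.append(float(np.var(resid, ddof=1)) / n + float(np.mean(x)) ** 2 * var_b)
        s_means.append(float(np.mean(scores)))
        s_vars.append(float(np.var(scores, ddof=1)) / n)

    def wald(means: list[float], variances: list[float]) -> tuple[float, float]:
        w = 1.0 / np.asarray(variances)
        m = np.asarray(means)
        grand = float(np.sum(w * m) / np.sum(w))
        stat = float(np.sum(w * (m - grand) ** 2))
        return stat, float(sps.chi2.sf(stat, df))

    comp.elevation_stat, comp.elevation_p = wald(a_vals, a_vars)
    comp.shift_stat, comp.shift_p = wald(s_means, s_vars)
    comp.intercepts_at_common = dict(zip(groups.keys(), a_vals))
    return comp
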