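"""Decay-model fits, flat-line tests, capsule-restricted slope comparison,
and the iterative Grubbs outlier screen.

Fits are unweighted by default (band-area weighting is available and logged
when enabled elsewhere). The slope comparison uses a pooled ordinary
least-squares model with a group indicator and a group x distance interaction,
so the reported p-value has a single, stated number of degrees of freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import optimize
from scipy import stats as sps

logger = logging.getLogger(__name__)


class FitError(RuntimeError):
    """Raised when a regression cannot be run or did not converge."""


@dataclass
class DecayFit:
    """A fitted radial model: density = A·exp(−λ·d) or density = a + b·d."""

    model: str  # "exponential" | "linear"
    params: dict[str, float]
    se: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    df_resid: int
    p_slope_zero: float | None
    rss: float
    r_squared: float
    n_points: int
    converged: bool = True
    boundary_flat: bool = False  # exponential degenerated to λ ≈ 0
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "params": self.params,
            "se": self.se,
            "ci95": {k: list(v) for k, v in self.ci95.items()},
            "df_resid": self.df_resid,
            "p_slope_zero": self.p_slope_zero,
            "rss": self.rss,
            "r_squared": self.r_squared,
            "n_points": self.n_points,
            "converged": self.converged,
            "boundary_flat": self.boundary_flat,
            "notes": self.notes,
        }


@dataclass
class SlopeComparison:
    """Two-group comparison of log-linear slopes over a common fit range."""

    slope_a: float
    slope_b: float
    se_a: float
    se_b: float
    delta: float  # slope_a − slope_b from the interaction term
    se_delta: float
    t_stat: float
    df: int
    p_interaction: float
    fit_range_um: tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "slope_a": self.slope_a,
            "slope_b": self.slope_b,
            "se_a": self.se_a,
            "se_b": self.se_b,
            "delta": self.delta,
            "se_delta": self.se_delta,
            "t_stat": self.t_stat,
            "df": self.df,
            "p_interaction": self.p_interaction,
            "fit_range_um": list(self.fit_range_um),
        }


@dataclass
class GrubbsIteration:
    index: int
    value: float
    statistic: float
    critical: float
    removed: bool


@dataclass
class GrubbsResult:
    iterations: list[GrubbsIteration]
    removed_indices: list[int]
    retained_indices: list[int]
    alpha: float
    notice: str | None = None


def _as_points(d, y) -> tuple[np.ndarray, np.ndarray]:
    d = np.asarray(d, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(d) | np.isnan(y))
    return d[keep], y[keep]


def fit_linear(d, y) -> DecayFit:
    """Ordinary least squares ``y = a + b·d`` with the flat-line test on b."""
    d, y = _as_points(d, y)
    if len(d) < 3:
        raise FitError(f"linear fit needs at least 3 points, got {len(d)}")
    if np.ptp(d) == 0:
        raise FitError("zero variance in distance values")
    X = sm.add_constant(d)
    res = sm.OLS(y, X).fit()
    a, b = res.params
    conf = res.conf_int(alpha=0.05)
    return DecayFit(
        model="linear",
        params={"a": float(a), "b": float(b)},
        se={"a": float(res.bse[0]), "b": float(res.bse[1])},
        ci95={
            "a": (float(conf[0][0]), float(conf[0][1])),
            "b": (float(conf[1][0]), float(conf[1][1])),
        },
        df_resid=int(res.df_resid),
        p_slope_zero=float(res.pvalues[1]),
        rss=float(res.ssr),
        r_squared=float(res.rsquared),
        n_points=len(d),
    )


def _loglinear_init(d: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    pos = y > 0
    if pos.sum() >= 2 and np.ptp(d[pos]) > 0:
        slope, intercept = np.polyfit(d[pos], np.log(y[pos]), 1)
        return float(np.exp(intercept)), float(max(-slope, 0.0))
    return float(max(y.mean(), 1e-12)), 0.0


def fit_exponential_decay(d, y) -> DecayFit:
    """Nonlinear least squares of ``density = A·exp(−λ·d)``.

    Initialized from the log-linear fit of the positive densities.
    Non-convergence raises :class:`FitError`; a fit with λ at (numerical)
    zero is flagged as a boundary fit degenerate with a flat line.
    """
    d, y = _as_points(d, y)
    if len(d) < 3:
        raise FitError(f"exponential fit needs at least 3 points, got {len(d)}")
    a0, lam0 = _loglinear_init(d, y)

    def model(dd, amp, lam):
        return amp * np.exp(-lam * dd)

    try:
        popt, pcov = optimize.curve_fit(
            model, d, y, p0=[a0, lam0], maxfev=20000
        )
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        raise FitError(f"exponential fit did not converge: {exc}") from exc
    amp, lam = (float(v) for v in popt)
    resid = y - model(d, amp, lam)
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    df_resid = len(d) - 2
    with np.errstate(invalid="ignore"):
        perr = np.sqrt(np.diag(pcov))
    tcrit = float(sps.t.ppf(0.975, df_resid)) if df_resid >= 1 else np.nan
    ci = {
        "A": (amp - tcrit * perr[0], amp + tcrit * perr[0]),
        "lambda": (lam - tcrit * perr[1], lam + tcrit * perr[1]),
    }
    if np.isfinite(perr[1]) and perr[1] > 0 and df_resid >= 1:
        t_lam = lam / perr[1]
        p_lam = float(2 * sps.t.sf(abs(t_lam), df_resid))
    else:
        p_lam = None
    boundary = abs(lam) < 1e-10
    notes = ["lambda at flat boundary"] if boundary else []
    return DecayFit(
        model="exponential",
        params={"A": amp, "lambda": lam},
        se={"A": float(perr[0]), "lambda": float(perr[1])},
        ci95={k: (float(lo), float(hi)) for k, (lo, hi) in ci.items()},
        df_resid=df_resid,
        p_slope_zero=p_lam,
        rss=rss,
        r_squared=1.0 - rss / tss if tss > 0 else 1.0,
        n_points=len(d),
        boundary_flat=boundary,
        notes=notes,
    )


def log_transform_profile(
    d, y, band_edges_um, max_range_um: float
) -> tuple[np.ndarray, np.ndarray, int]:
    """Restrict to bands wholly inside ``[0, max_range_um)`` and take ln(density).

    Zero or absent densities are excluded (count returned and logged); an
    all-zero restriction is an error.
    """
    if max_range_um <= 0:
        raise ValueError("max_range_um must be positive")
    d = np.asarray(d, dtype=float)
    y = np.asarray(y, dtype=float)
    edges = np.asarray(band_edges_um, dtype=float)
    lo, hi = edges[:-1], edges[1:]
    # a point is kept when the band containing it lies wholly inside [0, range)
    contains = (d[:, None] >= lo[None, :]) & (d[:, None] < hi[None, :])
    band_of = np.where(contains.any(axis=1), contains.argmax(axis=1), -1)
    in_range = (band_of >= 0) & (hi[np.clip(band_of, 0, None)] <= max_range_um)
    d_r, y_r = d[in_range], y[in_range]
    positive = np.nan_to_num(y_r, nan=0.0) > 0
    n_dropped = int((~positive).sum())
    if n_dropped:
        logger.info(
            "log_transform_profile: dropped %d zero/absent-density band point(s)",
            n_dropped,
        )
    if not positive.any():
        raise FitError("all densities are zero/absent inside the fit range")
    return d_r[positive], np.log(y_r[positive]), n_dropped


def compare_slopes(
    d_a, y_a, d_b, y_b, fit_range_um: tuple[float, float] = (0.0, 250.0)
) -> SlopeComparison:
    """Pooled OLS with group indicator, distance, and group×distance interaction.

    Inputs are (distance, transformed density) points per group; the reported
    p-value is that of the interaction term (difference of slopes).
    """
    d_a, y_a = _as_points(d_a, y_a)
    d_b, y_b = _as_points(d_b, y_b)
    if len(d_a) < 3 or len(d_b) < 3:
        raise FitError("each group needs at least 3 points for the slope comparison")
    d = np.concatenate([d_a, d_b])
    y = np.concatenate([y_a, y_b])
    g = np.concatenate([np.zeros(len(d_a)), np.ones(len(d_b))])
    X = np.column_stack([np.ones_like(d), d, g, d * g])
    res = sm.OLS(y, X).fit()
    slope_a = float(res.params[1])
    delta_b_minus_a = float(res.params[3])
    slope_b = slope_a + delta_b_minus_a
    # per-group slopes/SEs from separate fits (identical point estimates)
    res_a = sm.OLS(y_a, sm.add_constant(d_a)).fit()
    res_b = sm.OLS(y_b, sm.add_constant(d_b)).fit()
    return SlopeComparison(
        slope_a=slope_a,
        slope_b=slope_b,
        se_a=float(res_a.bse[1]),
        se_b=float(res_b.bse[1]),
        delta=float(-delta_b_minus_a),  # slope_a − slope_b
        se_delta=float(res.bse[3]),
        t_stat=float(res.tvalues[3]),
        df=int(res.df_resid),
        p_interaction=float(res.pvalues[3]),
        fit_range_um=(float(fit_range_um[0]), float(fit_range_um[1])),
    )


def grubbs_critical_value(alpha: float, n: int) -> float:
    """Two-sided Grubbs critical value G_crit(α, N)."""
    t = sps.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return float((n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2)))


def grubbs_screen(values, alpha: float = 0.05) -> GrubbsResult:
    """Iterative two-sided Grubbs outlier screen.

    While ``G = max|xᵢ − x̄| / s`` exceeds the critical value, the extreme
    point is removed and the test repeated on the remainder; removal stops the
    first time G ≤ G_crit or fewer than 3 points remain. Zero sample SD means
    no outlier is declarable (empty removal set with a notice).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("Grubbs screen needs at least 3 values")
    if not 0.0 < alpha < 0.5:
        raise ValueError("alpha must lie in (0, 0.5)")
    active = list(range(x.size))
    iterations: list[GrubbsIteration] = []
    removed: list[int] = []
    notice = None
    while len(active) >= 3:
        sub = x[active]
        s = sub.std(ddof=1)
        if s == 0:
            notice = "zero sample SD; no outlier declarable"
            break
        dev = np.abs(sub - sub.mean())
        j = int(np.argmax(dev))
        g = float(dev[j] / s)
        crit = grubbs_critical_value(alpha, len(sub))
        hit = g > crit
        iterations.append(
            GrubbsIteration(
                index=active[j],
                value=float(sub[j]),
                statistic=g,
                critical=crit,
                removed=hit,
            )
        )
        if not hit:
            break
        removed.append(active.pop(j))
    return GrubbsResult(
        iterations=iterations,
        removed_indices=removed,
        retained_indices=active,
        alpha=alpha,
        notice=notice,
    )
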