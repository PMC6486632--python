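"""Mechanism-discrimination diagnostics from double-reciprocal replots.

The inference chain mirrors the classical graphical analysis of inhibition
kinetics, made quantitative:

1. points beyond the substrate-inhibition optimum ``S* = sqrt(Km·KiTHF)``
   are excluded, using the per-series substrate-inhibition fit;
2. each inhibitor series is transformed to double-reciprocal
   (Lineweaver–Burk) coordinates and fitted with a straight line, giving a
   slope (Km_app/Vmax) and intercept (1/Vmax) per inhibitor level;
3. the slopes and intercepts are replotted against inhibitor
   concentration;
4. the slope replot is tested linear vs saturating-hyperbolic and the
   intercept replot flat vs linear, each by AICc *and* an
   extra-sum-of-squares F-test (both must agree, guarding against
   noise-driven calls), and the shape pair maps to a mechanism:

   ========================  =================  ====================
   slope replot              intercept replot   mechanism
   ========================  =================  ====================
   hyperbolic (saturating)   flat               hyperbolic_competitive
   linear                    flat               pure_competitive
   linear                    linear             pure_mixed
   anything else             —                  indeterminate
   ========================  =================  ====================

A saturating slope replot implies a finite apparent Km at infinite
inhibitor, hence a nonzero limiting velocity — the fingerprint of partial
(hyperbolic) competitive inhibition, where the ternary
enzyme–substrate–inhibitor complex still turns over.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

from .data import VelocitySeries
from .errors import DiagnosticError, DomainError
from .fitting import FitResult, fit_saturation

__all__ = [
    "ReciprocalFit",
    "MechanismCall",
    "exclude_substrate_inhibition",
    "double_reciprocal",
    "replot",
    "classify_mechanism",
    "diagnose_series",
]

logger = logging.getLogger(__name__)


@dataclass
class ReciprocalFit:
    """Straight-line fit of 1/v vs 1/[S] for one inhibitor level.

    Standard errors are carried along because reciprocal-space noise is
    strongly heteroscedastic across inhibitor levels (Var(1/v) scales with
    (1/v)²); the replot shape tests weight by them.
    """

    inhibitor_conc: float
    slope: float        # Km_app/Vmax in reciprocal space
    intercept: float    # 1/Vmax
    r_squared: float
    n_points: int
    slope_se: float = math.nan
    intercept_se: float = math.nan


@dataclass
class MechanismCall:
    """Outcome of the replot shape classification."""

    label: str                    # pure_competitive | pure_mixed | hyperbolic_competitive | indeterminate
    slope_shape: str              # linear | hyperbolic | indeterminate
    intercept_shape: str          # flat | linear | indeterminate
    limiting_velocity: float      # asymptotic v at S = uninhibited apparent Km (model units)
    limiting_velocity_se: float
    limiting_excludes_zero: bool
    stats: dict = field(default_factory=dict)
    reason: str = ""


def exclude_substrate_inhibition(series: VelocitySeries, eq3_fit: FitResult) -> VelocitySeries:
    """Drop points beyond the substrate-inhibition optimum.

    The optimum ``S* = sqrt(Km·KiTHF)`` of the substrate-inhibited rate law
    is the natural changepoint between the rising (informative for Km) and
    declining portions of the curve; points with S > S* are removed. A fit
    without ``ki_thf`` leaves the series unchanged.
    """
    if not eq3_fit.converged:
        raise DiagnosticError("substrate-inhibition fit did not converge")
    ki_thf = eq3_fit.params.get("ki_thf")
    if ki_thf is None:
        return series
    s_star = math.sqrt(eq3_fit.params["km"] * ki_thf)
    mask = series.substrate_conc <= s_star
    kept = series.subset(mask)
    if kept.n_substrate_levels < 3:
        raise DiagnosticError(
            f"fewer than 3 substrate levels survive exclusion at S*={s_star:.3g}")
    if kept.n_substrate_levels < series.n_substrate_levels / 2:
        logger.warning(
            "exclusion at S*=%.3g removed more than half the substrate grid; "
            "Km identifiability may suffer", s_star)
    return kept


def double_reciprocal(series_set: list[VelocitySeries]) -> list[ReciprocalFit]:
    """Per-inhibitor straight-line fits of 1/v vs 1/[S].

    Replicates are averaged per (inhibitor, substrate) cell before
    transformation; zero/negative velocities and zero substrate points are
    dropped with a logged warning. For noiseless Michaelis–Menten input
    the slope is exactly Km/Vmax and the intercept 1/Vmax.
    """
    fits = []
    for ser in series_set:
        avg = ser.averaged()
        good = (avg.velocity > 0) & (avg.substrate_conc > 0)
        n_bad = int((~good).sum())
        if n_bad:
            logger.warning("dropping %d non-positive point(s) from series I=%g",
                           n_bad, ser.inhibitor_conc)
        s, v = avg.substrate_conc[good], avg.velocity[good]
        if len(s) < 3:
            raise DiagnosticError(
                f"series at I={ser.inhibitor_conc} has fewer than 3 usable points")
        x, y = 1.0 / s, 1.0 / v
        lr = stats.linregress(x, y)
        fits.append(ReciprocalFit(
            inhibitor_conc=ser.inhibitor_conc, slope=float(lr.slope),
            intercept=float(lr.intercept), r_squared=float(lr.rvalue ** 2),
            n_points=len(s), slope_se=float(lr.stderr),
            intercept_se=float(lr.intercept_stderr)))
    return fits


def replot(fits: list[ReciprocalFit]) -> pd.DataFrame:
    """Slope and intercept vs inhibitor concentration, sorted by inhibitor.

    Duplicate inhibitor levels are merged (mean) with a logged note.
    """
    if len(fits) < 3:
        raise DiagnosticError("replot needs >= 3 inhibitor levels")
    df = pd.DataFrame({
        "inhibitor_conc": [f.inhibitor_conc for f in fits],
        "slope": [f.slope for f in fits],
        "intercept": [f.intercept for f in fits],
        "slope_se": [f.slope_se for f in fits],
        "intercept_se": [f.intercept_se for f in fits],
    })
    if df["inhibitor_conc"].duplicated().any():
        logger.info("duplicate inhibitor levels merged in replot")
        df = df.groupby("inhibitor_conc", as_index=False).mean()
    return df.sort_values("inhibitor_conc", ignore_index=True)


def diagnose_series(series_set: list[VelocitySeries],
                    exclude: bool = True) -> MechanismCall:
    """Full inference chain: exclusion -> double reciprocal -> replot ->
    mechanism classification.

    When ``exclude`` is set, the substrate-inhibition cutoff S* comes from
    the lowest-inhibitor series and is applied to every series, so all
    reciprocal lines share one substrate grid. (Per-series cutoffs drift
    upward with inhibitor — the apparent Km rises — which would leave
    different grids per series and imprint a spurious trend on the
    intercept replot.)
    """
    if exclude:
        base = min(series_set, key=lambda ser: ser.inhibitor_conc)
        eq3_fit = fit_saturation(base, model="eq3")
        series_set = [exclude_substrate_inhibition(ser, eq3_fit) for ser in series_set]
    return classify_mechanism(replot(double_reciprocal(series_set)))


def _weights(se: np.ndarray, n: int) -> np.ndarray:
    """Inverse-variance weights from propagated standard errors, scaled to
    mean 1; uniform when SEs are missing, zero or non-finite (e.g.
    noiseless input)."""
    if se is None:
        return np.ones(n)
    se = np.asarray(se, dtype=float)
    if not np.all(np.isfinite(se)) or np.any(se <= 0):
        return np.ones(n)
    w = 1.0 / se ** 2
    return w * (n / w.sum())


def _fit_line(x, y, w):
    sw = np.sqrt(w)
    A = np.column_stack([sw, sw * x])
    coef, *_ = np.linalg.lstsq(A, sw * y, rcond=None)
    rss = float(np.sum(w * (y - (coef[0] + coef[1] * x)) ** 2))
    return {"params": (float(coef[0]), float(coef[1])), "rss": rss, "k": 2}


def _fit_const(y, w):
    mu = float(np.average(y, weights=w))
    return {"params": (mu,), "rss": float(np.sum(w * (y - mu) ** 2)), "k": 1}


def _fit_hyperbola(x, y, w):
    """Saturating hyperbola y = y0 + (y_inf - y0)·x/(K + x), positive
    parameters enforced through log space; weighted residuals."""
    sw = np.sqrt(w)
    y0_init = max(y[np.argmin(x)], 1e-12)
    d_init = max(y.max() - y0_init, 1e-6 * y0_init)
    k_init = max(np.median(x[x > 0]), 1e-12)
    best = None
    for k_mult in (0.3, 1.0, 3.0):  # small deterministic multistart
        x0 = np.log([y0_init, d_init, k_init * k_mult])

        def resid(t):
            y0, d, k = np.exp(t)
            return sw * (y0 + d * x / (k + x) - y)

        sol = least_squares(resid, x0, method="lm", xtol=1e-14, ftol=1e-14,
                            max_nfev=10000)
        rss = float(sol.fun @ sol.fun)
        if best is None or rss < best["rss"]:
            y0, d, k = np.exp(sol.x)
            # delta-method SE of the asymptote y_inf = y0 + d
            se_inf = math.nan
            if len(x) > 3:
                s2 = rss / (len(x) - 3)
                try:
                    cov = s2 * np.linalg.inv(sol.jac.T @ sol.jac)
                    g = np.array([y0, d, 0.0])  # d y_inf / d log params
                    se_inf = float(np.sqrt(max(g @ cov @ g, 0.0)))
                except np.linalg.LinAlgError:
                    pass
            best = {"params": (float(y0), float(y0 + d), float(k)), "rss": rss,
                    "k": 3, "se_asymptote": se_inf}
    return best


def _aicc(n, rss, k):
    # k counts regression parameters only: replots have as few as 4-6
    # points, where adding the error variance to k makes the small-sample
    # correction degenerate (n - k - 1 <= 1) and the richer shape could
    # never be selected regardless of fit quality.
    if rss <= 0:
        return -math.inf
    if n - k - 1 <= 0:
        return math.inf
    return n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def _extra_ss_f(n, rss_red, rss_full, k_red, k_full):
    df1, df2 = k_full - k_red, n - k_full
    if df2 <= 0 or rss_full <= 0:
        return 0.0, 1.0
    num = (rss_red - rss_full) / df1
    den = rss_full / df2
    if num <= 0:
        return 0.0, 1.0
    f = num / den
    return f, float(stats.f.sf(f, df1, df2))


def classify_mechanism(replot_df: pd.DataFrame, alpha_level: float = 0.05) -> MechanismCall:
    """Classify the inhibition mechanism from slope/intercept replots.

    Requires >= 4 inhibitor levels (3-parameter hyperbola needs them);
    fewer yields ``indeterminate`` with a reason. A shape call is made only
    when AICc (margin > 2) and the F-test (p < ``alpha_level``) agree;
    otherwise the simpler shape is retained. An intercept "linear" call
    additionally requires a materially large trend (see inline note).
    """
    x = replot_df["inhibitor_conc"].to_numpy(dtype=float)
    n = len(x)
    if n < 4:
        return MechanismCall(
            label="indeterminate", slope_shape="indeterminate",
            intercept_shape="indeterminate", limiting_velocity=math.nan,
            limiting_velocity_se=math.nan, limiting_excludes_zero=False,
            reason=f"only {n} inhibitor levels; >= 4 required for shape testing")

    slope = replot_df["slope"].to_numpy(dtype=float)
    inter = replot_df["intercept"].to_numpy(dtype=float)
    w_slope = _weights(replot_df.get("slope_se"), n)
    w_inter = _weights(replot_df.get("intercept_se"), n)

    # slope replot: linear vs saturating hyperbola
    lin = _fit_line(x, slope, w_slope)
    hyp = _fit_hyperbola(x, slope, w_slope)
    d_aicc_slope = _aicc(n, lin["rss"], lin["k"]) - _aicc(n, hyp["rss"], hyp["k"])
    f_slope, p_slope = _extra_ss_f(n, lin["rss"], hyp["rss"], lin["k"], hyp["k"])
    slope_shape = "hyperbolic" if (d_aicc_slope > 2 and p_slope < alpha_level) else "linear"

    # intercept replot: flat vs linear. Besides the statistical agreement
    # rule, a "linear" call must be practically large: the fitted change
    # across the observed inhibitor range must exceed 20% of the mean
    # intercept. A real mixed mechanism moves 1/Vmax several-fold, while
    # reciprocal-space noise trends (heteroscedastic: Var(1/v) grows with
    # inhibitor at low substrate) stay at the few-percent level.
    const = _fit_const(inter, w_inter)
    ilin = _fit_line(x, inter, w_inter)
    d_aicc_int = _aicc(n, const["rss"], const["k"]) - _aicc(n, ilin["rss"], ilin["k"])
    f_int, p_int = _extra_ss_f(n, const["rss"], ilin["rss"], const["k"], ilin["k"])
    int_change = abs(ilin["params"][1]) * (x.max() - x.min())
    int_material = int_change > 0.2 * abs(const["params"][0])
    intercept_shape = ("linear"
                       if (d_aicc_int > 2 and p_int < alpha_level and int_material)
                       else "flat")

    table = {
        ("hyperbolic", "flat"): "hyperbolic_competitive",
        ("linear", "flat"): "pure_competitive",
        ("linear", "linear"): "pure_mixed",
    }
    label = table.get((slope_shape, intercept_shape), "indeterminate")

    # limiting velocity at S = uninhibited apparent Km, as I -> infinity:
    # 1/v = slope_inf/S + intercept; with S = slope(0)/intercept this is
    # v_inf = 1/(intercept_mean + slope_inf/Km_app0).
    inter_mean = float(const["params"][0])
    slope0, slope_inf = hyp["params"][0], hyp["params"][1]
    km_app0 = slope0 / inter_mean if inter_mean > 0 else math.nan
    if slope_shape == "hyperbolic" and km_app0 and km_app0 > 0:
        v_inf = 1.0 / (inter_mean + slope_inf / km_app0)
        se_asym = hyp.get("se_asymptote", math.nan)
        se_v = (v_inf ** 2) * se_asym / km_app0 if np.isfinite(se_asym) else math.nan
        excludes = bool(np.isfinite(se_v) and v_inf > 2 * se_v)
    else:
        # a linear (unbounded) slope replot drives the apparent Km, and
        # hence pushes the limiting velocity, to zero
        v_inf, se_v, excludes = 0.0, math.nan, False

    return MechanismCall(
        label=label, slope_shape=slope_shape, intercept_shape=intercept_shape,
        limiting_velocity=float(v_inf), limiting_velocity_se=float(se_v) if np.isfinite(se_v) else math.nan,
        limiting_excludes_zero=excludes,
        stats={
            "slope_delta_aicc": float(d_aicc_slope), "slope_f": f_slope, "slope_p": p_slope,
            "intercept_delta_aicc": float(d_aicc_int), "intercept_f": f_int,
            "intercept_p": p_int, "slope_asymptote": float(slope_inf),
            "slope_at_zero": float(slope0),
        })
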