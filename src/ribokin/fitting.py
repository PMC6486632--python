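"""Nonlinear least-squares estimation for every model in the package.

All fits minimise unweighted ordinary least squares on the measured
response (velocity, percent bound or percent activity), with the optimiser
running in log-parameter space so positivity constraints are automatic and
results are invariant to concentration-unit rescaling. Initialisation is
deterministic (derived from the data); the global fit additionally seeds
the inhibitor constant from a logarithmic grid search. Standard errors
come from the Gauss–Newton approximation of the covariance, mapped back
from log space by the delta method; percentile bootstrap intervals
(case-resampling, stratified by series) are available for any fit.

Non-convergence is surfaced in the returned :class:`FitResult` rather than
raised, so batch simulations can tally failures.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

from .data import BindingDataset, InhibitionDataset, VelocitySeries
from .errors import DomainError, IdentifiabilityError
from .models import KineticParams, velocity_variant

__all__ = [
    "FitResult",
    "ModelComparison",
    "fit_binding_isotherm",
    "fit_inhibition_curve",
    "fit_saturation",
    "fit_global",
    "bootstrap_ci",
    "compare_models",
    "GLOBAL_MODELS",
]

#: global-fit model name -> rate-law variant it evaluates
GLOBAL_MODELS = {
    "eq4": "hyperbolic_competitive",
    "pure_competitive": "pure_competitive",
    "pure_mixed": "pure_mixed",
}


@dataclass
class FitResult:
    """Point estimates plus everything needed to judge and reuse a fit."""

    model: str
    params: dict
    stderr: dict
    rss: float
    n_points: int
    n_params: int
    converged: bool
    message: str = ""
    fixed: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    ci: dict | None = None
    seed: int | None = None
    n_resamples: int = 0
    data_fingerprint: str = ""
    residuals: np.ndarray | None = None

    def aicc(self) -> float:
        """Small-sample corrected Akaike criterion; the error variance
        counts as one extra parameter (curve-fitting convention)."""
        n, k = self.n_points, self.n_params + 1
        if self.rss <= 0:
            return -math.inf
        base = n * math.log(self.rss / n) + 2 * k
        if n - k - 1 <= 0:
            return math.inf
        return base + 2 * k * (k + 1) / (n - k - 1)


@dataclass
class ModelComparison:
    """Side-by-side AICc/RSS table with nested F-tests and a verdict."""

    models: list          # dicts: model, rss, aicc, n_params
    f_tests: list         # dicts: full, reduced, f, p, df1, df2
    preferred: str        # model name, or "tie"
    delta_aicc: float     # margin of the best model over the runner-up


def _fingerprint(*arrays) -> str:
    h = hashlib.sha1()
    for a in arrays:
        h.update(np.ascontiguousarray(np.asarray(a, dtype=float)).tobytes())
    return h.hexdigest()[:12]


def _ls_log(predict, y, names, p0, fixed=None, model_name=""):
    """Least squares over log-transformed free parameters.

    ``predict(params_dict)`` returns the model response; ``p0`` maps every
    free name to a positive start value. Returns a FitResult.
    """
    fixed = dict(fixed or {})
    free = [n for n in names if n not in fixed]
    y = np.asarray(y, dtype=float)
    x0 = np.log([p0[n] for n in free])

    def _exp(v: float) -> float:
        # clip so exploratory optimiser steps can neither underflow to an
        # exact 0 (rejected by parameter validation) nor overflow
        return math.exp(min(max(v, -230.0), 230.0))

    def resid(x):
        p = dict(fixed)
        p.update({n: _exp(v) for n, v in zip(free, x)})
        return predict(p) - y

    warnings: list[str] = []
    try:
        sol = least_squares(resid, x0, method="lm", xtol=1e-14, ftol=1e-14, gtol=1e-14,
                            max_nfev=20000)
        ok = sol.success and np.all(np.isfinite(sol.x))
        message = str(sol.message)
    except Exception as exc:  # numerical failure, not a usage error
        return FitResult(model=model_name, params=dict(p0), stderr={}, rss=math.inf,
                         n_points=len(y), n_params=len(free), converged=False,
                         message=f"optimiser raised: {exc}", fixed=fixed)

    est = {n: _exp(v) for n, v in zip(free, sol.x)}
    r = sol.fun
    rss = float(r @ r)
    n, p = len(y), len(free)

    stderr = {n_: math.nan for n_ in free}
    jac = sol.jac
    col_norms = np.linalg.norm(jac, axis=0)
    if col_norms.max() > 0:
        for i, name in enumerate(free):
            if col_norms[i] < 1e-10 * col_norms.max():
                warnings.append(f"{name} unidentifiable (flat objective)")
    if ok and n > p:
        s2 = rss / (n - p)
        jtj = jac.T @ jac
        try:
            cov_log = s2 * np.linalg.inv(jtj)
        except np.linalg.LinAlgError:
            cov_log = s2 * np.linalg.pinv(jtj)
            warnings.append("singular information matrix; pseudo-inverse covariance")
        se_log = np.sqrt(np.clip(np.diag(cov_log), 0, None))
        # delta method: theta = exp(log theta)
        stderr = {name: est[name] * se_log[i] for i, name in enumerate(free)}

    return FitResult(
        model=model_name, params={**est, **fixed}, stderr=stderr, rss=rss,
        n_points=n, n_params=p, converged=bool(ok), message=message, fixed=fixed,
        warnings=warnings, residuals=r,
    )


# ---------------------------------------------------------------------------
# individual fitters

def fit_binding_isotherm(data: BindingDataset, fit_bmax: bool = False,
                         p0: dict | None = None) -> FitResult:
    """Estimate the apparent dissociation constant from a band-shift
    titration, ``%bound = Bmax·[P]/(Kd + [P])`` with Bmax fixed at 100
    unless ``fit_bmax``.

    Raises :class:`IdentifiabilityError` when the titration carries no
    signal (all zero) or only saturated points.
    """
    p_conc, y = data.protein_conc, data.percent_bound
    if y.max() <= 0:
        raise IdentifiabilityError("no binding signal: all percent-bound values are zero")
    bmax_ref = y.max() if fit_bmax else 100.0
    if y.min() >= 0.9 * bmax_ref and not fit_bmax:
        raise IdentifiabilityError(
            "titration is saturated at every concentration; Kd not identifiable")

    names = ["kd_app"] + (["bmax"] if fit_bmax else [])
    fixed = {} if fit_bmax else {"bmax": 100.0}
    if p0 is None:
        half = bmax_ref / 2.0
        pos = p_conc[p_conc > 0]
        kd0 = float(p_conc[np.argmin(np.abs(y - half))]) or float(np.median(pos))
        p0 = {"kd_app": max(kd0, 1e-6), "bmax": float(max(y.max(), 1.0))}

    def predict(p):
        return p["bmax"] * p_conc / (p["kd_app"] + p_conc)

    res = _ls_log(predict, y, names, p0, fixed=fixed, model_name="binding")
    if len(np.unique(p_conc)) < 4:
        res.warnings.append("fewer than 4 distinct protein concentrations")
    res.data_fingerprint = _fingerprint(p_conc, y)
    return res


def fit_inhibition_curve(data: InhibitionDataset, p0: dict | None = None) -> FitResult:
    """Estimate IC50 from a percent-activity-vs-RNA curve,
    ``%activity = 100·IC50/([I] + IC50)``.

    Flat data (no inhibition signal) raises :class:`IdentifiabilityError`.
    """
    i_conc, y = data.inhibitor_conc, data.percent_activity
    spread = y.max() - y.min()
    if spread <= 1e-3 * max(abs(y.max()), 1.0):
        raise IdentifiabilityError("no inhibition signal: activity curve is flat")
    if p0 is None:
        pos = i_conc[i_conc > 0]
        if len(pos) == 0:
            raise IdentifiabilityError("need at least one nonzero inhibitor concentration")
        ic0 = float(i_conc[np.argmin(np.abs(y - 50.0))])
        if ic0 <= 0:
            ic0 = float(stats.gmean(pos))
        p0 = {"ic50": ic0}

    def predict(p):
        return 100.0 * p["ic50"] / (i_conc + p["ic50"])

    res = _ls_log(predict, y, ["ic50"], p0, model_name="ic50")
    if len(np.unique(i_conc)) < 4:
        res.warnings.append("fewer than 4 distinct inhibitor concentrations")
    res.data_fingerprint = _fingerprint(i_conc, y)
    return res


def fit_saturation(series: VelocitySeries, model: str = "eq3",
                   p0: dict | None = None) -> FitResult:
    """Fit one saturation curve to plain Michaelis–Menten
    (``michaelis_menten``) or the substrate-inhibited form (``eq3``).

    For the substrate-inhibited model, a design with no point beyond the
    fitted velocity optimum sqrt(Km·KiTHF) leaves KiTHF weakly identified;
    that is recorded as a warning on the result, not an error.
    """
    if model not in ("michaelis_menten", "eq3"):
        raise DomainError(f"unknown saturation model {model!r}")
    s, v = series.substrate_conc, series.velocity
    names = ["vmax", "km"] + (["ki_thf"] if model == "eq3" else [])
    if series.n_substrate_levels <= len(names):
        raise IdentifiabilityError(
            f"{model} needs more than {len(names)} distinct substrate levels")
    if p0 is None:
        avg = series.averaged()
        vmax0 = float(v.max())
        peak = int(np.argmax(avg.velocity))
        rising_s, rising_v = avg.substrate_conc[: peak + 1], avg.velocity[: peak + 1]
        half_idx = int(np.argmin(np.abs(rising_v - vmax0 / 2.0)))
        km0 = float(rising_s[half_idx])
        if km0 <= 0:
            km0 = float(np.median(s[s > 0]))
        p0 = {"vmax": vmax0, "km": km0, "ki_thf": float(s.max())}

    if model == "michaelis_menten":
        def predict(p):
            return p["vmax"] * s / (p["km"] + s)
    else:
        def predict(p):
            return p["vmax"] * s / (p["km"] + s * (1.0 + s / p["ki_thf"]))

    res = _ls_log(predict, v, names, p0, model_name=model)
    if model == "eq3" and res.converged:
        s_opt = math.sqrt(res.params["km"] * res.params["ki_thf"])
        if s.max() <= s_opt:
            res.warnings.append(
                "no substrate concentrations beyond the velocity optimum; "
                "ki_thf weakly identified")
    res.data_fingerprint = _fingerprint(s, v)
    return res


def _stack(series_set: list[VelocitySeries]):
    s = np.concatenate([ser.substrate_conc for ser in series_set])
    i = np.concatenate([np.full(len(ser), ser.inhibitor_conc) for ser in series_set])
    v = np.concatenate([ser.velocity for ser in series_set])
    return s, i, v


def _global_param_names(model: str, substrate_inhibition: bool) -> list[str]:
    names = ["vmax", "km"]
    if substrate_inhibition:
        names.append("ki_thf")
    names.append("ki")
    if model in ("eq4", "pure_mixed"):
        names.append("alpha")
    return names


def fit_global(series_set: list[VelocitySeries], model: str = "eq4",
               fixed: dict | None = None, substrate_inhibition: bool = True,
               multistart: bool = False, p0: dict | None = None) -> FitResult:
    """Global fit across inhibitor series with (Vmax, Km[, KiTHF]) and the
    inhibition parameters shared by every series.

    ``model`` selects the rate law: ``eq4`` (hyperbolic competitive),
    ``pure_competitive`` or ``pure_mixed``. ``fixed`` pins parameters
    (e.g. ``{"alpha": 1.0}``); a parameter made redundant that way is
    flagged unidentifiable in the result's warnings. ``multistart`` runs a
    deterministic 3×3 grid over (Ki, α) starts and keeps the best optimum.
    """
    if model not in GLOBAL_MODELS:
        raise DomainError(f"unknown global model {model!r}; choose from {sorted(GLOBAL_MODELS)}")
    levels = sorted({ser.inhibitor_conc for ser in series_set})
    if len(levels) < 3 or 0.0 not in levels:
        raise IdentifiabilityError(
            "global fit needs >= 3 inhibitor levels including 0, got "
            f"{levels}")
    fixed = dict(fixed or {})
    variant = GLOBAL_MODELS[model]
    s_all, i_all, v_all = _stack(series_set)
    names = _global_param_names(model, substrate_inhibition)

    def predict(p):
        kp = KineticParams(
            vmax=p["vmax"], km=p["km"],
            ki_thf=p.get("ki_thf"), ki=p.get("ki"), alpha=p.get("alpha", 1.0),
        )
        return velocity_variant(s_all, i_all, kp, variant)

    if p0 is None:
        base = min(series_set, key=lambda ser: ser.inhibitor_conc).averaged()
        vmax0 = float(v_all.max())
        # half-max search on the rising limb only: with substrate
        # inhibition the half-max velocity recurs on the falling limb
        peak = int(np.argmax(base.velocity))
        rising_s = base.substrate_conc[: peak + 1]
        rising_v = base.velocity[: peak + 1]
        half_idx = int(np.argmin(np.abs(rising_v - vmax0 / 2.0)))
        km0 = float(rising_s[half_idx])
        if km0 <= 0:
            km0 = float(np.median(s_all[s_all > 0]))
        p0 = {"vmax": vmax0, "km": km0, "ki_thf": float(s_all.max()), "alpha": 10.0}
        # deterministic log-grid seed for the inhibitor constant
        if "ki" not in fixed:
            grid = np.geomspace(1e-3, 10.0, 13)
            rss_grid = []
            for ki0 in grid:
                trial = {**{k: p0[k] for k in names if k != "ki"}, "ki": ki0, **fixed}
                r = predict(trial) - v_all
                rss_grid.append(r @ r)
            p0["ki"] = float(grid[int(np.argmin(rss_grid))])
        else:
            p0["ki"] = fixed["ki"]

    starts = [p0]
    if multistart:
        starts = [
            {**p0, "ki": p0["ki"] * fk, "alpha": fa}
            for fk in (0.3, 1.0, 3.0) for fa in (3.0, 10.0, 30.0)
        ]
    best = None
    for start in starts:
        res = _ls_log(predict, v_all, names, start, fixed=fixed, model_name=model)
        if best is None or (res.converged and res.rss < best.rss):
            best = res
    best.data_fingerprint = _fingerprint(s_all, i_all, v_all)
    return best


# ---------------------------------------------------------------------------
# bootstrap and model comparison

def _resample_series(series_set, rng):
    out = []
    for ser in series_set:
        idx = rng.integers(0, len(ser), size=len(ser))
        out.append(ser.subset(np.sort(idx)))
    return out


def bootstrap_ci(result: FitResult, data, n_resamples: int = 1000, *,
                 seed: int, level: float = 0.95, **fit_kwargs) -> FitResult:
    """Percentile bootstrap intervals by case resampling.

    Resampling is stratified by series for global fits (each inhibitor
    series keeps its size). Refits warm-start at the full-data estimates.
    Returns a copy of ``result`` with ``ci`` populated; failed refits are
    skipped and counted in the warnings. The seed is mandatory and the
    output is reproducible given it.
    """
    if not result.converged:
        raise DomainError("bootstrap requires a converged fit")
    warnings = list(result.warnings)
    if n_resamples < 100:
        warnings.append(f"n_resamples={n_resamples} < 100: intervals are unreliable")
    rng = np.random.default_rng(seed)
    free = [n for n in result.params if n not in result.fixed]
    p0 = {n: result.params[n] for n in result.params}
    draws = {n: [] for n in free}
    failures = 0
    for _ in range(n_resamples):
        if result.model == "binding":
            idx = rng.integers(0, len(data), size=len(data))
            boot = BindingDataset(data.protein_conc[idx], data.percent_bound[idx])
            try:
                fit = fit_binding_isotherm(boot, p0=p0, **fit_kwargs)
            except IdentifiabilityError:
                fit = None
        elif result.model == "ic50":
            idx = rng.integers(0, len(data), size=len(data))
            boot = InhibitionDataset(data.inhibitor_conc[idx], data.percent_activity[idx])
            try:
                fit = fit_inhibition_curve(boot, p0=p0)
            except IdentifiabilityError:
                fit = None
        elif result.model in ("michaelis_menten", "eq3"):
            idx = np.sort(rng.integers(0, len(data), size=len(data)))
            boot = data.subset(idx)
            try:
                fit = fit_saturation(boot, model=result.model, p0=p0)
            except IdentifiabilityError:
                fit = None
        elif result.model in GLOBAL_MODELS:
            boot = _resample_series(data, rng)
            fit = fit_global(boot, model=result.model, fixed=result.fixed,
                             p0=p0, **fit_kwargs)
        else:
            raise DomainError(f"bootstrap does not know model {result.model!r}")
        if fit is None or not fit.converged:
            failures += 1
            continue
        for n in free:
            draws[n].append(fit.params[n])
    if failures:
        warnings.append(f"{failures}/{n_resamples} bootstrap refits failed")
    lo_q, hi_q = 100 * (1 - level) / 2, 100 * (1 + level) / 2
    ci = {}
    for n in free:
        if draws[n]:
            arr = np.asarray(draws[n])
            ci[n] = (float(np.percentile(arr, lo_q)), float(np.percentile(arr, hi_q)))
    return replace(result, ci=ci, seed=seed, n_resamples=n_resamples, warnings=warnings)


def compare_models(fits: list[FitResult]) -> ModelComparison:
    """Rank fits of the same data by AICc and test nested pairs by the
    extra-sum-of-squares F-test.

    The preferred model is the AICc minimiser when its margin over the
    runner-up exceeds 2; otherwise a tie is reported. Pairs with differing
    parameter counts are treated as nested (the smaller model is the
    boundary/limit of the larger, as with pure-competitive inside the
    hyperbolic law); a larger model fitting worse than the smaller one
    yields F = 0, p = 1.
    """
    if len(fits) < 2:
        raise DomainError("need at least two fits to compare")
    prints = {f.data_fingerprint for f in fits}
    if len(prints) != 1 or "" in prints:
        raise DomainError("fits do not share identical data")
    rows = [{"model": f.model, "rss": f.rss, "aicc": f.aicc(), "n_params": f.n_params}
            for f in fits]
    order = sorted(range(len(rows)), key=lambda i: rows[i]["aicc"])
    delta = rows[order[1]]["aicc"] - rows[order[0]]["aicc"]
    preferred = rows[order[0]]["model"] if delta > 2 else "tie"

    f_tests = []
    for i in range(len(fits)):
        for j in range(len(fits)):
            fi, fj = fits[i], fits[j]
            if fi.n_params <= fj.n_params:
                continue
            full, red = fi, fj
            df_full = full.n_points - full.n_params
            df1 = full.n_params - red.n_params
            if df_full <= 0:
                continue
            num = (red.rss - full.rss) / df1
            den = full.rss / df_full
            if num <= 0 or den <= 0:
                fstat, p = 0.0, 1.0
            else:
                fstat = num / den
                p = float(stats.f.sf(fstat, df1, df_full))
            f_tests.append({"full": full.model, "reduced": red.model,
                            "f": fstat, "p": p, "df1": df1, "df2": df_full})
    return ModelComparison(models=rows, f_tests=f_tests, preferred=preferred,
                           delta_aicc=float(delta))
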