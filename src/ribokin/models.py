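"""Closed-form models for RNA–protein binding and RNA-mediated enzyme inhibition.

The package centres on four algebraic models used to analyse how an RNA
ligand binds a folate-dependent enzyme (SHMT1) and inhibits its catalysis:

* a one-site binding isotherm for band-shift (EMSA) titrations,
  ``%bound = Bmax·[P]/(Kd + [P])``;
* a one-site dose-response curve for inhibition at fixed substrates,
  ``%activity = 100·(1 − [I]/([I] + IC50))``;
* a Michaelis–Menten rate law extended with substrate inhibition by the
  folate substrate, ``v = Vmax·S/(Km + S·(1 + S/KiTHF))``;
* the same rate law further extended with *hyperbolic (partial)
  competitive* inhibition, in which the inhibitor raises the apparent Km
  by the saturating factor ``(1 + I/Ki)/(1 + I/(α·Ki))`` and the velocity
  therefore tends to a nonzero floor as I → ∞.

All concentrations are in μM; velocities carry arbitrary (absorbance-based)
units, so only ratios and concentration-valued parameters are meaningful.
Every function accepts scalars or numpy arrays for the concentration
arguments and broadcasts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DomainError

__all__ = [
    "BindingParams",
    "InhibitionCurveParams",
    "KineticParams",
    "fraction_bound",
    "percent_activity",
    "velocity_substrate_inhibition",
    "velocity_hyperbolic_competitive",
    "velocity_variant",
    "limiting_velocity",
    "km_inhibition_factor",
    "substrate_optimum",
    "VARIANTS",
]

VARIANTS = ("michaelis_menten", "pure_competitive", "pure_mixed", "hyperbolic_competitive")


def _check_nonneg(x, name: str):
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise DomainError(f"{name} must be non-negative, got {x!r}")
    return arr


@dataclass(frozen=True)
class BindingParams:
    """One-site binding isotherm parameters.

    Parameters
    ----------
    kd_app : float
        Apparent dissociation constant of the protein–RNA complex, μM.
    bmax : float
        Maximal percent bound. Fixed at 100 by convention (densitometry is
        normalised so full binding is 100%); fitting it is opt-in.
    """

    kd_app: float
    bmax: float = 100.0

    def __post_init__(self):
        if not self.kd_app > 0:
            raise DomainError(f"kd_app must be > 0, got {self.kd_app}")
        if not 0 < self.bmax <= 100:
            raise DomainError(f"bmax must be in (0, 100], got {self.bmax}")


@dataclass(frozen=True)
class InhibitionCurveParams:
    """Dose-response parameter: IC50, the inhibitor concentration at
    half-maximal residual activity, μM."""

    ic50: float

    def __post_init__(self):
        if not self.ic50 > 0:
            raise DomainError(f"ic50 must be > 0, got {self.ic50}")


@dataclass(frozen=True)
class KineticParams:
    """Rate-law parameters.

    Parameters
    ----------
    vmax : float
        Maximal velocity, arbitrary units/s.
    km : float
        Michaelis constant for the varied substrate, μM.
    ki_thf : float, optional
        Substrate-inhibition constant (dead-end second-folate binding), μM.
        ``None`` means no substrate inhibition.
    ki : float, optional
        Inhibitor dissociation constant from the free enzyme, μM.
    alpha : float, optional
        Factor by which binding of one ligand reduces affinity for the
        other (dimensionless). ``alpha = 1`` means the inhibitor leaves Km
        unchanged; the pure-competitive limit α → ∞ is expressed through
        the ``pure_competitive`` variant rather than a numeric infinity.
    """

    vmax: float
    km: float
    ki_thf: float | None = None
    ki: float | None = None
    alpha: float | None = None

    def __post_init__(self):
        for name in ("vmax", "km", "ki_thf", "ki", "alpha"):
            val = getattr(self, name)
            if val is not None and not val > 0:
                raise DomainError(f"{name} must be > 0 when present, got {val}")

    def _require(self, *names: str):
        missing = [n for n in names if getattr(self, n) is None]
        if missing:
            raise ConfigurationError(
                f"model requires parameters {missing} but they are absent"
            )


def fraction_bound(p_conc, params: BindingParams):
    """Percent of RNA bound at protein concentration ``p_conc`` (μM).

    Strictly increasing in ``p_conc``; tends to ``bmax`` at saturation and
    equals ``bmax/2`` at ``p_conc = kd_app``.
    """
    p = _check_nonneg(p_conc, "p_conc")
    return params.bmax * p / (params.kd_app + p)


def percent_activity(i_conc, params: InhibitionCurveParams):
    """Residual enzyme activity (percent) at inhibitor concentration
    ``i_conc`` (μM): ``100·(1 − I/(I + IC50))``. Decreases from 100 to 0."""
    i = _check_nonneg(i_conc, "i_conc")
    return 100.0 * (1.0 - i / (i + params.ic50))


def velocity_substrate_inhibition(thf, params: KineticParams):
    """Rate law with substrate inhibition by the folate substrate.

    ``v = Vmax·S / (Km + S·(1 + S/KiTHF))``. The velocity peaks at
    ``S* = sqrt(Km·KiTHF)`` and declines beyond it.
    """
    params._require("ki_thf")
    s = _check_nonneg(thf, "thf")
    return params.vmax * s / (params.km + s * (1.0 + s / params.ki_thf))


def km_inhibition_factor(i_conc, ki: float, alpha: float):
    """Saturating factor ``(1 + I/Ki)/(1 + I/(α·Ki))`` multiplying Km under
    hyperbolic competitive inhibition. Rises from 1 at I=0 to α as I → ∞."""
    if not ki > 0 or not alpha > 0:
        raise DomainError("ki and alpha must be > 0")
    i = _check_nonneg(i_conc, "i_conc")
    return (1.0 + i / ki) / (1.0 + i / (alpha * ki))


def velocity_hyperbolic_competitive(thf, i_conc, params: KineticParams):
    """Rate law combining substrate inhibition with hyperbolic competitive
    inhibition.

    The apparent Km is multiplied by ``(1 + I/Ki)/(1 + I/(α·Ki))``; the
    ternary enzyme–substrate–inhibitor complex remains productive, so the
    velocity saturates at a nonzero floor (see :func:`limiting_velocity`)
    instead of vanishing at high inhibitor.
    """
    params._require("ki_thf", "ki", "alpha")
    s = _check_nonneg(thf, "thf")
    f = km_inhibition_factor(i_conc, params.ki, params.alpha)
    return params.vmax * s / (params.km * f + s * (1.0 + s / params.ki_thf))


def limiting_velocity(thf, params: KineticParams):
    """I → ∞ limit of the hyperbolic-competitive rate law:
    ``Vmax·S/(α·Km + S·(1 + S/KiTHF))``. Strictly positive for S > 0 —
    the signature that distinguishes partial from pure competitive
    inhibition."""
    params._require("ki_thf", "ki", "alpha")
    s = _check_nonneg(thf, "thf")
    return params.vmax * s / (params.alpha * params.km + s * (1.0 + s / params.ki_thf))


def substrate_optimum(params: KineticParams) -> float:
    """Substrate concentration maximising the substrate-inhibited rate law:
    ``S* = sqrt(Km·KiTHF)``."""
    params._require("ki_thf")
    return float(np.sqrt(params.km * params.ki_thf))


def velocity_variant(s, i_conc, params: KineticParams, variant: str):
    """Evaluate one of the standard rate-law variants used as competing
    hypotheses in mechanism discrimination.

    ``michaelis_menten``
        Plain hyperbola, no inhibitor, no substrate inhibition.
    ``pure_competitive``
        Km multiplied by ``(1 + I/Ki)``; equals the hyperbolic-competitive
        law in the limit α → ∞. Substrate-inhibition term retained when
        ``ki_thf`` is present.
    ``pure_mixed``
        Slope factor ``(1 + I/Ki)`` on Km and intercept factor
        ``(1 + I/(α·Ki))`` on the substrate term (here α·Ki plays the role
        of the inhibitor constant for the enzyme–substrate complex).
    ``hyperbolic_competitive``
        Alias for :func:`velocity_hyperbolic_competitive`.
    """
    s_arr = _check_nonneg(s, "s")
    if variant == "michaelis_menten":
        return params.vmax * s_arr / (params.km + s_arr)
    si = 0.0 if params.ki_thf is None else s_arr / params.ki_thf
    if variant == "pure_competitive":
        params._require("ki")
        i = _check_nonneg(i_conc, "i_conc")
        return params.vmax * s_arr / (params.km * (1.0 + i / params.ki) + s_arr * (1.0 + si))
    if variant == "pure_mixed":
        params._require("ki", "alpha")
        i = _check_nonneg(i_conc, "i_conc")
        den = params.km * (1.0 + i / params.ki) + s_arr * (
            1.0 + i / (params.alpha * params.ki) + si
        )
        return params.vmax * s_arr / den
    if variant == "hyperbolic_competitive":
        return velocity_hyperbolic_competitive(s_arr, i_conc, params)
    raise ConfigurationError(f"unknown variant {variant!r}; choose from {VARIANTS}")
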