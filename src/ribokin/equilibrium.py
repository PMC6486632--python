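"""Rapid-equilibrium species balance for the hyperbolic-competitive scheme.

The binding scheme couples four equilibria on the enzyme (E), the varied
folate substrate (S) and the RNA inhibitor (R)::

    E   + S  ⇌  E·S        Ks
    E   + R  ⇌  E·R        Ki
    E·S + R  ⇌  E·R·S      α·Ki
    E·R + S  ⇌  E·R·S      α·Ks     (thermodynamic cycle closure)

plus, optionally, a dead-end second-folate site responsible for substrate
inhibition. The second folate binds both productive complexes with the
same constant,

    E·S   + S  ⇌  E·S·S      KiTHF
    E·R·S + S  ⇌  E·R·S·S    KiTHF

which is exactly the closure under which the scheme's rapid-equilibrium
rate law reduces to the closed-form hyperbolic-competitive equation (the
substrate-inhibition term ``S(1 + S/KiTHF)`` is then independent of R).

Both E·S and E·R·S turn over with the same kcat; the dead-end complexes do
not. Solving the mass balances for free S and R gives the species
distribution without assuming ligands are in excess, so this module serves
as a brute-force oracle for the closed-form rate law and quantifies when
ligand depletion matters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import root

from .errors import DomainError, EquilibriumError

__all__ = ["SchemeSpec", "SpeciesState", "solve_equilibrium", "oracle_velocity"]

#: relative tolerance demanded of each mass balance in a returned state
BALANCE_RTOL = 1e-9


@dataclass(frozen=True)
class SchemeSpec:
    """Equilibrium constants (μM), turnover and total concentrations (μM).

    ``ks`` is identified with the Michaelis constant under the
    rapid-equilibrium assumption. ``alpha`` multiplies both cross-binding
    constants (cycle closure). ``ki_thf = None`` disables the dead-end
    second-folate site.
    """

    ks: float
    ki: float
    alpha: float
    kcat: float
    e_total: float
    s_total: float
    r_total: float
    ki_thf: float | None = None

    def __post_init__(self):
        for name in ("ks", "ki", "alpha", "kcat", "e_total", "s_total"):
            if not getattr(self, name) > 0:
                raise DomainError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.r_total < 0:
            raise DomainError(f"r_total must be >= 0, got {self.r_total}")
        if self.ki_thf is not None and not self.ki_thf > 0:
            raise DomainError(f"ki_thf must be > 0 when present, got {self.ki_thf}")


@dataclass(frozen=True)
class SpeciesState:
    """Equilibrium concentrations of every species, μM.

    ``ess`` and ``erss`` are the dead-end second-folate complexes on E·S
    and E·R·S respectively (zero when the scheme has no dead-end site).
    """

    e: float
    es: float
    er: float
    ers: float
    ess: float
    erss: float
    s_free: float
    r_free: float

    def total_enzyme(self) -> float:
        return self.e + self.es + self.er + self.ers + self.ess + self.erss

    def bound_enzyme(self) -> float:
        return self.es + self.er + self.ers + self.ess + self.erss


def _species(spec: SchemeSpec, s: float, r: float) -> SpeciesState:
    """Species distribution given free ligand concentrations."""
    ks, ki, a = spec.ks, spec.ki, spec.alpha
    kthf = spec.ki_thf
    # binding polynomial terms, relative to free E
    t_es = s / ks
    t_er = r / ki
    t_ers = s * r / (a * ks * ki)
    t_ess = t_es * (s / kthf) if kthf else 0.0
    t_erss = t_ers * (s / kthf) if kthf else 0.0
    den = 1.0 + t_es + t_er + t_ers + t_ess + t_erss
    e = spec.e_total / den
    return SpeciesState(
        e=e, es=e * t_es, er=e * t_er, ers=e * t_ers,
        ess=e * t_ess, erss=e * t_erss, s_free=s, r_free=r,
    )


def _residuals(spec: SchemeSpec, s: float, r: float) -> tuple[float, float]:
    """Relative mass-balance residuals for S and R."""
    st = _species(spec, s, r)
    s_bound = st.es + st.ers + 2.0 * (st.ess + st.erss)
    f_s = (s + s_bound - spec.s_total) / spec.s_total
    if spec.r_total > 0:
        r_bound = st.er + st.ers + st.erss
        f_r = (r + r_bound - spec.r_total) / spec.r_total
    else:
        f_r = 0.0
    return f_s, f_r


def solve_equilibrium(spec: SchemeSpec, max_iter: int = 200) -> SpeciesState:
    """Solve the coupled mass-action/mass-balance system for the unique
    non-negative equilibrium.

    Root-finding runs on log-transformed free-ligand concentrations
    (guaranteeing positivity) with deterministic initialisation at the
    totals. Raises :class:`EquilibriumError` with residual diagnostics if
    the balances are not met to ``BALANCE_RTOL`` relative.
    """
    has_r = spec.r_total > 0

    if has_r:
        x0 = np.log([spec.s_total, spec.r_total])

        def fun(x):
            return _residuals(spec, float(np.exp(x[0])), float(np.exp(x[1])))
    else:
        x0 = np.log([spec.s_total])

        def fun(x):
            return [_residuals(spec, float(np.exp(x[0])), 0.0)[0]]

    sol = root(fun, x0, method="hybr", tol=1e-14, options={"maxfev": max_iter * len(x0)})
    s = float(np.exp(sol.x[0]))
    r = float(np.exp(sol.x[1])) if has_r else 0.0
    f_s, f_r = _residuals(spec, s, r)
    if max(abs(f_s), abs(f_r)) > BALANCE_RTOL:
        raise EquilibriumError(
            "species balance did not converge",
            diagnostics={"residual_s": f_s, "residual_r": f_r,
                         "s_free": s, "r_free": r, "solver_message": sol.message},
        )
    return _species(spec, s, r)


def closed_form_at_free(spec: SchemeSpec, state: SpeciesState) -> float:
    """Evaluate the closed-form hyperbolic-competitive rate law at the
    *free* ligand concentrations of a solved state.

    The rapid-equilibrium rate law is exactly a function of free S and R;
    agreement with :func:`oracle_velocity` at this point is limited only
    by solver tolerance. Evaluating the closed form at *total*
    concentrations instead incurs an additional depletion error of order
    ``e_total / r_total``.
    """
    s, r = state.s_free, state.r_free
    f = (1.0 + r / spec.ki) / (1.0 + r / (spec.alpha * spec.ki))
    si = 1.0 + (s / spec.ki_thf if spec.ki_thf else 0.0)
    vmax = spec.kcat * spec.e_total
    return vmax * s / (spec.ks * f + s * si)


def oracle_velocity(spec: SchemeSpec) -> float:
    """Initial velocity of the scheme: ``kcat·([E·S] + [E·R·S])``.

    Both the binary enzyme–folate complex and the ternary complex with RNA
    are productive with the same turnover number — the defining assumption
    of hyperbolic (partial) competitive inhibition. In the excess-ligand
    regime this matches the closed-form rate law
    :func:`ribokin.models.velocity_hyperbolic_competitive`; when enzyme is
    comparable to Ki it quantifies the inhibitor-depletion bias instead.
    """
    st = solve_equilibrium(spec)
    return spec.kcat * (st.es + st.ers)
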