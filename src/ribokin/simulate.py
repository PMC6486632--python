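"""Synthetic datasets with the statistical structure of the assays analysed.

Every generator produces data from a known ground truth with multiplicative
Gaussian noise (constant coefficient of variation, default 5%, three
replicates — the standard error structure of coupled spectrophotometric
assays), so that every estimation and diagnostic stage of the package can
be exercised end-to-end with a known answer.

Built-in designs reproduce the experimental layouts the analysis targets:

``thf-inhibitor-grid``
    Initial velocities with the folate substrate (THF) varied over
    10–488 μM (8 log-spaced levels) at saturating serine (10 mM) and six
    fixed tRNA concentrations 0–1.77 μM.
``serine-inhibitor-grid``
    Serine varied 0.156–10 mM (seven two-fold steps, stored in μM) at
    80 μM THF, same tRNA grid.
``protein-titration``
    Band-shift titration, protein 0.3–9.6 μM in six two-fold steps.
``rna-dose-response``
    Percent activity at fixed substrates, RNA log-spaced 1 nM–10 μM.

The number of substrate levels per velocity curve (8) is a design choice
recorded in the design's ``notes`` field.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .data import BindingDataset, InhibitionDataset, VelocitySeries
from .equilibrium import SchemeSpec, oracle_velocity
from .errors import DomainError
from .models import (
    BindingParams,
    InhibitionCurveParams,
    KineticParams,
    fraction_bound,
    percent_activity,
    velocity_variant,
)

__all__ = [
    "ExperimentDesign",
    "builtin_design",
    "BUILTIN_DESIGN_NAMES",
    "generate_velocity_matrix",
    "generate_binding_dataset",
    "generate_inhibition_curve",
    "substream_rng",
]

logger = logging.getLogger(__name__)

DEFAULT_CV = 0.05
DEFAULT_REPLICATES = 3


@dataclass(frozen=True)
class ExperimentDesign:
    """A measurement layout: which concentrations are visited, how many
    replicates per cell, and how noisy the readout is (fractional CV)."""

    name: str
    substrate_grid: tuple = ()
    inhibitor_grid: tuple = ()
    substrate_name: str = "THF"
    inhibitor_name: str = "tRNA"
    cosubstrate_name: str = ""
    cosubstrate_conc_um: float = 0.0
    replicates: int = DEFAULT_REPLICATES
    cv: float = DEFAULT_CV
    notes: str = ""

    def __post_init__(self):
        if self.replicates < 1:
            raise DomainError("replicates must be >= 1")
        if self.cv < 0:
            raise DomainError("cv must be >= 0")
        if any(s <= 0 for s in self.substrate_grid):
            raise DomainError("substrate grid must be strictly positive")
        if any(i < 0 for i in self.inhibitor_grid):
            raise DomainError("inhibitor grid must be non-negative")


_TRNA_GRID = (0.0, 0.11, 0.22, 0.44, 0.88, 1.77)


def _builtins() -> dict:
    thf_grid = tuple(np.round(np.geomspace(10.0, 488.0, 8), 2))
    serine_grid = tuple(10000.0 / 2 ** k for k in range(6, -1, -1))  # 156.25 .. 10000 uM
    return {
        "thf-inhibitor-grid": ExperimentDesign(
            name="thf-inhibitor-grid", substrate_grid=thf_grid,
            inhibitor_grid=_TRNA_GRID, substrate_name="THF",
            inhibitor_name="tRNA", cosubstrate_name="L-serine",
            cosubstrate_conc_um=10000.0,
            notes="8 log-spaced THF levels over the assayed 10-488 uM range "
                  "(level count is a design choice)"),
        "serine-inhibitor-grid": ExperimentDesign(
            name="serine-inhibitor-grid", substrate_grid=serine_grid,
            inhibitor_grid=_TRNA_GRID, substrate_name="serine",
            inhibitor_name="tRNA", cosubstrate_name="THF",
            cosubstrate_conc_um=80.0,
            notes="serine 0.156-10 mM in two-fold steps, stored in uM; "
                  "fixed THF 80 uM"),
        "protein-titration": ExperimentDesign(
            name="protein-titration",
            substrate_grid=(0.3, 0.6, 1.2, 2.4, 4.8, 9.6),
            substrate_name="SHMT1",
            notes="band-shift titration, six two-fold protein steps"),
        "rna-dose-response": ExperimentDesign(
            name="rna-dose-response",
            inhibitor_grid=tuple(np.geomspace(1e-3, 10.0, 10)),
            inhibitor_name="RNA",
            notes="10 log-spaced RNA concentrations, 1 nM-10 uM"),
    }


BUILTIN_DESIGN_NAMES = tuple(sorted(_builtins()))


def builtin_design(name: str, **overrides) -> ExperimentDesign:
    """Fetch a built-in design, optionally overriding fields
    (``cv=0``, ``replicates=1``, ...)."""
    designs = _builtins()
    if name not in designs:
        raise DomainError(f"unknown design {name!r}; available: {BUILTIN_DESIGN_NAMES}")
    d = designs[name]
    return replace(d, **overrides) if overrides else d


def substream_rng(seed: int, stage: str) -> np.random.Generator:
    """Named substream: one user seed fans out to independent generators
    per pipeline stage."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())]))


def _noisy(rng, values: np.ndarray, cv: float) -> np.ndarray:
    if cv == 0:
        return values.copy()
    return values * (1.0 + cv * rng.standard_normal(values.shape))


def generate_velocity_matrix(design: ExperimentDesign, truth: KineticParams,
                             seed: int = 0, generator: str = "closed_form",
                             variant: str | None = None) -> list[VelocitySeries]:
    """Simulate one velocity series per inhibitor level.

    ``variant`` defaults to the richest rate law the truth parameters
    support (hyperbolic competitive when ``ki`` and ``alpha`` are present,
    else substrate-inhibited, else Michaelis–Menten). With
    ``generator="oracle"`` velocities come from the rapid-equilibrium
    species balance at trace enzyme (total enzyme 1e-4 of min(Km, Ki)), a
    fully independent route to the same numbers.

    Per replicate, velocity = model value × (1 + CV·z) with z standard
    normal; negative draws are truncated at 0 with a logged count.
    """
    if not design.substrate_grid or not len(design.inhibitor_grid):
        raise DomainError("design needs both a substrate grid and an inhibitor grid")
    if variant is None:
        if truth.ki is not None and truth.alpha is not None:
            variant = "hyperbolic_competitive"
        elif truth.ki_thf is not None:
            variant = "substrate_inhibition"
        else:
            variant = "michaelis_menten"
    rng = substream_rng(seed, "velocity")
    s_grid = np.asarray(design.substrate_grid, dtype=float)
    out = []
    for i_conc in design.inhibitor_grid:
        if generator == "closed_form":
            if variant == "substrate_inhibition":
                from .models import velocity_substrate_inhibition
                v_model = velocity_substrate_inhibition(s_grid, truth)
            else:
                v_model = velocity_variant(s_grid, i_conc, truth, variant)
        elif generator == "oracle":
            e_tot = 1e-4 * min(truth.km, truth.ki if truth.ki else truth.km)
            v_model = np.array([
                oracle_velocity(SchemeSpec(
                    ks=truth.km, ki=truth.ki, alpha=truth.alpha,
                    kcat=truth.vmax / e_tot, e_total=e_tot,
                    s_total=s, r_total=float(i_conc), ki_thf=truth.ki_thf))
                for s in s_grid])
        else:
            raise DomainError(f"unknown generator {generator!r}")
        s_rep = np.tile(s_grid, design.replicates)
        rep = np.repeat(np.arange(design.replicates), len(s_grid))
        v = _noisy(rng, np.tile(v_model, design.replicates), design.cv)
        n_neg = int((v < 0).sum())
        if n_neg:
            logger.warning("truncated %d negative simulated velocities to 0", n_neg)
            v = np.clip(v, 0.0, None)
        out.append(VelocitySeries(
            inhibitor_conc=float(i_conc), substrate_conc=s_rep, velocity=v,
            replicate=rep, substrate_name=design.substrate_name,
            inhibitor_name=design.inhibitor_name,
            series_id=f"{design.name}:I={i_conc:g}"))
    return out


def generate_binding_dataset(design: ExperimentDesign, truth: BindingParams,
                             seed: int = 0) -> BindingDataset:
    """Simulate a percent-bound titration over the design's protein grid
    (stored in ``substrate_grid``); noisy values are clipped to [0, 100]."""
    if not design.substrate_grid:
        raise DomainError("design needs a protein concentration grid")
    rng = substream_rng(seed, "binding")
    p = np.tile(np.asarray(design.substrate_grid, dtype=float), design.replicates)
    rep = np.repeat(np.arange(design.replicates), len(design.substrate_grid))
    y = np.clip(_noisy(rng, fraction_bound(p, truth), design.cv), 0.0, 100.0)
    return BindingDataset(protein_conc=p, percent_bound=y, replicate=rep)


def generate_inhibition_curve(design: ExperimentDesign, truth: InhibitionCurveParams,
                              seed: int = 0) -> InhibitionDataset:
    """Simulate a percent-activity curve over the design's inhibitor grid;
    noisy values are clipped to [0, 100·(1 + 5·CV)]."""
    if not len(design.inhibitor_grid):
        raise DomainError("design needs an inhibitor concentration grid")
    rng = substream_rng(seed, "inhibition")
    i = np.tile(np.asarray(design.inhibitor_grid, dtype=float), design.replicates)
    rep = np.repeat(np.arange(design.replicates), len(design.inhibitor_grid))
    cap = 100.0 * (1.0 + 5.0 * design.cv)
    y = np.clip(_noisy(rng, percent_activity(i, truth), design.cv), 0.0, cap)
    return InhibitionDataset(inhibitor_conc=i, percent_activity=y, replicate=rep,
                             inhibitor_name=design.inhibitor_name)
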