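"""In-memory containers for the experimental data types the package fits."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError

__all__ = ["VelocitySeries", "BindingDataset", "InhibitionDataset"]


def _as_float(x) -> np.ndarray:
    return np.atleast_1d(np.asarray(x, dtype=float))


@dataclass
class VelocitySeries:
    """Replicate initial-velocity measurements over a substrate grid at one
    fixed inhibitor concentration.

    ``substrate_conc`` (μM), ``velocity`` (arbitrary units) and
    ``replicate`` (integer index) are parallel arrays, one entry per
    measured point.
    """

    inhibitor_conc: float
    substrate_conc: np.ndarray
    velocity: np.ndarray
    replicate: np.ndarray | None = None
    substrate_name: str = "THF"
    inhibitor_name: str = "tRNA"
    series_id: str = ""

    def __post_init__(self):
        self.substrate_conc = _as_float(self.substrate_conc)
        self.velocity = _as_float(self.velocity)
        if self.replicate is None:
            self.replicate = np.zeros(len(self.substrate_conc), dtype=int)
        else:
            self.replicate = np.atleast_1d(np.asarray(self.replicate, dtype=int))
        if not (len(self.substrate_conc) == len(self.velocity) == len(self.replicate)):
            raise DomainError("substrate_conc, velocity and replicate must be equal length")
        if self.inhibitor_conc < 0 or np.any(self.substrate_conc < 0):
            raise DomainError("concentrations must be non-negative")

    def __len__(self) -> int:
        return len(self.velocity)

    @property
    def n_substrate_levels(self) -> int:
        return len(np.unique(self.substrate_conc))

    def averaged(self) -> "VelocitySeries":
        """Collapse replicates: mean velocity per distinct substrate level."""
        levels = np.unique(self.substrate_conc)
        means = np.array([self.velocity[self.substrate_conc == s].mean() for s in levels])
        return VelocitySeries(
            inhibitor_conc=self.inhibitor_conc, substrate_conc=levels, velocity=means,
            substrate_name=self.substrate_name, inhibitor_name=self.inhibitor_name,
            series_id=self.series_id,
        )

    def subset(self, mask: np.ndarray) -> "VelocitySeries":
        return VelocitySeries(
            inhibitor_conc=self.inhibitor_conc,
            substrate_conc=self.substrate_conc[mask],
            velocity=self.velocity[mask],
            replicate=self.replicate[mask],
            substrate_name=self.substrate_name,
            inhibitor_name=self.inhibitor_name,
            series_id=self.series_id,
        )


@dataclass
class BindingDataset:
    """Percent RNA bound versus protein concentration (band-shift titration)."""

    protein_conc: np.ndarray
    percent_bound: np.ndarray
    replicate: np.ndarray | None = None

    def __post_init__(self):
        self.protein_conc = _as_float(self.protein_conc)
        self.percent_bound = _as_float(self.percent_bound)
        if self.replicate is None:
            self.replicate = np.zeros(len(self.protein_conc), dtype=int)
        else:
            self.replicate = np.atleast_1d(np.asarray(self.replicate, dtype=int))
        if len(self.protein_conc) != len(self.percent_bound):
            raise DomainError("protein_conc and percent_bound must be equal length")
        if np.any(self.protein_conc < 0):
            raise DomainError("protein_conc must be non-negative")

    def __len__(self) -> int:
        return len(self.protein_conc)


@dataclass
class InhibitionDataset:
    """Percent residual activity versus RNA concentration at fixed substrates."""

    inhibitor_conc: np.ndarray
    percent_activity: np.ndarray
    replicate: np.ndarray | None = None
    inhibitor_name: str = "RNA"

    def __post_init__(self):
        self.inhibitor_conc = _as_float(self.inhibitor_conc)
        self.percent_activity = _as_float(self.percent_activity)
        if self.replicate is None:
            self.replicate = np.zeros(len(self.inhibitor_conc), dtype=int)
        else:
            self.replicate = np.atleast_1d(np.asarray(self.replicate, dtype=int))
        if len(self.inhibitor_conc) != len(self.percent_activity):
            raise DomainError("inhibitor_conc and percent_activity must be equal length")
        if np.any(self.inhibitor_conc < 0):
            raise DomainError("inhibitor_conc must be non-negative")

    def __len__(self) -> int:
        return len(self.inhibitor_conc)
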