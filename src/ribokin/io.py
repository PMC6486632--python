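"""CSV schemas, run configuration and JSON result serialisation.

Three plain-text table schemas tie the pipeline together (UTF-8, decimal
point, exact headers):

velocity table
    ``series_id, inhibitor_name, inhibitor_conc_uM, substrate_name,
    substrate_conc_uM, replicate, velocity``
binding table
    ``protein_conc_uM, replicate, percent_bound``
inhibition table
    ``inhibitor_name, inhibitor_conc_uM, replicate, percent_activity``

Machine-readable results are JSON with a provenance block (package
version, config hash, seed); run configurations are flat ``key = value``
text files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data import BindingDataset, InhibitionDataset, VelocitySeries
from .errors import SchemaError
from .fitting import FitResult

__all__ = [
    "VELOCITY_COLUMNS", "BINDING_COLUMNS", "INHIBITION_COLUMNS",
    "read_velocity_table", "write_velocity_table",
    "read_binding_table", "write_binding_table",
    "read_inhibition_table", "write_inhibition_table",
    "RunConfig", "read_config", "result_to_dict", "write_result_json",
]

VELOCITY_COLUMNS = ["series_id", "inhibitor_name", "inhibitor_conc_uM",
                    "substrate_name", "substrate_conc_uM", "replicate", "velocity"]
BINDING_COLUMNS = ["protein_conc_uM", "replicate", "percent_bound"]
INHIBITION_COLUMNS = ["inhibitor_name", "inhibitor_conc_uM", "replicate",
                      "percent_activity"]


def _read_checked(path, columns, numeric) -> pd.DataFrame:
    # round_trip parsing so written files read back bit-identically
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise SchemaError(
                f"{path}: non-numeric value in column {col!r} at data row {bad[0] + 1}")
        if coerced.isna().any():
            raise SchemaError(f"{path}: empty cell in column {col!r}")
        df[col] = coerced
    neg = [c for c in numeric if c.endswith("_uM") and (df[c] < 0).any()]
    if neg:
        raise SchemaError(f"{path}: negative concentrations in {neg}")
    return df[columns]


def read_velocity_table(path) -> list[VelocitySeries]:
    """Parse a velocity CSV into one series per inhibitor concentration."""
    df = _read_checked(path, VELOCITY_COLUMNS,
                       ["inhibitor_conc_uM", "substrate_conc_uM", "replicate", "velocity"])
    out = []
    for (i_conc, sid), grp in df.groupby(["inhibitor_conc_uM", "series_id"], sort=True):
        out.append(VelocitySeries(
            inhibitor_conc=float(i_conc),
            substrate_conc=grp["substrate_conc_uM"].to_numpy(),
            velocity=grp["velocity"].to_numpy(),
            replicate=grp["replicate"].to_numpy(dtype=int),
            substrate_name=str(grp["substrate_name"].iloc[0]),
            inhibitor_name=str(grp["inhibitor_name"].iloc[0]),
            series_id=str(sid)))
    return out


def write_velocity_table(series_set: list[VelocitySeries], path) -> None:
    rows = []
    for ser in series_set:
        for s, r, v in zip(ser.substrate_conc, ser.replicate, ser.velocity):
            rows.append({
                "series_id": ser.series_id or f"I={ser.inhibitor_conc:g}",
                "inhibitor_name": ser.inhibitor_name,
                "inhibitor_conc_uM": ser.inhibitor_conc,
                "substrate_name": ser.substrate_name,
                "substrate_conc_uM": s, "replicate": int(r), "velocity": v})
    pd.DataFrame(rows, columns=VELOCITY_COLUMNS).to_csv(path, index=False)


def read_binding_table(path) -> BindingDataset:
    df = _read_checked(path, BINDING_COLUMNS, BINDING_COLUMNS)
    return BindingDataset(protein_conc=df["protein_conc_uM"].to_numpy(),
                          percent_bound=df["percent_bound"].to_numpy(),
                          replicate=df["replicate"].to_numpy(dtype=int))


def write_binding_table(data: BindingDataset, path) -> None:
    pd.DataFrame({
        "protein_conc_uM": data.protein_conc,
        "replicate": data.replicate.astype(int),
        "percent_bound": data.percent_bound,
    }).to_csv(path, index=False)


def read_inhibition_table(path) -> InhibitionDataset:
    df = _read_checked(path, INHIBITION_COLUMNS,
                       ["inhibitor_conc_uM", "replicate", "percent_activity"])
    return InhibitionDataset(inhibitor_conc=df["inhibitor_conc_uM"].to_numpy(),
                             percent_activity=df["percent_activity"].to_numpy(),
                             replicate=df["replicate"].to_numpy(dtype=int),
                             inhibitor_name=str(df["inhibitor_name"].iloc[0])
                             if len(df) else "RNA")


def write_inhibition_table(data: InhibitionDataset, path) -> None:
    pd.DataFrame({
        "inhibitor_name": data.inhibitor_name,
        "inhibitor_conc_uM": data.inhibitor_conc,
        "replicate": data.replicate.astype(int),
        "percent_activity": data.percent_activity,
    }, columns=INHIBITION_COLUMNS).to_csv(path, index=False)


@dataclass
class RunConfig:
    """Flat configuration for a simulate/fit run (``key = value`` file)."""

    model: str = "eq4"
    design: str = "thf-inhibitor-grid"
    seed: int = 0
    cv: float | None = None
    replicates: int | None = None
    bootstrap: int = 0
    truth: dict = field(default_factory=dict)
    out_dir: str = "."

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha1(payload).hexdigest()[:12]


_TRUTH_KEYS = {"vmax", "km", "ki_thf", "ki", "alpha", "kd_app", "bmax", "ic50"}


def read_config(path) -> RunConfig:
    """Parse a ``key = value`` run configuration file. Unknown keys raise;
    truth parameters (vmax, km, ki, ...) are collected into ``truth``."""
    cfg = RunConfig()
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise SchemaError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        if key in _TRUTH_KEYS:
            cfg.truth[key] = float(value)
        elif key in ("model", "design", "out_dir"):
            setattr(cfg, key, value)
        elif key in ("seed", "bootstrap", "replicates"):
            setattr(cfg, key, int(value))
        elif key == "cv":
            cfg.cv = float(value)
        else:
            raise SchemaError(f"{path}:{lineno}: unknown key {key!r}")
    return cfg


def result_to_dict(result: FitResult, seed: int | None = None,
                   config_hash: str = "") -> dict:
    """JSON-ready dict for a fit result, with a provenance block."""
    d = {
        "model": result.model,
        "params": {k: float(v) for k, v in result.params.items()},
        "stderr": {k: (float(v) if np.isfinite(v) else None)
                   for k, v in result.stderr.items()},
        "rss": float(result.rss),
        "n_points": result.n_points,
        "n_params": result.n_params,
        "converged": result.converged,
        "aicc": float(result.aicc()) if np.isfinite(result.aicc()) else None,
        "warnings": list(result.warnings),
        "provenance": {
            "package": "ribokin",
            "version": __version__,
            "seed": seed if seed is not None else result.seed,
            "config_hash": config_hash,
        },
    }
    if result.ci:
        d["ci95"] = {k: [float(lo), float(hi)] for k, (lo, hi) in result.ci.items()}
        d["n_resamples"] = result.n_resamples
    return d


def write_result_json(result: FitResult, path, seed: int | None = None,
                      config_hash: str = "") -> None:
    Path(path).write_text(json.dumps(result_to_dict(result, seed, config_hash),
                                     indent=2, sort_keys=True) + "\n")
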