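"""Readers and writers: mixture YAML files, actuator config YAML, trace CSV.

CSV dialect: comma-separated, ``.`` decimal, UTF-8, mandatory header row;
``#``-prefixed provenance comment lines precede the header.
"""

from __future__ import annotations

import hashlib
import io as _io
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .actuator_sim import ActuatorConfig, MembraneSpec, TurgorTrace
from .association import ComplexModel
from .mixtures import MixtureComposition, mixture_from_ratio

__all__ = [
    "packaged_mixture_path",
    "load_mixture_file",
    "load_actuator_config",
    "provenance_lines",
    "write_csv",
    "read_csv",
    "write_trace_csv",
    "read_trace_csv",
]

PathLike = Union[str, Path]


def packaged_mixture_path() -> Path:
    """Path of the packaged mixture fixture file."""
    return Path(resources.files("turgorkit").joinpath("data/mixtures.yaml"))


def load_mixture_file(path: Optional[PathLike] = None) -> list[dict]:
    """Load mixture definitions from YAML.

    Each entry maps to a dict with keys ``mixture`` (MixtureComposition),
    ``measured_MPa``, ``measured_sd_MPa`` and ``estimated_ref_MPa`` (the last
    three optional, ``None`` when absent).
    """
    path = Path(path) if path is not None else packaged_mixture_path()
    doc = yaml.safe_load(path.read_text())
    entries = []
    for item in doc.get("mixtures", []):
        name = item["name"]
        pH = float(item.get("pH", 7.0))
        if "ratio" in item:
            mix = mixture_from_ratio(
                item["ratio"], float(item["total_molarity"]), pH=pH, name=name
            )
        elif "molarities" in item:
            molarities = {k: float(v) for k, v in item["molarities"].items()}
            mix = MixtureComposition(
                species_molarity=molarities,
                total_molarity=float(item.get("total_molarity",
                                              sum(molarities.values()))),
                pH=pH,
                name=name,
            )
        else:
            raise ValueError(f"mixture {name!r} needs 'ratio' or 'molarities'")
        entries.append(
            {
                "mixture": mix,
                "measured_MPa": item.get("measured_MPa"),
                "measured_sd_MPa": item.get("measured_sd_MPa"),
                "estimated_ref_MPa": item.get("estimated_ref_MPa"),
            }
        )
    return entries


def load_actuator_config(path: PathLike) -> ActuatorConfig:
    """Build an :class:`ActuatorConfig` from a YAML file."""
    doc = yaml.safe_load(Path(path).read_text()) or {}
    mem = doc.get("membrane", {})
    membrane_kwargs = {}
    for key, target in (("S_OM", "S_OM"), ("alpha_OM", "alpha_OM")):
        if key in mem:
            membrane_kwargs[target] = float(mem[key])
    for key in ("sigma", "P_s"):
        if key in mem:
            membrane_kwargs[key] = {k: float(v) for k, v in mem[key].items()}
    membrane = MembraneSpec(**membrane_kwargs)
    kwargs = {"membrane": membrane}
    if "V0" in doc:
        kwargs["V_0"] = float(doc["V0"])
    for key in ("k_BD", "P_ref", "piston_area"):
        if key in doc:
            kwargs[key] = float(doc[key])
    if "mode" in doc:
        kwargs["mode"] = str(doc["mode"])
    if "coupling" in doc and doc["coupling"] is not None:
        kwargs["coupling"] = ComplexModel(K_assoc=float(doc["coupling"]["K_assoc"]))
    return ActuatorConfig(**kwargs)


def provenance_lines(seed: Optional[int] = None, **context) -> list[str]:
    """Deterministic ``#``-prefixed provenance header for output files."""
    digest = hashlib.sha1(
        repr(sorted(context.items())).encode()
    ).hexdigest()[:12]
    lines = [f"# turgorkit {__version__}", f"# config_hash: {digest}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    return lines


def write_csv(df: pd.DataFrame, path: PathLike,
              seed: Optional[int] = None, **context) -> None:
    """Write a dataframe as CSV with a provenance comment header."""
    buf = _io.StringIO()
    for line in provenance_lines(seed=seed, **context):
        buf.write(line + "\n")
    df.to_csv(buf, index=False)
    Path(path).write_text(buf.getvalue())


def read_csv(path: PathLike) -> pd.DataFrame:
    """Read a CSV written by :func:`write_csv` (skipping comment lines)."""
    return pd.read_csv(path, comment="#", float_precision="round_trip")


def trace_to_frame(trace: TurgorTrace) -> pd.DataFrame:
    """Trace as a dataframe: time, nondimensional time, volume, pressure, amounts."""
    data = {
        "t_s": trace.time,
        "t_over_ts": trace.t_over_ts
        if trace.t_over_ts is not None
        else np.full_like(trace.time, np.nan),
        "volume_m3": trace.volume,
        "pressure_MPa": trace.pressure / 1e6,
    }
    for sp, amounts in trace.chamber_amounts.items():
        data[f"amount_{sp}_mol"] = amounts
    return pd.DataFrame(data)


def write_trace_csv(trace: TurgorTrace, path: PathLike,
                    seed: Optional[int] = None, **context) -> None:
    write_csv(trace_to_frame(trace), path, seed=seed, **context)


def read_trace_csv(path: PathLike) -> TurgorTrace:
    df = read_csv(path)
    amount_cols = [c for c in df.columns if c.startswith("amount_")]
    t_over = df["t_over_ts"].to_numpy()
    return TurgorTrace(
        time=df["t_s"].to_numpy(),
        volume=df["volume_m3"].to_numpy(),
        pressure=df["pressure_MPa"].to_numpy() * 1e6,
        chamber_amounts={
            c[len("amount_"):-len("_mol")]: df[c].to_numpy() for c in amount_cols
        },
        pi_internal=np.full(len(df), np.nan),
        t_over_ts=None if np.all(np.isnan(t_over)) else t_over,
    )
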