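"""Delimited-text readers/writers for the pipeline's file formats.

Trace files carry the header ``time_s,pressure_kPa,displacement_mm,
extruded_mass_g,temperature_C``; the optional channels may be absent.
Sweep and creep files use ``control,G_prime_Pa,G_double_prime_Pa`` and
``time_s,strain``.  All writers round-trip losslessly through their
readers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import ExtrusionTrace

__all__ = [
    "write_trace",
    "read_trace",
    "write_table",
    "read_table",
    "write_records_json",
]

TRACE_COLUMNS = ["time_s", "pressure_kPa", "displacement_mm",
                 "extruded_mass_g", "temperature_C"]


def write_trace(trace: ExtrusionTrace, path) -> None:
    trace.to_frame().to_csv(path, index=False, float_format="%.6g")


def read_trace(path) -> ExtrusionTrace:
    df = pd.read_csv(path)
    for col in ("time_s", "pressure_kPa", "displacement_mm"):
        if col not in df.columns:
            raise ValueError(f"trace file missing required column {col!r}")
    mass = df["extruded_mass_g"].to_numpy() if "extruded_mass_g" in df.columns else None
    temp = float(df["temperature_C"].iloc[0]) if "temperature_C" in df.columns else 25.0
    return ExtrusionTrace(
        time=df["time_s"].to_numpy(),
        pressure=df["pressure_kPa"].to_numpy(),
        displacement=df["displacement_mm"].to_numpy(),
        extruded_mass=mass,
        temperature_C=temp,
    )


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, index=index)


def read_table(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, index_col=index_col)


def write_records_json(records, path) -> None:
    """Write per-printlet PAT records as a JSON array of objects."""
    payload = [r.to_dict() for r in records]
    Path(path).write_text(json.dumps(payload, indent=1, default=_coerce) + "\n")


def _coerce(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, set):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
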