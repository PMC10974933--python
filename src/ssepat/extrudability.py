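"""Extrudability-profile extraction from plunger pressure-time traces.

Turns a friction-corrected extrusion trace plus the syringe/nozzle geometry
into the standard extrudability feature vector: yield point and yield time,
maximum pressure, pressure at flow cessation, Young modulus (elastic slope
of the pressure-displacement ramp), steady-flow shear stress and rate, and
apparent/dynamic viscosities from capillary-flow relations:

* plunger speed      PDS = TPS * (LH / D)^2
* volumetric flow    Q   = PDS * A_syringe = pi * LH^2 * TPS / 4
* wall shear rate    gamma = 4 Q / (pi r^3)
* dynamic viscosity  mu = F * pi * D_tip^4 / (128 * Q * L * A_syringe)

The steady shear-stress convention is configurable: ``nozzle-area`` divides
the steady plunger force by the nozzle cross-section pi r^2 (default);
``capillary-wall`` uses the wall stress ΔP r / (2 L).  Apparent viscosity is
always stress / shear-rate, so the internal identity
``apparent_viscosity * shear_rate == shear_stress_steady`` holds under
either convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .simulate import ExtrusionTrace, SystemParams, ValidationError

__all__ = [
    "PrintSettings",
    "ProfileConfig",
    "ExtrudabilityProfile",
    "plunger_speed",
    "flow_rate",
    "shear_rate",
    "dynamic_viscosity",
    "baseline_correct",
    "extract_profile",
]


class YieldUndetectedError(RuntimeError):
    """No initial linear region / yield departure could be located."""


@dataclass(frozen=True)
class PrintSettings:
    """Print parameters that set the volumetric demand."""

    target_print_speed: float  # TPS, mm/s
    layer_height: float = 0.61  # LH, mm

    def __post_init__(self) -> None:
        if self.target_print_speed <= 0 or self.layer_height <= 0:
            raise ValidationError("target_print_speed and layer_height must be > 0")


@dataclass(frozen=True)
class ProfileConfig:
    """Detection tolerances for :func:`extract_profile`.

    rel_tol : relative departure from the initial linear fit that marks the
        yield point (fraction of the fitted value).
    r2_min : minimum R^2 the expanding-window linear fit must keep.
    steady_frac : final fraction of the compression step averaged as the
        steady-flow window.
    cessation_window : seconds at the end of the post-compression hold
        averaged as the pressure at flow cessation.
    sustain : consecutive samples the departure must persist (noise guard).
    stress_convention : 'nozzle-area' or 'capillary-wall'.
    literal_flow_rate : use the literal reading Q = TPS * (D_syringe / 2)
        instead of the volumetric coupling (compatibility only).
    """

    rel_tol: float = 0.05
    r2_min: float = 0.99
    steady_frac: float = 0.20
    cessation_window: float = 5.0
    min_linear_points: int = 5
    sustain: int = 3
    stress_convention: str = "nozzle-area"
    literal_flow_rate: bool = False

    def __post_init__(self) -> None:
        if self.stress_convention not in ("nozzle-area", "capillary-wall"):
            raise ValidationError("unknown stress_convention")


@dataclass
class ExtrudabilityProfile:
    """Per-run extrudability feature vector."""

    yield_point: float  # kPa
    yield_time: float  # s
    max_pressure: float  # kPa
    pressure_flow_cessation: float  # kPa
    young_modulus: float  # kPa/mm
    shear_stress_steady: float  # kPa
    shear_rate: float  # 1/s
    apparent_viscosity: float  # kPa.s
    dynamic_viscosity: float  # Pa.s
    plunger_speed: float  # mm/s
    flow_rate: float  # mm^3/s

    def to_series(self) -> pd.Series:
        return pd.Series(asdict(self))


def plunger_speed(settings: PrintSettings, syringe_diameter: float) -> float:
    """Plunger displacement speed ``PDS = TPS * (LH / D)^2`` in mm/s."""
    if syringe_diameter <= 0:
        raise ValidationError("syringe_diameter must be > 0")
    return settings.target_print_speed * (settings.layer_height / syringe_diameter) ** 2


def flow_rate(settings: PrintSettings, syringe_diameter: float = 19.3,
              literal: bool = False) -> float:
    """Volumetric flow demand in mm^3/s.

    Default: plunger speed times syringe cross-section, which reduces to
    ``pi * LH^2 * TPS / 4`` and is independent of the syringe diameter.
    ``literal=True`` applies the (dimensionally inconsistent) shorthand of
    print speed times syringe radius instead; it exists only for
    compatibility with legacy spreadsheets.
    """
    if literal:
        return settings.target_print_speed * syringe_diameter / 2.0
    return math.pi * settings.layer_height**2 * settings.target_print_speed / 4.0


def shear_rate(Q: float, nozzle_radius: float) -> float:
    """Wall shear rate in a capillary, ``4 Q / (pi r^3)``, 1/s."""
    if nozzle_radius <= 0:
        raise ValidationError("nozzle_radius must be > 0")
    if Q < 0:
        raise ValidationError("Q must be >= 0")
    return 4.0 * Q / (math.pi * nozzle_radius**3)


def dynamic_viscosity(steady_force: float, Q: float, nozzle_length: float,
                      nozzle_diameter: float, syringe_area: float) -> float:
    """Dynamic viscosity from the capillary force balance, Pa.s.

    Inverts ``F = 128 Q mu L A / (pi D^4)`` (force in N, lengths in mm,
    Q in mm^3/s); the N/mm^2 result is converted to Pa.s.
    """
    if steady_force < 0:
        raise ValidationError("steady_force must be >= 0")
    for name, v in (("Q", Q), ("nozzle_length", nozzle_length),
                    ("nozzle_diameter", nozzle_diameter), ("syringe_area", syringe_area)):
        if v <= 0:
            raise ValidationError(f"{name} must be > 0")
    mu = steady_force * math.pi * nozzle_diameter**4 / (128.0 * Q * nozzle_length * syringe_area)
    return mu * 1.0e6  # N/mm^2 * s -> Pa.s


def baseline_correct(trace: ExtrusionTrace, baseline: ExtrusionTrace,
                     duration_tol: float = 0.05) -> ExtrusionTrace:
    """Subtract a friction-only baseline run from the measured pressure.

    The baseline pressure is interpolated onto the trace's time grid and
    subtracted, clipping at zero; all other channels pass through.  The two
    runs must come from the same protocol: their durations may differ by at
    most ``duration_tol`` (fractional).
    """
    d_t, d_b = trace.time[-1], baseline.time[-1]
    if abs(d_t - d_b) > duration_tol * max(d_t, d_b):
        raise ValidationError(
            f"baseline protocol mismatch: trace duration {d_t:.1f}s vs baseline {d_b:.1f}s"
        )
    base_p = np.interp(trace.time, baseline.time, baseline.pressure)
    corrected = np.clip(trace.pressure - base_p, 0.0, None)
    return ExtrusionTrace(
        time=trace.time.copy(),
        pressure=corrected,
        displacement=trace.displacement.copy(),
        extruded_mass=None if trace.extruded_mass is None else trace.extruded_mass.copy(),
        temperature_C=trace.temperature_C,
        metadata={**trace.metadata, "baseline_corrected": True},
        internal_pressure=trace.internal_pressure,
    )


def _compression_and_hold(trace: ExtrusionTrace) -> tuple[slice, slice]:
    """Locate the leading compression step and the following hold.

    The plunger velocity is reconstructed from the displacement channel;
    the compression step is the initial contiguous forward-motion run and
    the hold everything after it up to the first backward motion (or the
    end of the trace).
    """
    vel = np.gradient(trace.displacement, trace.time)
    vmax = float(np.max(vel)) if len(vel) else 0.0
    if vmax <= 0:
        raise ValidationError("trace contains no forward compression step")
    thr = 0.1 * vmax
    moving = vel > thr
    start = int(np.argmax(moving))
    stop = start
    while stop < len(vel) and moving[stop]:
        stop += 1
    hold_stop = stop
    while hold_stop < len(vel) and vel[hold_stop] > -thr:
        hold_stop += 1
    if hold_stop <= stop:
        raise ValidationError("no hold step follows the compression step")
    return slice(start, stop), slice(stop, hold_stop)


def _expanding_linear_fit(x: np.ndarray, y: np.ndarray, r2_min: float,
                          min_pts: int, rel_tol: float
                          ) -> tuple[int, float, float]:
    """Longest prefix window keeping R^2 >= r2_min; returns (end, slope, intercept).

    Uses O(n) cumulative sums; the window grows from ``min_pts`` and the
    largest admissible end index wins (maximal linear region).  Because R^2
    alone barely reacts when the window creeps past the yield bend, the
    window is then trimmed backwards while its own last sample deviates
    from the window's fit by more than ``rel_tol`` (relative).
    """
    n = len(x)
    if n < min_pts:
        raise YieldUndetectedError("too few samples for a linear fit")
    cx, cy = np.cumsum(x), np.cumsum(y)
    cxx, cyy, cxy = np.cumsum(x * x), np.cumsum(y * y), np.cumsum(x * y)
    k = np.arange(1, n + 1, dtype=float)
    sxx = cxx - cx**2 / k
    syy = cyy - cy**2 / k
    sxy = cxy - cx * cy / k
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where((sxx > 0) & (syy > 0), sxy**2 / (sxx * syy), 0.0)
    ok = np.nonzero(r2[min_pts - 1:] >= r2_min)[0]
    if len(ok) == 0:
        raise YieldUndetectedError("no initial linear region with sufficient R^2")
    end = int(ok[-1]) + min_pts  # exclusive end index

    def fit(m: int) -> tuple[float, float]:
        slope = sxy[m - 1] / sxx[m - 1]
        return float(slope), float((cy[m - 1] - slope * cx[m - 1]) / m)

    slope, intercept = fit(end)
    while end > min_pts:
        pred = slope * x[end - 1] + intercept
        if abs(y[end - 1] - pred) <= rel_tol * abs(pred):
            break
        end -= 1
        slope, intercept = fit(end)
    return end, slope, intercept


def extract_profile(
    trace: ExtrusionTrace,
    system: SystemParams,
    settings: PrintSettings,
    config: ProfileConfig | None = None,
) -> ExtrudabilityProfile:
    """Extract the extrudability feature vector from a compression run.

    The trace must contain a forward compression step followed by a hold.
    The yield point is the pressure where the pressure-displacement curve
    first departs from its initial linear fit by more than ``rel_tol``
    (sustained over ``sustain`` samples); the linear region is found by an
    expanding-window regression keeping R^2 >= ``r2_min`` and its slope is
    the Young modulus (kPa/mm).  Steady flow is averaged over the last
    ``steady_frac`` of the compression step and the flow-cessation pressure
    over the final ``cessation_window`` seconds of the hold.
    """
    cfg = config or ProfileConfig()
    comp, hold = _compression_and_hold(trace)
    t = trace.time[comp]
    p = trace.pressure[comp]
    x = trace.displacement[comp]

    end, slope, intercept = _expanding_linear_fit(x, p, cfg.r2_min,
                                                  cfg.min_linear_points, cfg.rel_tol)
    pred = slope * x + intercept
    dev = np.abs(p - pred) > cfg.rel_tol * np.abs(pred)
    dev[:end] = False
    # sustained departure: first index where `sustain` consecutive samples deviate
    idx = None
    run = 0
    for i in range(end, len(dev)):
        run = run + 1 if dev[i] else 0
        if run >= cfg.sustain:
            idx = i - cfg.sustain + 1
            break
    if idx is None:
        raise YieldUndetectedError("yield undetected: no sustained departure from linearity")

    yield_point = float(p[idx])
    yield_time = float(t[idx])
    max_pressure = float(np.max(p))

    n_steady = max(2, int(round(cfg.steady_frac * len(p))))
    steady_pressure = float(np.mean(p[-n_steady:]))
    steady_force = steady_pressure * system.syringe_area / 1000.0  # N

    t_hold = trace.time[hold]
    p_hold = trace.pressure[hold]
    in_win = t_hold >= t_hold[-1] - cfg.cessation_window
    pressure_flow_cessation = float(np.mean(p_hold[in_win]))

    pds = plunger_speed(settings, system.syringe_inner_diameter)
    Q = flow_rate(settings, system.syringe_inner_diameter, literal=cfg.literal_flow_rate)
    gamma = shear_rate(Q, system.nozzle_radius)

    if cfg.stress_convention == "nozzle-area":
        nozzle_area = math.pi * system.nozzle_radius**2
        stress = steady_force / nozzle_area * 1000.0  # N/mm^2 -> kPa
    else:  # capillary-wall
        stress = steady_pressure * system.nozzle_radius / (2.0 * system.nozzle_length)

    apparent = stress / gamma if gamma > 0 else float("nan")  # kPa.s
    mu = dynamic_viscosity(steady_force, Q, system.nozzle_length,
                           system.nozzle_inner_diameter, system.syringe_area)

    return ExtrudabilityProfile(
        yield_point=yield_point,
        yield_time=yield_time,
        max_pressure=max_pressure,
        pressure_flow_cessation=pressure_flow_cessation,
        young_modulus=slope,
        shear_stress_steady=stress,
        shear_rate=gamma,
        apparent_viscosity=apparent,
        dynamic_viscosity=mu,
        plunger_speed=pds,
        flow_rate=Q,
    )
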