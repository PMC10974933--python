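"""Physics-based synthetic data for the semi-solid-extrusion (SSE) pipeline.

This module stands in for the instrumented hardware: the pressure-sensing
motor-driven printhead, the oscillatory rheometer, and the camera used for
batch imaging.  Every downstream stage (extrudability profiling, PAT
reporting, quality control) consumes data generated here from known
ground-truth parameters, which makes the whole pipeline testable end to end.

Extrusion model
---------------
The syringe content is treated as a quasi-static pressurized reservoir:

* inflow  ``Q_in = plunger_speed * A_syringe``  (mm^3/s)
* the internal pressure integrates ``dP/dt = (Q_in - Q_out) / compliance``
* outflow is zero until the internal pressure exceeds the yield pressure,
  then follows Herschel-Bulkley capillary flow through the nozzle: the wall
  shear stress is ``tau_w = P * r / (2 L)``, the yield contribution is
  subtracted, and the excess drives a power-law Rabinowitsch flow
  ``Q_out = pi r^3 (n / (3n+1)) * ((tau_w - tau_y) / K)^(1/n)``.

For a Newtonian fluid (``n = 1``, zero yield) the steady state reduces
exactly to Hagen-Poiseuille, which the tests use as an independent oracle.

The measured channel adds a constant plunger-friction baseline
(``friction_force / A_syringe``) and Gaussian sensor noise; the noise-free
internal pressure is kept on the trace so that baseline correction can be
validated against it.

Units: mm, s, N and kPa internally; the Herschel-Bulkley consistency is in
Pa.s^n and wall stresses are converted to Pa before applying it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "FluidParams",
    "SystemParams",
    "ProtocolStep",
    "PlungerProtocol",
    "ExtrusionTrace",
    "EventSpec",
    "GelParams",
    "BurgersParams",
    "simulate_extrusion_trace",
    "simulate_print_run",
    "simulate_rheometer",
    "render_batch_image",
]


class ValidationError(ValueError):
    """Raised when simulator parameters are non-physical."""


@dataclass(frozen=True)
class FluidParams:
    """Herschel-Bulkley description of a semi-solid printing mass.

    yield_pressure : plunger pressure at flow onset, kPa.  The equivalent
        wall yield stress is ``yield_pressure * r / (2 L)``.
    consistency_K : Pa.s^n
    flow_index_n : shear-thinning exponent (n < 1 thins with rate)
    density : g/mm^3
    """

    yield_pressure: float = 400.0
    consistency_K: float = 5.0
    flow_index_n: float = 0.4
    density: float = 1.2e-3

    def __post_init__(self) -> None:
        if self.yield_pressure < 0:
            raise ValidationError("yield_pressure must be >= 0")
        if self.consistency_K <= 0:
            raise ValidationError("consistency_K must be > 0")
        if not 0 < self.flow_index_n <= 1.5:
            raise ValidationError("flow_index_n must be in (0, 1.5]")
        if self.density <= 0:
            raise ValidationError("density must be > 0")


@dataclass(frozen=True)
class SystemParams:
    """Geometry and parasitics of the syringe / nozzle / sensor assembly.

    Defaults follow the 20 mL Luer-Lock syringe with a 20-gauge tapered
    nozzle used throughout: 19.3 mm syringe bore, 0.61 mm nozzle bore,
    25 mm wetted nozzle length.
    """

    syringe_inner_diameter: float = 19.3  # mm
    nozzle_inner_diameter: float = 0.61  # mm
    nozzle_length: float = 25.0  # mm
    compliance: float = 0.8  # mm^3/kPa, mass + syringe + plunger seal
    friction_force: float = 2.0  # N, plunger-barrel sliding friction
    noise_sd: float = 3.0  # kPa additive sensor noise
    temperature_C: float = 25.0

    def __post_init__(self) -> None:
        for name in ("syringe_inner_diameter", "nozzle_inner_diameter", "nozzle_length"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.compliance <= 0:
            raise ValidationError("compliance must be > 0")
        if self.friction_force < 0:
            raise ValidationError("friction_force must be >= 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")

    @property
    def syringe_area(self) -> float:
        """Syringe cross-sectional area, mm^2."""
        return math.pi * self.syringe_inner_diameter**2 / 4.0

    @property
    def nozzle_radius(self) -> float:
        return self.nozzle_inner_diameter / 2.0

    @property
    def friction_pressure(self) -> float:
        """Friction baseline expressed as pressure, kPa (N/mm^2 -> kPa)."""
        return 1000.0 * self.friction_force / self.syringe_area


@dataclass(frozen=True)
class ProtocolStep:
    """One plunger step: either a travel at constant speed or a hold.

    Exactly one of ``distance`` (mm, for ``speed != 0``) and
    ``hold_duration`` (s, for ``speed == 0``) must be given.
    """

    speed: float  # mm/s, signed (negative = retraction)
    distance: float | None = None
    hold_duration: float | None = None

    def __post_init__(self) -> None:
        if (self.distance is None) == (self.hold_duration is None):
            raise ValidationError("step needs exactly one of distance / hold_duration")
        if self.distance is not None:
            if self.speed == 0:
                raise ValidationError("distance step requires non-zero speed")
            if self.distance <= 0:
                raise ValidationError("distance must be > 0")
        if self.hold_duration is not None and self.hold_duration <= 0:
            raise ValidationError("hold_duration must be > 0")

    @property
    def duration(self) -> float:
        if self.hold_duration is not None:
            return self.hold_duration
        return abs(self.distance / self.speed)


@dataclass(frozen=True)
class PlungerProtocol:
    """Ordered plunger steps plus the sampling rate of the pressure record."""

    steps: tuple[ProtocolStep, ...]
    sampling_rate: float = 10.0  # Hz

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValidationError("protocol needs at least one step")
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be > 0")
        object.__setattr__(self, "steps", tuple(self.steps))

    @property
    def duration(self) -> float:
        return sum(s.duration for s in self.steps)

    @classmethod
    def compression_cycle(
        cls,
        target_print_speed: float,
        layer_height: float = 0.61,
        syringe_diameter: float = 19.3,
        travel: float = 5.0,
        hold: float = 60.0,
        retract_factor: float = 10.0,
        sampling_rate: float = 10.0,
    ) -> "PlungerProtocol":
        """Four-step compression/shrinkage cycle used for characterization.

        Compression at the plunger speed implied by the target print speed
        (``TPS * (LH/D)^2``), a hold, a 10x-faster retraction over the same
        travel, and a final hold.
        """
        pds = target_print_speed * (layer_height / syringe_diameter) ** 2
        return cls(
            steps=(
                ProtocolStep(speed=pds, distance=travel),
                ProtocolStep(speed=0.0, hold_duration=hold),
                ProtocolStep(speed=-retract_factor * pds, distance=travel),
                ProtocolStep(speed=0.0, hold_duration=hold),
            ),
            sampling_rate=sampling_rate,
        )


@dataclass(frozen=True)
class EventSpec:
    """A transient process upset injected into a simulation.

    ``clog``: the nozzle radius is reduced by ``magnitude`` (fraction of the
    radius, 0 < magnitude <= 1) over the window -- observed as a pressure rise.
    ``bubble``: the volumetric compliance is multiplied by ``1 + magnitude``
    over the window, with stored volume conserved at onset, so the pressure
    drops by ``1/(1+magnitude)`` and then recovers -- observed as a dip.
    """

    kind: str
    onset_time: float
    magnitude: float
    duration: float

    def __post_init__(self) -> None:
        if self.kind not in ("bubble", "clog"):
            raise ValidationError("event kind must be 'bubble' or 'clog'")
        if self.kind == "clog" and not 0 < self.magnitude <= 1:
            raise ValidationError("clog magnitude must be in (0, 1]")
        if self.kind == "bubble" and self.magnitude <= 0:
            raise ValidationError("bubble magnitude must be > 0")
        if self.duration <= 0:
            raise ValidationError("event duration must be > 0")


@dataclass
class ExtrusionTrace:
    """Sampled record from a (simulated) instrumented printhead.

    ``pressure`` is the measured channel (internal pressure + friction
    baseline + noise); ``internal_pressure`` is the friction- and noise-free
    ground truth the simulator integrated, kept for validation.
    """

    time: np.ndarray  # s, strictly increasing
    pressure: np.ndarray  # kPa, measured
    displacement: np.ndarray  # mm, plunger travel
    extruded_mass: np.ndarray | None = None  # g, cumulative
    temperature_C: float = 25.0
    metadata: dict = field(default_factory=dict)
    internal_pressure: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        self.displacement = np.asarray(self.displacement, dtype=float)
        n = len(self.time)
        if len(self.pressure) != n or len(self.displacement) != n:
            raise ValidationError("trace channels must have equal length")
        if n > 1 and not np.all(np.diff(self.time) > 0):
            raise ValidationError("time must be strictly increasing")
        if self.extruded_mass is not None:
            self.extruded_mass = np.asarray(self.extruded_mass, dtype=float)
            if len(self.extruded_mass) != n:
                raise ValidationError("extruded_mass length mismatch")
            if n > 1 and np.any(np.diff(self.extruded_mass) < -1e-12):
                raise ValidationError("extruded_mass must be non-decreasing")

    def __len__(self) -> int:
        return len(self.time)

    @property
    def sampling_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.time)))

    def to_frame(self) -> pd.DataFrame:
        data = {
            "time_s": self.time,
            "pressure_kPa": self.pressure,
            "displacement_mm": self.displacement,
        }
        if self.extruded_mass is not None:
            data["extruded_mass_g"] = self.extruded_mass
        data["temperature_C"] = np.full(len(self.time), self.temperature_C)
        return pd.DataFrame(data)


def _hb_outflow(pressure_kpa: float, radius: float, length: float, tau_y: float,
                K: float, n: float) -> float:
    """Herschel-Bulkley capillary outflow, mm^3/s, for internal pressure in kPa."""
    if pressure_kpa <= 0:
        return 0.0
    tau_w = pressure_kpa * 1000.0 * radius / (2.0 * length)  # Pa
    if tau_w <= tau_y:
        return 0.0
    gamma_w = ((tau_w - tau_y) / K) ** (1.0 / n)
    return math.pi * radius**3 * (n / (3.0 * n + 1.0)) * gamma_w


def _speed_samples(protocol: PlungerProtocol) -> np.ndarray:
    """Per-sample plunger speed at the protocol's sampling rate."""
    fs = protocol.sampling_rate
    chunks = []
    for step in protocol.steps:
        k = max(1, int(round(step.duration * fs)))
        chunks.append(np.full(k, step.speed))
    return np.concatenate(chunks)


def _integrate(
    fluid: FluidParams | None,
    system: SystemParams,
    speeds: np.ndarray,
    fs: float,
    events: list[EventSpec],
    rng: np.random.Generator,
    temperature_C: float | None,
):
    """Core quasi-static integrator shared by all extrusion simulations."""
    n = len(speeds)
    dt = 1.0 / fs
    t = np.arange(1, n + 1) * dt
    displacement = np.cumsum(speeds) * dt

    # Per-sample event modifiers.
    radius_scale = np.ones(n)
    comp_scale = np.ones(n)
    for ev in events or []:
        i0 = int(np.searchsorted(t, ev.onset_time))
        i1 = int(np.searchsorted(t, ev.onset_time + ev.duration))
        if ev.kind == "clog":
            radius_scale[i0:i1] *= 1.0 - ev.magnitude
        else:
            comp_scale[i0:i1] *= 1.0 + ev.magnitude

    internal = np.zeros(n)
    mass = np.zeros(n)
    if fluid is not None:
        r0 = system.nozzle_radius
        L = system.nozzle_length
        tau_y = fluid.yield_pressure * 1000.0 * r0 / (2.0 * L)  # Pa
        area = system.syringe_area
        P = 0.0
        m = 0.0
        prev_comp = system.compliance
        for i in range(n):
            comp = system.compliance * comp_scale[i]
            if comp > prev_comp:
                # bubble onset: stored volume conserved, pressure drops
                P *= prev_comp / comp
            prev_comp = comp
            q_in = speeds[i] * area
            q_out = _hb_outflow(P, r0 * radius_scale[i], L, tau_y,
                                fluid.consistency_K, fluid.flow_index_n)
            P = max(P + (q_in - q_out) * dt / comp, 0.0)
            m += fluid.density * q_out * dt
            internal[i] = P
            mass[i] = m

    measured = internal + system.friction_pressure
    if system.noise_sd > 0:
        measured = measured + rng.normal(0.0, system.noise_sd, size=n)

    return ExtrusionTrace(
        time=t,
        pressure=measured,
        displacement=displacement,
        extruded_mass=mass if fluid is not None else np.zeros(n),
        temperature_C=system.temperature_C if temperature_C is None else temperature_C,
        internal_pressure=internal,
    )


def simulate_extrusion_trace(
    fluid: FluidParams | None,
    system: SystemParams,
    protocol: PlungerProtocol,
    events: list[EventSpec] | None = None,
    seed: int = 0,
) -> ExtrusionTrace:
    """Simulate a plunger-driven extrusion run.

    ``fluid=None`` runs an empty-syringe friction baseline: the measured
    channel is the friction pressure plus noise and nothing is extruded.
    Identical seeds and parameters give bit-identical traces.
    """
    rng = np.random.default_rng(seed)
    speeds = _speed_samples(protocol)
    trace = _integrate(fluid, system, speeds, protocol.sampling_rate,
                       events or [], rng, None)
    trace.metadata = {"seed": seed, "kind": "protocol"}
    return trace


def simulate_print_run(
    fluid: FluidParams,
    system: SystemParams,
    timeline,
    layer_height: float = 0.61,
    events: list[EventSpec] | None = None,
    seed: int = 0,
) -> ExtrusionTrace:
    """Simulate the pressure record of a whole batch print.

    The commanded nozzle speed of the motion timeline is converted to a
    plunger speed through the volumetric coupling ``PDS = TPS * (LH/D)^2``
    (zero during travel moves), and the same quasi-static integrator as
    :func:`simulate_extrusion_trace` is run over it.  The returned trace
    shares the timeline's time base, so PAT segmentation needs no offset.
    """
    rng = np.random.default_rng(seed)
    samples = timeline.samples
    ratio = (layer_height / system.syringe_inner_diameter) ** 2
    speeds = np.where(samples["extruding"].to_numpy(),
                      samples["speed_mm_s"].to_numpy() * ratio, 0.0)
    fs = timeline.sampling_rate
    trace = _integrate(fluid, system, speeds, fs, events or [], rng, None)
    trace.metadata = {"seed": seed, "kind": "print_run", "layer_height": layer_height}
    return trace


# ---------------------------------------------------------------------------
# Rheometer emulation


@dataclass(frozen=True)
class GelParams:
    """Parameters of the synthetic gel used for oscillatory sweeps.

    The frequency sweep is a weak power law ``G' = G0 * f^a`` with
    ``G'' = loss_ratio * G'`` (parallel on log axes, gel-like when
    loss_ratio < 1).  The amplitude sweep keeps a G' plateau and decays past
    a characteristic stress ``tau_c``; G'' decays with half the exponent so
    the two moduli cross above ``tau_c`` (the flow point).
    """

    plateau_modulus: float = 2.0e4  # Pa
    frequency_exponent: float = 0.05
    loss_ratio: float = 0.3
    char_stress: float = 1000.0  # Pa
    decay_exponent: float = 4.0

    def __post_init__(self) -> None:
        if self.plateau_modulus <= 0:
            raise ValidationError("plateau_modulus must be > 0")
        if self.loss_ratio <= 0:
            raise ValidationError("loss_ratio must be > 0")
        if self.char_stress <= 0 or self.decay_exponent <= 0:
            raise ValidationError("char_stress and decay_exponent must be > 0")


@dataclass(frozen=True)
class BurgersParams:
    """Burgers (Maxwell + Kelvin-Voigt in series) creep parameters.

    Creep compliance ``J(t) = 1/E1 + t/eta1 + (1/E2)(1 - exp(-t E2/eta2))``.
    ``eta1=None`` removes the viscous branch (purely elastic + retarded
    recovery, 100% recoverable).
    """

    E1: float = 5.0e4  # Pa, instantaneous modulus
    eta1: float | None = 2.0e6  # Pa.s, steady-flow viscosity
    E2: float = 2.0e5  # Pa, retarded modulus
    eta2: float = 2.0e6  # Pa.s, retardation viscosity

    def __post_init__(self) -> None:
        if self.E1 <= 0 or self.E2 <= 0 or self.eta2 <= 0:
            raise ValidationError("Burgers moduli/viscosities must be > 0")
        if self.eta1 is not None and self.eta1 <= 0:
            raise ValidationError("eta1 must be > 0 or None")

    def compliance(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        tt = np.maximum(t, 0.0)
        J = np.full_like(tt, 1.0 / self.E1)
        if self.eta1 is not None:
            J = J + tt / self.eta1
        lam = self.eta2 / self.E2
        J = J + (1.0 / self.E2) * (1.0 - np.exp(-tt / lam))
        return np.where(t < 0, 0.0, J)


def simulate_rheometer(
    gel: GelParams,
    creep: BurgersParams,
    seed: int = 0,
    freq_range: tuple[float, float] = (0.01, 100.0),
    n_freq: int = 31,
    stress_range: tuple[float, float] = (0.2387, 10000.0),
    n_stress: int = 41,
    creep_stress: float = 500.0,
    creep_on: float = 60.0,
    creep_off: float = 60.0,
    n_cycles: int = 3,
    creep_rate: float = 5.0,
    noise_rel: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate a frequency sweep, an amplitude sweep and a creep trace.

    Defaults mirror the characterization protocol: 0.01-100 Hz frequency
    sweep, 0.2387-10000 Pa amplitude sweep at 1 Hz, and three creep cycles
    of 500 Pa applied for 60 s followed by 60 s of recovery.  Multi-cycle
    creep strain is built by Boltzmann superposition of the Burgers
    compliance, so the analytic unrecovered strain per cycle is
    ``stress * on_time / eta1``.
    """
    rng = np.random.default_rng(seed)

    f = np.logspace(math.log10(freq_range[0]), math.log10(freq_range[1]), n_freq)
    gp = gel.plateau_modulus * f**gel.frequency_exponent
    gpp = gel.loss_ratio * gp
    mult = np.exp(rng.normal(0.0, noise_rel, size=(2, n_freq)))
    freq_sweep = pd.DataFrame(
        {"control": f, "G_prime_Pa": gp * mult[0], "G_double_prime_Pa": gpp * mult[1]}
    )

    tau = np.logspace(math.log10(stress_range[0]), math.log10(stress_range[1]), n_stress)
    x = tau / gel.char_stress
    gp_a = gel.plateau_modulus / (1.0 + x**gel.decay_exponent)
    gpp_a = gel.loss_ratio * gel.plateau_modulus / (1.0 + x ** (gel.decay_exponent / 2.0))
    mult = np.exp(rng.normal(0.0, noise_rel, size=(2, n_stress)))
    amp_sweep = pd.DataFrame(
        {"control": tau, "G_prime_Pa": gp_a * mult[0], "G_double_prime_Pa": gpp_a * mult[1]}
    )

    period = creep_on + creep_off
    total = n_cycles * period
    t = np.arange(0.0, total + 1.0 / creep_rate, 1.0 / creep_rate)
    strain = np.zeros_like(t)
    for k in range(n_cycles):
        strain += creep_stress * creep.compliance(t - k * period)
        strain -= creep_stress * creep.compliance(t - (k * period + creep_on))
    strain *= np.exp(rng.normal(0.0, noise_rel * 0.1, size=t.shape))
    creep_df = pd.DataFrame({"time_s": t, "strain": strain})
    creep_df.attrs["cycles"] = [(k * period, k * period + creep_on) for k in range(n_cycles)]
    creep_df.attrs["applied_stress_Pa"] = creep_stress
    return freq_sweep, amp_sweep, creep_df


# ---------------------------------------------------------------------------
# Batch image rendering


def render_batch_image(
    batch,
    pixel_scale: float = 10.0,
    defects: dict | None = None,
    seed: int = 0,
    margin_mm: float = 5.0,
    noise_sd: float = 5.0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a printlet batch as a grayscale raster plus a ground-truth table.

    Each printlet is a bright disk on a dark background at its batch
    coordinate.  ``defects`` maps printlet id to a dict with optional keys
    ``diameter_offset`` (mm, added to the nominal diameter) and ``notch``
    (``(angle_deg, depth_mm)``: a bite of radius ``depth_mm`` removed at the
    rim, breaking circularity).  The ground truth lists every rendered
    diameter in mm; overlapping disks are recorded as a warning, not an error.
    """
    if pixel_scale <= 0:
        raise ValidationError("pixel_scale must be > 0")
    defects = defects or {}
    rng = np.random.default_rng(seed)

    printlets = list(batch.printlets)
    if not printlets:
        img = np.zeros((int(2 * margin_mm * pixel_scale),) * 2, dtype=np.uint8)
        return img, pd.DataFrame(
            columns=["printlet_id", "cx_mm", "cy_mm", "diameter_mm", "notched", "warning"]
        )

    xs = np.array([p.cx for p in printlets])
    ys = np.array([p.cy for p in printlets])
    radii = np.array(
        [p.radius + defects.get(p.id, {}).get("diameter_offset", 0.0) / 2.0 for p in printlets]
    )
    x0, y0 = xs.min() - margin_mm - radii.max(), ys.min() - margin_mm - radii.max()
    x1, y1 = xs.max() + margin_mm + radii.max(), ys.max() + margin_mm + radii.max()
    w = int(math.ceil((x1 - x0) * pixel_scale))
    h = int(math.ceil((y1 - y0) * pixel_scale))
    yy, xx = np.mgrid[0:h, 0:w]
    xm = xx / pixel_scale + x0
    ym = yy / pixel_scale + y0

    img = np.zeros((h, w), dtype=float)
    rows = []
    for p, r in zip(printlets, radii):
        mask = (xm - p.cx) ** 2 + (ym - p.cy) ** 2 <= r**2
        spec = defects.get(p.id, {})
        notched = False
        if "notch" in spec:
            ang, depth = spec["notch"]
            nx = p.cx + r * math.cos(math.radians(ang))
            ny = p.cy + r * math.sin(math.radians(ang))
            mask &= (xm - nx) ** 2 + (ym - ny) ** 2 > depth**2
            notched = True
        img[mask] = 255.0
        overlap = any(
            (p.cx - q.cx) ** 2 + (p.cy - q.cy) ** 2 < (r + rq) ** 2
            for q, rq in zip(printlets, radii)
            if q.id != p.id
        )
        rows.append(
            {
                "printlet_id": p.id,
                "cx_mm": p.cx,
                "cy_mm": p.cy,
                "diameter_mm": 2.0 * r,
                "notched": notched,
                "warning": "overlap" if overlap else "",
            }
        )
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    img = np.clip(img, 0, 255).astype(np.uint8)
    return img, pd.DataFrame(rows)


def steady_state_pressure(fluid: FluidParams, system: SystemParams,
                          plunger_speed: float) -> float:
    """Analytic steady internal pressure (kPa) at a constant plunger speed.

    Inverts the Herschel-Bulkley capillary law at ``Q = v * A_syringe``;
    this is the value the integrator converges to and serves as the ground
    truth for parameter-recovery tests.
    """
    q = plunger_speed * system.syringe_area
    if q <= 0:
        return 0.0
    r, L = system.nozzle_radius, system.nozzle_length
    n = fluid.flow_index_n
    gamma_w = q / (math.pi * r**3 * n / (3.0 * n + 1.0))
    tau_y = fluid.yield_pressure * 1000.0 * r / (2.0 * L)
    tau_w = tau_y + fluid.consistency_K * gamma_w**n
    return tau_w * 2.0 * L / r / 1000.0
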