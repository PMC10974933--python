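"""Oscillatory-sweep and creep-recovery summaries.

Implements the standard gel characterization workflow: classify gel-like
behaviour from a frequency sweep (G' above G'' and the two moduli parallel
on log-log axes), read yield and flow stresses off an amplitude sweep
(G' leaving its plateau, and the G'/G'' crossover), and reduce a multi-cycle
creep-recovery trace to per-cycle recovery percentages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import ValidationError

__all__ = [
    "OscillatorySweep",
    "CreepTrace",
    "CycleSummary",
    "RheoSummary",
    "classify_gel",
    "amplitude_summary",
    "creep_summary",
]


@dataclass
class OscillatorySweep:
    """One oscillatory sweep: control variable (Hz or Pa) vs G', G''."""

    control: np.ndarray
    G_storage: np.ndarray  # Pa
    G_loss: np.ndarray  # Pa

    def __post_init__(self) -> None:
        self.control = np.asarray(self.control, dtype=float)
        self.G_storage = np.asarray(self.G_storage, dtype=float)
        self.G_loss = np.asarray(self.G_loss, dtype=float)
        n = len(self.control)
        if len(self.G_storage) != n or len(self.G_loss) != n:
            raise ValidationError("sweep channels must have equal length")
        if n < 5:
            raise ValidationError("sweep needs at least 5 points")
        if not np.all(np.diff(self.control) > 0):
            raise ValidationError("control variable must be strictly increasing")
        if np.any(self.G_storage <= 0) or np.any(self.G_loss <= 0):
            raise ValidationError("moduli must be > 0")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "OscillatorySweep":
        return cls(df["control"], df["G_prime_Pa"], df["G_double_prime_Pa"])


@dataclass
class CreepTrace:
    """Strain vs time under cyclic constant-stress loading."""

    time: np.ndarray  # s
    strain: np.ndarray
    cycles: list  # [(on_start, off_start), ...] in s
    applied_stress: float  # Pa

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.strain = np.asarray(self.strain, dtype=float)
        if len(self.time) != len(self.strain):
            raise ValidationError("time/strain length mismatch")
        if not self.cycles:
            raise ValidationError("at least one cycle required")
        flat = [b for pair in self.cycles for b in pair]
        if any(b2 <= b1 for b1, b2 in zip(flat, flat[1:])):
            raise ValidationError("cycle boundaries must be strictly ordered")
        if flat[0] < self.time[0] - 1e-9 or flat[-1] > self.time[-1] + 1e-9:
            raise ValidationError("cycle boundaries outside time range")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CreepTrace":
        return cls(df["time_s"], df["strain"], df.attrs["cycles"],
                   df.attrs.get("applied_stress_Pa", float("nan")))


@dataclass
class CycleSummary:
    cycle: int
    initial_strain: float
    peak_strain: float
    residual_strain: float
    recovered_pct: float
    degenerate: bool = False


@dataclass
class RheoSummary:
    """Reduced rheological characterization of one mass."""

    is_gel: bool | None = None
    storage_slope: float | None = None
    loss_slope: float | None = None
    yield_stress: float | None = None
    flow_stress: float | None = None
    cycles: list = field(default_factory=list)


def classify_gel(freq_sweep: OscillatorySweep, parallel_tol: float = 0.1
                 ) -> tuple[bool, float, float]:
    """Gel classification from a frequency sweep.

    A mass is gel-like when the storage modulus dominates at every
    frequency and the two moduli are parallel on log-log axes: the
    difference of their log-log slopes is within ``parallel_tol``.
    Returns ``(is_gel, slope_G', slope_G'')``.
    """
    lw = np.log10(freq_sweep.control)
    sp = float(np.polyfit(lw, np.log10(freq_sweep.G_storage), 1)[0])
    sl = float(np.polyfit(lw, np.log10(freq_sweep.G_loss), 1)[0])
    dominated = bool(np.all(freq_sweep.G_storage > freq_sweep.G_loss))
    return dominated and abs(sp - sl) <= parallel_tol, sp, sl


def amplitude_summary(amp_sweep: OscillatorySweep, plateau_tol: float = 0.05,
                      plateau_points: int = 5, crossover: str = "interpolated"
                      ) -> tuple[float | None, float | None]:
    """Yield and flow stresses from an amplitude sweep.

    The yield stress is the lowest control stress where G' deviates from
    the plateau median (median of the first ``plateau_points`` values) by
    more than ``plateau_tol``; the flow stress is the stress where G' - G''
    changes sign, located by log-linear interpolation between the
    bracketing points (``crossover='bracket-mean'`` returns the arithmetic
    mean of the bracketing stresses instead).  Either value is ``None``
    when the sweep does not exhibit it.
    """
    gp = amp_sweep.G_storage
    tau = amp_sweep.control
    ref = float(np.median(gp[:plateau_points]))
    if np.any(np.abs(gp[:plateau_points] / ref - 1.0) > plateau_tol):
        raise ValidationError("no initial G' plateau within tolerance")

    dev = np.abs(gp / ref - 1.0) > plateau_tol
    dev[:plateau_points] = dev[:plateau_points] & False
    yield_stress = float(tau[np.argmax(dev)]) if dev.any() else None

    diff = gp - amp_sweep.G_loss
    sign_change = np.nonzero(np.diff(np.sign(diff)) != 0)[0]
    if len(sign_change) == 0:
        flow_stress = None
    else:
        i = int(sign_change[0])
        if crossover == "bracket-mean":
            flow_stress = float(0.5 * (tau[i] + tau[i + 1]))
        else:
            # interpolate log10(tau) where log10(G') == log10(G'')
            d0 = np.log10(gp[i]) - np.log10(amp_sweep.G_loss[i])
            d1 = np.log10(gp[i + 1]) - np.log10(amp_sweep.G_loss[i + 1])
            f = d0 / (d0 - d1)
            lt = np.log10(tau[i]) + f * (np.log10(tau[i + 1]) - np.log10(tau[i]))
            flow_stress = float(10.0**lt)
    return yield_stress, flow_stress


def creep_summary(trace: CreepTrace) -> list[CycleSummary]:
    """Per-cycle creep-recovery statistics.

    For each cycle: the strain at the cycle start, the peak strain at the
    end of loading, the residual strain at the end of recovery, and the
    recovered percentage ``100 * (peak - residual) / (peak - initial)``.
    A cycle whose peak does not exceed its initial strain is flagged
    degenerate (recovery undefined).
    """
    out = []
    t = trace.time
    s = trace.strain

    def before(t_bound: float, default: float) -> float:
        # strain at the last sample strictly before a step boundary, so the
        # instantaneous elastic jump at the boundary itself is not included
        i = int(np.searchsorted(t, t_bound - 1e-12))
        return float(s[i - 1]) if i > 0 else default

    for k, (on_start, off_start) in enumerate(trace.cycles):
        off_end = trace.cycles[k + 1][0] if k + 1 < len(trace.cycles) else t[-1] + 1e-9
        s0 = before(on_start, 0.0)
        in_load = (t >= on_start) & (t < off_start)
        peak = float(np.max(s[in_load])) if in_load.any() else before(off_start, s0)
        resid = before(off_end, s0)
        if peak <= s0:
            out.append(CycleSummary(k, s0, peak, resid, float("nan"), degenerate=True))
            continue
        rec = 100.0 * (peak - resid) / (peak - s0)
        out.append(CycleSummary(k, s0, peak, resid, rec))
    return out
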