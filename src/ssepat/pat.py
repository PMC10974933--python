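"""In-line process-analytical-technology (PAT) stage.

Pairs a plunger pressure trace with the gcode motion timeline, reduces the
print to one quality record per dosage unit (time-weighted mean pressure,
force-time area under the curve, duration, weight when the extruded-mass
channel is present), and flags process upsets: a clog shows as a sustained
pressure rise above the local baseline, entrained air as a sustained drop.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .gcode import MotionTimeline
from .simulate import ExtrusionTrace, ValidationError

__all__ = [
    "Segment",
    "PrintletRecord",
    "AnomalyEvent",
    "segment_by_printlet",
    "printlet_report",
    "batch_report",
    "detect_anomalies",
    "export_scatter",
]


@dataclass(frozen=True)
class Segment:
    """Contiguous run of trace samples attributed to one printlet (or travel)."""

    printlet_id: str | None
    start: int  # sample index, inclusive
    stop: int  # exclusive


@dataclass
class PrintletRecord:
    """Per-dose in-line quality report."""

    printlet_id: str
    x: float
    y: float
    z: float
    assigned_speed: float  # mm/s
    mean_pressure: float  # kPa, time-weighted
    auc: float  # N.s, trapezoidal force-time area
    duration: float  # s
    temperature_C: float
    humidity_pct: float | None = None
    weight: float | None = None  # g
    diameter: float | None = None  # mm
    flags: set = field(default_factory=set)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["flags"] = sorted(self.flags)
        return d


@dataclass
class AnomalyEvent:
    kind: str  # 'clog' | 'air'
    t_start: float
    t_end: float
    peak_deviation: float  # kPa
    printlet_id: str | None = None


def segment_by_printlet(trace: ExtrusionTrace, timeline: MotionTimeline,
                        offset: float = 0.0) -> list[Segment]:
    """Attribute every trace sample to the printlet active at its time.

    Returns contiguous, non-overlapping, exhaustive segments; travel (and
    any trace tail beyond the timeline) is labelled ``None``.  A trace
    shorter than the timeline produces a truncated segmentation and a
    warning in the first segment-free case handled by the caller.
    """
    if len(timeline.moves) == 0:
        return []
    ids = timeline.printlet_at(trace.time - offset)
    if all(i is None for i in ids):
        raise ValidationError("trace and timeline do not overlap")
    segments = []
    start = 0
    for i in range(1, len(ids) + 1):
        if i == len(ids) or ids[i] != ids[start]:
            segments.append(Segment(printlet_id=ids[start], start=start, stop=i))
            start = i
    return segments


def _trapz_mean(t: np.ndarray, y: np.ndarray) -> float:
    if len(t) < 2:
        return float(y[0])
    return float(np.trapezoid(y, t) / (t[-1] - t[0]))


def printlet_report(segment: Segment, trace: ExtrusionTrace,
                    timeline: MotionTimeline, syringe_area: float,
                    humidity_pct: float | None = None) -> PrintletRecord:
    """Reduce one segment to its per-printlet quality record.

    AUC is the trapezoidal integral of force (pressure times syringe
    cross-section, kPa.mm^2/1000 = N) against time; mean pressure is the
    time-weighted mean over the segment.  Segments of fewer than 3 samples
    are flagged ``short_segment`` but still reported.
    """
    if segment.stop <= segment.start:
        raise ValidationError("empty segment")
    sl = slice(segment.start, segment.stop)
    t = trace.time[sl]
    p = trace.pressure[sl]
    flags = set()
    if segment.stop - segment.start < 3:
        flags.add("short_segment")
    force = p * syringe_area / 1000.0  # N
    auc = float(np.trapezoid(force, t)) if len(t) > 1 else 0.0
    duration = float(t[-1] - t[0] + (t[1] - t[0] if len(t) > 1 else 0.0))

    in_seg = (timeline.samples["time_s"].to_numpy() >= t[0]) & (
        timeline.samples["time_s"].to_numpy() <= t[-1]
    )
    sub = timeline.samples[in_seg]
    if len(sub):
        x, y, z = (float(sub[c].mean()) for c in ("x", "y", "z"))
        printing = sub[sub["extruding"]]
        speed = float(printing["speed_mm_s"].mode().iloc[0]) if len(printing) else float("nan")
    else:
        x = y = z = speed = float("nan")

    weight = None
    if trace.extruded_mass is not None:
        m0 = trace.extruded_mass[max(segment.start - 1, 0)]
        weight = float(trace.extruded_mass[segment.stop - 1] - m0)

    return PrintletRecord(
        printlet_id=segment.printlet_id,
        x=x, y=y, z=z,
        assigned_speed=speed,
        mean_pressure=_trapz_mean(t, p),
        auc=auc,
        duration=duration,
        temperature_C=trace.temperature_C,
        humidity_pct=humidity_pct,
        weight=weight,
        flags=flags,
    )


def batch_report(trace: ExtrusionTrace, timeline: MotionTimeline,
                 syringe_area: float, offset: float = 0.0,
                 detect: bool = True, **detect_kwargs) -> list[PrintletRecord]:
    """Segment a whole print and report every printlet, with anomaly flags."""
    segments = segment_by_printlet(trace, timeline, offset=offset)
    records = [
        printlet_report(s, trace, timeline, syringe_area)
        for s in segments
        if s.printlet_id is not None
    ]
    if detect:
        events = detect_anomalies(trace, timeline=timeline, **detect_kwargs)
        by_id = {r.printlet_id: r for r in records}
        for ev in events:
            if ev.printlet_id in by_id:
                by_id[ev.printlet_id].flags.add(ev.kind)
    return records


def detect_anomalies(trace: ExtrusionTrace, window: float = 10.0,
                     k_sigma: float = 4.0, min_duration: float = 1.0,
                     merge_gap: float = 1.0,
                     timeline: MotionTimeline | None = None) -> list[AnomalyEvent]:
    """Flag clog (sustained rise) and air (sustained drop) events.

    A trailing rolling median over ``window`` seconds forms the local
    baseline (trailing, not centered, so that a sustained ramp away from
    the recent past registers as a deviation), and the robust SD is the
    scaled median absolute deviation (1.4826 * MAD) of the whole residual
    series -- the sensor noise floor.  Samples beyond ``k_sigma`` robust
    SDs from the baseline, sustained for at least ``min_duration`` seconds,
    become events; events of the same kind separated by less than
    ``merge_gap`` are merged, and each event is attributed to the printlet
    active at its peak deviation when a timeline is given.
    """
    p = trace.pressure
    if not np.all(np.isfinite(p)):
        bad = int(np.argmax(~np.isfinite(p)))
        raise ValidationError(f"non-finite pressure sample at index {bad}")
    fs = trace.sampling_rate
    if trace.time[-1] <= window:
        raise ValidationError("trace shorter than the detection window")
    w = max(3, int(round(window * fs)))
    med = pd.Series(p).rolling(w, min_periods=1).median().to_numpy()
    resid = p - med
    sd = max(1.4826 * float(np.median(np.abs(resid - np.median(resid)))), 1e-9)
    z = resid / sd

    events: list[AnomalyEvent] = []
    for kind, mask in (("clog", z > k_sigma), ("air", z < -k_sigma)):
        runs = [
            (a, b) for a, b in _runs(mask)
            if trace.time[b - 1] - trace.time[a] >= min_duration
        ]
        merged: list[list[int]] = []
        for a, b in runs:
            if merged and (trace.time[a] - trace.time[merged[-1][1] - 1]) < merge_gap:
                merged[-1][1] = b
            else:
                merged.append([a, b])
        for a, b in merged:
            dev = p[a:b] - med[a:b]
            peak = int(np.argmax(np.abs(dev)))
            ev = AnomalyEvent(
                kind=kind,
                t_start=float(trace.time[a]),
                t_end=float(trace.time[b - 1]),
                peak_deviation=float(abs(dev[peak])),
            )
            if timeline is not None:
                ev.printlet_id = timeline.printlet_at(
                    np.array([trace.time[a + peak]])
                )[0]
            events.append(ev)
    events.sort(key=lambda e: e.t_start)
    return events


def _runs(mask: np.ndarray) -> list:
    """(start, stop) index pairs of True runs."""
    out = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            out.append((start, i))
            start = None
    if start is not None:
        out.append((start, len(mask)))
    return out


def export_scatter(trace: ExtrusionTrace, timeline: MotionTimeline,
                   offset: float = 0.0) -> pd.DataFrame:
    """Per-sample spatial scatter table (x, y, z, pressure, printlet_id).

    One row per extruding trace sample -- the basis of the 3D scatter view
    that locates every pressure reading at its deposition coordinate.
    """
    ts = timeline.samples
    samp_t = ts["time_s"].to_numpy()
    idx = np.clip(np.searchsorted(samp_t, trace.time - offset), 0, len(samp_t) - 1)
    extruding = ts["extruding"].to_numpy()[idx] & (trace.time - offset <= samp_t[-1] + 1e-9)
    return pd.DataFrame(
        {
            "x": ts["x"].to_numpy()[idx][extruding],
            "y": ts["y"].to_numpy()[idx][extruding],
            "z": ts["z"].to_numpy()[idx][extruding],
            "pressure_kPa": trace.pressure[extruding],
            "printlet_id": ts["printlet_id"].to_numpy(dtype=object)[idx][extruding],
        }
    )
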