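"""Batch design, gcode generation/randomization and motion modelling.

A batch is a grid of cylindrical printlets.  ``design_batch`` emits a
minimal slicer's toolpath (concentric perimeters plus rectilinear infill,
RepRap-flavour absolute G0/G1 with F in mm/min), with every printlet
delimited by structured comment markers so downstream stages can attribute
any instant of the print to a dosage unit:

    ; PRINTLET P001 BEGIN [PRIMING]
    ...moves...
    ; PRINTLET P001 END

``randomize_speeds`` permutes the per-printlet print speeds (a seeded
uniform permutation of the requested speed multiset) by rewriting the F
words of printing moves only.  ``motion_timeline`` replays a gcode file
under constant-velocity kinematics (no acceleration model -- the analysis
works with commanded speed) into a time-resolved nozzle position record.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import ValidationError

__all__ = [
    "Printlet",
    "BatchModel",
    "MotionTimeline",
    "design_batch",
    "randomize_speeds",
    "motion_timeline",
]

_BEGIN_RE = re.compile(r"^; PRINTLET (\S+) BEGIN( PRIMING)?\s*$")
_END_RE = re.compile(r"^; PRINTLET (\S+) END\s*$")
_WORD_RE = re.compile(r"([XYZEF])(-?\d+\.?\d*)")


@dataclass(frozen=True)
class Printlet:
    id: str
    cx: float  # mm
    cy: float  # mm
    radius: float  # mm
    height: float  # mm
    assigned_speed: float  # mm/s
    priming: bool = False


@dataclass
class BatchModel:
    """Printlet layout plus the shared slicing parameters."""

    printlets: list
    layer_height: float
    spacing: float  # edge-to-edge gap, mm

    def __post_init__(self) -> None:
        ids = [p.id for p in self.printlets]
        if len(ids) != len(set(ids)):
            raise ValidationError("printlet ids must be unique")
        if self.layer_height <= 0 or self.spacing <= 0:
            raise ValidationError("layer_height and spacing must be > 0")


def _circle_points(cx: float, cy: float, r: float, segments: int = 36) -> list:
    ang = np.linspace(0.0, 2.0 * math.pi, segments + 1)
    return [(cx + r * math.cos(a), cy + r * math.sin(a)) for a in ang]


def _printlet_toolpath(p: Printlet, layer_height: float, shells: int,
                       infill: float, width: float) -> list:
    """Per-layer toolpath: list of layers, each a list of polylines."""
    n_layers = math.ceil(p.height / layer_height)
    layers = []
    for k in range(n_layers):
        paths = []
        for s in range(shells):
            r = p.radius - width / 2.0 - s * width
            if r > width / 2.0:
                paths.append(_circle_points(p.cx, p.cy, r))
        r_in = p.radius - shells * width
        if infill > 0 and r_in > width:
            gap = width / infill
            offsets = np.arange(-r_in + gap / 2.0, r_in, gap)
            lines = []
            for j, off in enumerate(offsets):
                half = math.sqrt(max(r_in**2 - off**2, 0.0))
                if half < width:
                    continue
                if k % 2 == 0:
                    a, b = (p.cx - half, p.cy + off), (p.cx + half, p.cy + off)
                else:
                    a, b = (p.cx + off, p.cy - half), (p.cx + off, p.cy + half)
                lines.append([a, b] if j % 2 == 0 else [b, a])
            paths.extend(lines)
        layers.append(paths)
    return layers


def design_batch(
    n: int = 60,
    radius: float = 6.0,
    height: float = 2.4,
    layer_height: float = 0.61,
    spacing: float = 10.0,
    speeds: tuple = (10.0, 20.0, 30.0),
    counts: tuple = (20, 20, 20),
    priming: tuple = (5.0, 10),
    shells: int = 2,
    infill: float = 0.7,
    extrusion_width: float = 0.61,
    travel_speed: float = 100.0,
    allow_overlap: bool = False,
) -> tuple[BatchModel, str]:
    """Build the batch model and its gcode.

    ``n`` printlets receive the main ``speeds`` in block order of ``counts``
    (use :func:`randomize_speeds` on the output for the randomized
    assignment); ``priming = (speed, count)`` prepends syringe-pressurizing
    printlets printed first.  Printlets sit on a square grid with pitch
    ``2 * radius + spacing`` (edge-to-edge gap = ``spacing``).
    """
    if n != sum(counts):
        raise ValidationError(f"n={n} must equal sum(counts)={sum(counts)}")
    if len(speeds) != len(counts):
        raise ValidationError("speeds and counts must have equal length")
    prime_speed, prime_count = priming
    pitch = 2.0 * radius + spacing
    if pitch < 2.0 * radius and not allow_overlap:
        raise ValidationError("printlets overlap at the chosen spacing")

    total = n + prime_count
    cols = math.ceil(math.sqrt(total))
    speed_list = [prime_speed] * prime_count
    for s, c in zip(speeds, counts):
        speed_list.extend([s] * c)

    printlets = []
    for i in range(total):
        row, col = divmod(i, cols)
        printlets.append(
            Printlet(
                id=f"P{i + 1:03d}",
                cx=col * pitch,
                cy=row * pitch,
                radius=radius,
                height=height,
                assigned_speed=speed_list[i],
                priming=i < prime_count,
            )
        )
    batch = BatchModel(printlets=printlets, layer_height=layer_height, spacing=spacing)

    lines = [
        "; ssepat batch gcode",
        f"; printlets {total} (priming {prime_count})",
        f"; layer_height {layer_height}",
        "G90",
        "G21",
    ]
    travel_f = travel_speed * 60.0
    e = 0.0
    for p in printlets:
        marker = f"; PRINTLET {p.id} BEGIN" + (" PRIMING" if p.priming else "")
        lines.append(marker)
        f_print = p.assigned_speed * 60.0
        layers = _printlet_toolpath(p, layer_height, shells, infill, extrusion_width)
        for k, paths in enumerate(layers):
            z = (k + 1) * layer_height
            for path in paths:
                x0, y0 = path[0]
                lines.append(f"G0 X{x0:.3f} Y{y0:.3f} Z{z:.3f} F{travel_f:.0f}")
                prev = path[0]
                for (x1, y1) in path[1:]:
                    seg = math.hypot(x1 - prev[0], y1 - prev[1])
                    e += seg * layer_height * extrusion_width
                    lines.append(f"G1 X{x1:.3f} Y{y1:.3f} E{e:.5f} F{f_print:.0f}")
                    prev = (x1, y1)
        lines.append(f"; PRINTLET {p.id} END")
    return batch, "\n".join(lines) + "\n"


def _parse_blocks(text: str) -> list:
    """Split gcode into (printlet_id or None, priming, [line indices]) blocks."""
    lines = text.splitlines()
    blocks = []
    current = None
    for i, line in enumerate(lines):
        m = _BEGIN_RE.match(line)
        if m:
            current = {"id": m.group(1), "priming": bool(m.group(2)), "lines": []}
            blocks.append(current)
            continue
        if _END_RE.match(line):
            current = None
            continue
        if current is not None:
            current["lines"].append(i)
    return lines, blocks


def randomize_speeds(gcode_text: str, speeds: tuple = (10.0, 20.0, 30.0),
                     counts: tuple = (20, 20, 20), seed: int = 0
                     ) -> tuple[str, pd.DataFrame]:
    """Randomly reassign per-printlet print speeds.

    The multiset of assigned speeds equals the requested ``counts`` exactly
    for every seed; the assignment is a seeded uniform permutation over the
    non-priming printlet blocks.  Only F words on printing moves (G1 lines
    carrying an E word) are rewritten; travel moves and priming blocks are
    untouched.
    """
    lines, blocks = _parse_blocks(gcode_text)
    main = [b for b in blocks if not b["priming"]]
    if not blocks:
        raise ValidationError(
            "no '; PRINTLET <id> BEGIN' markers found; use design_batch output"
        )
    if len(main) != sum(counts):
        raise ValidationError(
            f"{len(main)} printlet blocks but sum(counts)={sum(counts)}"
        )
    pool = []
    for s, c in zip(speeds, counts):
        pool.extend([s] * c)
    rng = np.random.default_rng(seed)
    assigned = rng.permutation(pool)

    rows = []
    for b, speed in zip(main, assigned):
        f_new = f"F{speed * 60.0:.0f}"
        for i in b["lines"]:
            line = lines[i]
            if line.startswith("G1") and " E" in line:
                lines[i] = re.sub(r"F-?\d+\.?\d*", f_new, line)
        rows.append({"printlet_id": b["id"], "assigned_speed": float(speed)})
    return "\n".join(lines) + "\n", pd.DataFrame(rows)


@dataclass
class MotionTimeline:
    """Time-resolved nozzle motion derived from gcode.

    ``moves`` holds one row per gcode move with exact start/end times
    (duration = length / commanded speed); ``samples`` is the uniform
    resampling used to pair the motion with a pressure trace.
    """

    moves: pd.DataFrame
    samples: pd.DataFrame
    sampling_rate: float

    def __post_init__(self) -> None:
        t = self.samples["time_s"].to_numpy()
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValidationError("sample times must be strictly increasing")

    @property
    def total_time(self) -> float:
        return float(self.moves["t_end"].iloc[-1]) if len(self.moves) else 0.0

    def printlet_at(self, times: np.ndarray) -> np.ndarray:
        """Printlet id active at each time (object array, None for travel)."""
        t_end = self.moves["t_end"].to_numpy()
        ids = self.moves["printlet_id"].to_numpy(dtype=object)
        idx = np.searchsorted(t_end, times, side="left")
        idx = np.clip(idx, 0, len(ids) - 1)
        out = ids[idx]
        out = np.where(np.asarray(times) > t_end[-1] + 1e-9, None, out)
        return out


def motion_timeline(gcode_text: str, sampling_rate: float = 10.0) -> MotionTimeline:
    """Replay gcode into a sampled motion record.

    Constant-velocity kinematics per move: duration is path length divided
    by the commanded speed (F/60 mm/s, modal).  Only absolute-coordinate
    G0/G1 moves are supported; G91 raises an unsupported-dialect error.
    """
    if sampling_rate <= 0:
        raise ValidationError("sampling_rate must be > 0")
    lines, _ = _parse_blocks(gcode_text)
    x = y = z = e = 0.0
    feed = 0.0
    t = 0.0
    current_printlet = None
    rows = []
    for line in lines:
        m = _BEGIN_RE.match(line)
        if m:
            current_printlet = m.group(1)
            continue
        if _END_RE.match(line):
            current_printlet = None
            continue
        code = line.split(";")[0].strip()
        if code.startswith("G91"):
            raise ValidationError("relative-mode gcode (G91) is not supported")
        if not (code.startswith("G0 ") or code.startswith("G1 ")
                or code in ("G0", "G1")):
            continue
        words = dict((k, float(v)) for k, v in _WORD_RE.findall(code))
        nx, ny, nz = words.get("X", x), words.get("Y", y), words.get("Z", z)
        ne = words.get("E", e)
        feed = words.get("F", feed)
        dist = math.sqrt((nx - x) ** 2 + (ny - y) ** 2 + (nz - z) ** 2)
        if dist == 0.0 and ne == e:
            x, y, z = nx, ny, nz
            continue
        speed = feed / 60.0
        if speed <= 0:
            raise ValidationError("move with no feedrate in effect")
        duration = dist / speed if dist > 0 else abs(ne - e) / speed
        rows.append(
            {
                "t_start": t, "t_end": t + duration,
                "x0": x, "y0": y, "z0": z, "x1": nx, "y1": ny, "z1": nz,
                "speed_mm_s": speed, "de": ne - e,
                "printlet_id": current_printlet,
            }
        )
        t += duration
        x, y, z, e = nx, ny, nz, ne

    moves = pd.DataFrame(rows)
    if len(moves) == 0:
        samples = pd.DataFrame(
            columns=["time_s", "x", "y", "z", "speed_mm_s", "extruding", "printlet_id"]
        )
        return MotionTimeline(moves=moves, samples=samples, sampling_rate=sampling_rate)

    dt = 1.0 / sampling_rate
    n = int(math.ceil(t / dt))
    ts = np.arange(1, n + 1) * dt
    t_end = moves["t_end"].to_numpy()
    t_start = moves["t_start"].to_numpy()
    idx = np.clip(np.searchsorted(t_end, ts, side="left"), 0, len(moves) - 1)
    frac = np.clip(
        (ts - t_start[idx]) / np.maximum(t_end[idx] - t_start[idx], 1e-12), 0.0, 1.0
    )
    mx0, my0, mz0 = (moves[c].to_numpy()[idx] for c in ("x0", "y0", "z0"))
    mx1, my1, mz1 = (moves[c].to_numpy()[idx] for c in ("x1", "y1", "z1"))
    samples = pd.DataFrame(
        {
            "time_s": ts,
            "x": mx0 + frac * (mx1 - mx0),
            "y": my0 + frac * (my1 - my0),
            "z": mz0 + frac * (mz1 - mz0),
            "speed_mm_s": moves["speed_mm_s"].to_numpy()[idx],
            "extruding": moves["de"].to_numpy()[idx] > 0,
            "printlet_id": moves["printlet_id"].to_numpy(dtype=object)[idx],
        }
    )
    return MotionTimeline(moves=moves, samples=samples, sampling_rate=sampling_rate)
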