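"""Published characterization tables for four hydrochlorothiazide pastes.

Small reference datasets used by the comparison and consistency analyses:
the compression/shrinkage protocol rows, the rheometer-vs-printhead yield
points at 40 C, and the full extrudability feature tables measured at 25 C
with a texture analyzer (TA) and with the instrumented printhead (SSE-P)
for four formulations (F1-F4) at three print speeds.

Viscosity columns are kept on the scale the source tables print them
(apparent in kPa.s-scale units, dynamic likewise); the analyses here use
them only in ratio and correlation form, where the scale cancels.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "compression_cycle_table",
    "yield_point_comparison",
    "ta_speed_table",
    "ssep_speed_table",
]


def compression_cycle_table() -> pd.DataFrame:
    """Compression/shrinkage protocol per target print speed.

    Plunger speeds follow PDS = TPS*(LH/D)^2 with LH=0.61 mm, D=19.3 mm;
    durations are the 5 mm travel divided by the speed, truncated to
    integer seconds.  Retraction runs 10x faster than compression.
    """
    return pd.DataFrame(
        {
            "target_print_speed": [10, 20, 30],
            "plunger_speed": [0.010, 0.020, 0.030],
            "compression_time_s": [500, 250, 166],
            "retraction_speed": [-0.100, -0.200, -0.300],
            "retraction_time_s": [50, 25, 16],
            "hold_time_s": [60, 60, 60],
        }
    ).set_index("target_print_speed")


def yield_point_comparison() -> pd.DataFrame:
    """Yield point per formulation at 40 C: rheometer (Pa) vs printhead (kPa)."""
    return pd.DataFrame(
        {
            "formulation": ["F1", "F2", "F3", "F4"],
            "rheometer_Pa": [607.0, 1064.0, 198.0, 1064.0],
            "ssep_kPa": [366.0, 305.0, 417.0, 363.0],
        }
    ).set_index("formulation")


def _speed_table(rows) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    return df.set_index(["formulation", "speed"])


def ta_speed_table() -> pd.DataFrame:
    """Texture-analyzer extrudability features at 25 C (per formulation x speed)."""
    cols = ["formulation", "speed", "max_pressure", "pressure_flow_cessation",
            "young_modulus", "shear_stress_steady", "apparent_viscosity",
            "dynamic_viscosity"]
    data = [
        ("F1", 10, 1094.5, 900.3, 204.1, 1759.9, 12.8, 35.6),
        ("F1", 20, 1435.9, 1022.8, 303.1, 2370.6, 7.9, 22.9),
        ("F1", 30, 1712.3, 1141.0, 405.9, 2878.5, 6.9, 11.9),
        ("F2", 10, 511.9, 340.9, 222.5, 901.4, 6.3, 17.5),
        ("F2", 20, 745.7, 385.2, 372.9, 1237.2, 4.3, 12.0),
        ("F2", 30, 1033.6, 575.2, 328.6, 1719.6, 4.0, 11.1),
        ("F3", 10, 678.6, 425.0, 349.7, 1034.7, 7.2, 20.1),
        ("F3", 20, 814.3, 505.3, 292.9, 1424.8, 5.0, 13.8),
        ("F3", 30, 1103.9, 640.1, 286.9, 1698.8, 3.9, 11.0),
        ("F4", 10, 1056.8, 757.7, 401.7, 1835.5, 12.8, 35.6),
        ("F4", 20, 1445.3, 832.7, 578.2, 2478.5, 8.6, 24.0),
        ("F4", 30, 1525.2, 864.1, 462.6, 2628.5, 6.1, 17.0),
    ]
    return _speed_table([dict(zip(cols, r)) for r in data])


def ssep_speed_table() -> pd.DataFrame:
    """Instrumented-printhead extrudability features at 25 C."""
    cols = ["formulation", "speed", "yield_point", "yield_time", "max_pressure",
            "pressure_flow_cessation", "young_modulus", "shear_stress_steady",
            "apparent_viscosity", "dynamic_viscosity"]
    data = [
        ("F1", 10, 471.5, 120.0, 1402.3, 1020.6, 240.4, 1993.7, 13.9, 38.6),
        ("F1", 20, 451.5, 64.5, 1611.2, 1160.3, 133.2, 2248.9, 7.8, 21.8),
        ("F1", 30, 478.1, 40.3, 1979.9, 1126.2, 301.9, 2767.7, 6.4, 18.0),
        ("F2", 10, 450.1, 124.4, 964.8, 631.7, 304.9, 1473.6, 10.2, 28.6),
        ("F2", 20, 413.2, 40.7, 1261.2, 744.6, 711.4, 1831.0, 6.4, 17.8),
        ("F2", 30, 438.8, 35.0, 1416.7, 748.4, 763.1, 2243.5, 5.2, 14.5),
        ("F3", 10, 408.7, 162.8, 817.9, 569.8, 166.1, 1114.0, 7.7, 21.6),
        ("F3", 20, 358.3, 37.9, 1170.6, 567.5, 178.4, 1418.4, 4.9, 13.7),
        ("F3", 30, 334.8, 23.3, 1286.5, 632.9, 682.3, 2293.9, 5.3, 5.5),
        ("F4", 10, 386.4, 177.8, 1082.3, 797.8, 170.0, 1971.5, 13.7, 38.2),
        ("F4", 20, 415.0, 77.3, 2524.7, 1647.5, 214.6, 2722.3, 9.5, 26.4),
        ("F4", 30, 405.9, 44.5, 2083.5, 1158.9, 509.4, 3663.3, 8.5, 23.7),
    ]
    return _speed_table([dict(zip(cols, r)) for r in data])
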