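"""Off-line quality control and statistics.

Image-based printlet measurement (equivalent-circle diameter, circularity,
dimensional accuracy, edge-defect flagging), paired instrument-comparison
regression, and speed-effect testing (per-response one-way ANOVA, Tukey HSD
pairwise comparisons, and the multivariate Wilks/Pillai/Roy statistics from
the between/within cross-product eigenvalues).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from skimage import filters, measure
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .simulate import ValidationError

__all__ = [
    "PrintletMeasurement",
    "ComparisonResult",
    "GroupTestResult",
    "measure_printlets",
    "compare_instruments",
    "speed_effect_tests",
]


@dataclass
class PrintletMeasurement:
    printlet_id: int
    cx: float  # px
    cy: float  # px
    diameter: float  # mm, equivalent-circle
    circularity: float  # 4*pi*A/P^2
    accuracy: float  # % of design diameter
    edge_defect: bool


@dataclass
class ComparisonResult:
    parameter: str
    slope: float
    intercept: float
    pearson_r: float
    p_value: float
    n: int
    degenerate: bool = False


@dataclass
class GroupTestResult:
    """Univariate + multivariate speed-effect test results."""

    factor_levels: list
    anova: pd.DataFrame  # per-response F and p
    tukey: dict  # response -> pairwise HSD table (DataFrame)
    wilks_lambda: float | None = None
    pillai_trace: float | None = None
    roy_greatest_root: float | None = None
    manova_p: dict = field(default_factory=dict)
    multivariate_available: bool = True


def measure_printlets(image: np.ndarray, pixel_scale: float,
                      design_diameter: float, min_area_mm2: float = 3.0,
                      circ_min: float = 0.85) -> list[PrintletMeasurement]:
    """Measure every printlet in a batch photograph.

    Otsu global threshold, connected components above ``min_area_mm2``,
    then per component: equivalent-circle diameter ``2*sqrt(A/pi)`` scaled
    to mm, circularity ``4*pi*A/P^2``, dimensional accuracy
    ``100*(1 - |d - design|/design)`` and an edge-defect flag when the
    circularity falls below ``circ_min``.  A blank image yields an empty
    list.
    """
    if pixel_scale <= 0:
        raise ValidationError("pixel_scale must be > 0")
    img = np.asarray(image, dtype=float)
    if img.max() <= img.min():
        return []
    thr = filters.threshold_otsu(img)
    binary = img > thr
    labels = measure.label(binary)
    min_area_px = min_area_mm2 * pixel_scale**2
    out = []
    for i, region in enumerate(measure.regionprops(labels)):
        if region.area < min_area_px:
            continue
        d_px = 2.0 * math.sqrt(region.area / math.pi)
        d_mm = d_px / pixel_scale
        perim = region.perimeter
        circ = min(4.0 * math.pi * region.area / perim**2, 1.0) if perim > 0 else 0.0
        acc = 100.0 * (1.0 - abs(d_mm - design_diameter) / design_diameter)
        cy, cx = region.centroid
        out.append(
            PrintletMeasurement(
                printlet_id=len(out) + 1,
                cx=cx, cy=cy,
                diameter=d_mm,
                circularity=circ,
                accuracy=max(acc, 0.0),
                edge_defect=circ < circ_min,
            )
        )
    return out


def compare_instruments(values_a: pd.DataFrame, values_b: pd.DataFrame,
                        parameters: list[str]) -> list[ComparisonResult]:
    """Paired regression of instrument B on instrument A per parameter.

    Both tables must share their row keys (index); for each parameter an
    ordinary least-squares line of b on a is fitted and the Pearson r with
    its two-sided p-value (t distribution) reported.  Zero-variance columns
    are flagged degenerate with undefined r.
    """
    missing = values_a.index.symmetric_difference(values_b.index)
    if len(missing):
        raise ValidationError(f"unmatched row keys: {list(missing)}")
    if len(values_a) < 3:
        raise ValidationError("need at least 3 matched rows")
    a = values_a.loc[values_b.index]
    out = []
    for param in parameters:
        x = a[param].to_numpy(dtype=float)
        y = values_b[param].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            out.append(ComparisonResult(param, float("nan"), float("nan"),
                                        float("nan"), float("nan"), len(x),
                                        degenerate=True))
            continue
        res = stats.linregress(x, y)
        out.append(
            ComparisonResult(
                parameter=param,
                slope=float(res.slope),
                intercept=float(res.intercept),
                pearson_r=float(res.rvalue),
                p_value=float(res.pvalue),
                n=len(x),
            )
        )
    return out


def _manova_stats(Y: np.ndarray, groups: np.ndarray):
    """Wilks' lambda, Pillai's trace and Roy's greatest root from B/W eigenvalues."""
    levels = np.unique(groups)
    grand = Y.mean(axis=0)
    p = Y.shape[1]
    B = np.zeros((p, p))
    W = np.zeros((p, p))
    for g in levels:
        sub = Y[groups == g]
        d = (sub.mean(axis=0) - grand)[:, None]
        B += len(sub) * (d @ d.T)
        C = sub - sub.mean(axis=0)
        W += C.T @ C
    try:
        WB = np.linalg.solve(W, B)
    except np.linalg.LinAlgError:
        return None
    eig = np.linalg.eigvals(WB).real
    eig = np.clip(eig, 0.0, None)
    wilks = float(np.prod(1.0 / (1.0 + eig)))
    pillai = float(np.sum(eig / (1.0 + eig)))
    roy = float(np.max(eig))
    return wilks, pillai, roy


def speed_effect_tests(records: pd.DataFrame, responses: list[str],
                       factor: str, alpha: float = 0.05) -> GroupTestResult:
    """Test the effect of a factor (e.g. printing speed) on quality responses.

    Per response: one-way ANOVA (standard sums of squares) and pairwise
    Tukey HSD at family level ``alpha``.  Across all responses jointly:
    Wilks' lambda, Pillai's trace and Roy's greatest root from the
    eigenvalues of W^-1 B; a singular within-matrix flags the multivariate
    block unavailable while the univariate results are still returned.
    """
    levels = sorted(records[factor].unique())
    if len(levels) < 2:
        raise ValidationError("need at least 2 factor levels")
    for g in levels:
        if (records[factor] == g).sum() < 2:
            raise ValidationError(f"need at least 2 observations in level {g}")

    anova_rows = []
    tukey = {}
    for resp in responses:
        groups = [records.loc[records[factor] == g, resp].to_numpy() for g in levels]
        F, pval = stats.f_oneway(*groups)
        anova_rows.append({"response": resp, "F": float(F), "p": float(pval)})
        hsd = pairwise_tukeyhsd(records[resp].to_numpy(),
                                records[factor].to_numpy(), alpha=alpha)
        tukey[resp] = pd.DataFrame(hsd.summary().data[1:],
                                   columns=hsd.summary().data[0])

    Y = records[responses].to_numpy(dtype=float)
    mstats = _manova_stats(Y, records[factor].to_numpy())
    result = GroupTestResult(
        factor_levels=levels,
        anova=pd.DataFrame(anova_rows).set_index("response"),
        tukey=tukey,
    )
    if mstats is None or not np.all(np.isfinite(mstats)):
        result.multivariate_available = False
    else:
        result.wilks_lambda, result.pillai_trace, result.roy_greatest_root = mstats
    return result
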