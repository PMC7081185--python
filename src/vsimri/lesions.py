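"""ROI statistics linking ischemic-edema status to vascular metrics.

Tissue status is classified from the mean apparent diffusion coefficient:
a region with mean ADC below 650 um²/s is ischemic edema, above is normal
(exact equality is classified normal).  Edema and normal regions are then
compared on macrovascular (pial vessel diameter) and microvascular (VSI,
Q, MVD) metrics with Student's t-tests and cutoff proportions
(VSI > 10 um, MVD > 200 mm⁻²).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from .relaxometry import ParameterMap

__all__ = [
    "ADC_EDEMA_THRESHOLD",
    "VSI_CUTOFF_UM",
    "MVD_CUTOFF_PER_MM2",
    "RoiSummary",
    "TestResult",
    "classify_tissue",
    "roi_metric_summary",
    "proportion_above",
    "students_t",
    "export_double_box",
    "pool_macrovascular",
]

ADC_EDEMA_THRESHOLD = 650.0  # um^2/s
VSI_CUTOFF_UM = 10.0
MVD_CUTOFF_PER_MM2 = 200.0


@dataclass
class RoiSummary:
    """Per-ROI statistics for one metric."""

    roi_id: str
    metric: str
    mean: float
    median: float
    values: np.ndarray
    n_voxels: int

    def __post_init__(self) -> None:
        if self.n_voxels <= 0:
            raise ValueError("n_voxels must be positive")


@dataclass
class TestResult:
    """Student's t-test outcome."""

    statistic: float
    p_value: float
    paired: bool
    n_per_group: tuple
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0, 1]")


def classify_tissue(mean_adc: float, threshold: float = ADC_EDEMA_THRESHOLD) -> str:
    """'edema' when mean ADC < threshold, else 'normal' (boundary: normal)."""
    if mean_adc < 0:
        raise ValueError("mean_adc must be non-negative")
    return "edema" if mean_adc < threshold else "normal"


def roi_metric_summary(
    pmap: ParameterMap, roi_mask: np.ndarray, roi_id: str = "", metric: str = ""
) -> RoiSummary:
    """Summary of a parameter map over the valid voxels of one ROI.

    Only voxels valid in the map contribute; the raw value vector is kept
    for histogram and test operations downstream.
    """
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != pmap.values.shape:
        raise ValueError(f"ROI {roi_id!r} mask does not match map geometry")
    sel = roi_mask & pmap.valid_mask
    n = int(sel.sum())
    if n == 0:
        raise ValueError(f"ROI {roi_id!r} contains no valid voxels")
    vals = pmap.values[sel]
    return RoiSummary(
        roi_id=roi_id,
        metric=metric or pmap.units,
        mean=float(vals.mean()),
        median=float(np.median(vals)),
        values=vals,
        n_voxels=n,
    )


def proportion_above(values, cutoff: float) -> float:
    """Fraction of values strictly greater than ``cutoff``."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("proportion_above requires non-empty values")
    return float((values > cutoff).mean())


def students_t(group_a, group_b, paired: bool = False) -> TestResult:
    """Classical two-sided Student's t-test, assembled from first principles.

    Unpaired uses the pooled-variance statistic; paired operates on the
    within-pair differences.  The t cumulative distribution is evaluated
    through the Student-t CDF special function.  Zero-variance cases are
    handled explicitly: equal means give t = 0, p = 1; unequal means with
    zero variance are flagged degenerate with p = 0.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if paired:
        if a.size != b.size:
            raise ValueError("paired test requires equal group sizes")
        d = a - b
        n = d.size
        mean = d.mean()
        var = d.var(ddof=1)
        df = n - 1
        if var == 0.0:
            if mean == 0.0:
                return TestResult(0.0, 1.0, True, (n, n))
            return TestResult(np.inf if mean > 0 else -np.inf, 0.0, True, (n, n), True)
        t = mean / np.sqrt(var / n)
    else:
        na, nb = a.size, b.size
        df = na + nb - 2
        var_pooled = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
        diff = a.mean() - b.mean()
        if var_pooled == 0.0:
            if diff == 0.0:
                return TestResult(0.0, 1.0, False, (na, nb))
            return TestResult(
                np.inf if diff > 0 else -np.inf, 0.0, False, (na, nb), True
            )
        t = diff / np.sqrt(var_pooled * (1.0 / na + 1.0 / nb))
        n = (na, nb)
    p = 2.0 * special.stdtr(df, -abs(t))
    npg = (a.size, b.size)
    return TestResult(float(t), float(min(max(p, 0.0), 1.0)), paired, npg)


def export_double_box(
    adc_values,
    metric_values,
    roi_labels,
    sides=None,
    metric_name: str = "metric",
    adc_threshold: float = ADC_EDEMA_THRESHOLD,
) -> pd.DataFrame:
    """Long-format table pairing per-voxel ADC with a microvascular metric.

    One row per voxel with columns (roi, side, adc, metric, tissue_class);
    ``tissue_class`` comes from the ROI mean ADC against the threshold.
    The threshold itself is carried in ``df.attrs['adc_threshold']`` as the
    reference line of the double box plot.
    """
    adc = np.asarray(adc_values, dtype=float)
    met = np.asarray(metric_values, dtype=float)
    labels = np.asarray(roi_labels)
    if adc.size == 0:
        raise ValueError("empty input")
    if not (adc.size == met.size == labels.size):
        raise ValueError("adc, metric and roi label vectors must have equal length")
    if sides is None:
        sides = np.array(["" for _ in range(adc.size)])
    else:
        sides = np.asarray(sides)
        if sides.size != adc.size:
            raise ValueError("sides must match value vectors in length")
    df = pd.DataFrame(
        {"roi": labels, "side": sides, "adc": adc, metric_name: met}
    )
    roi_class = {
        roi: classify_tissue(g["adc"].mean(), adc_threshold)
        for roi, g in df.groupby("roi")
    }
    df["tissue_class"] = df["roi"].map(roi_class)
    df.attrs["adc_threshold"] = adc_threshold
    return df


def pool_macrovascular(
    diameters: pd.DataFrame,
    early_days=(1, 4),
    late_day: int = 7,
    venous=("cRHV", "DCV"),
    arterial=("MCA",),
) -> pd.DataFrame:
    """Pool per-animal vessel diameters for edema-vs-recovered comparison.

    Input is a tidy table with columns (animal, day, vessel, diameter_mm).
    For each animal: the *maximum* venous and *minimum* arterial diameter
    over the early reperfusion days, and the day-``late_day`` value for the
    late phase.  Returns a tidy table (animal, vessel, phase, diameter_mm).
    """
    required = {"animal", "day", "vessel", "diameter_mm"}
    if not required.issubset(diameters.columns):
        raise ValueError(f"diameter table needs columns {sorted(required)}")
    lo, hi = min(early_days), max(early_days)
    rows = []
    for (animal, vessel), g in diameters.groupby(["animal", "vessel"]):
        early = g[(g["day"] >= lo) & (g["day"] <= hi)]["diameter_mm"]
        late = g[g["day"] == late_day]["diameter_mm"]
        if len(early):
            agg = early.max() if vessel in venous else early.min()
            rows.append(
                {"animal": animal, "vessel": vessel, "phase": "early", "diameter_mm": agg}
            )
        if len(late):
            rows.append(
                {
                    "animal": animal,
                    "vessel": vessel,
                    "phase": "late",
                    "diameter_mm": float(late.iloc[0]),
                }
            )
    return pd.DataFrame(rows)
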