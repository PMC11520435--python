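"""Descriptive layer: BMI arithmetic, frequency and percentile tables,
within-sample weight-status classification, and normality-check exports.

The weight-status convention is the within-sample percentile rule used for
under-five anthropometry: underweight below the 5th percentile of observed
BMI, normal from the 5th up to the 85th, overweight from the 85th up to the
95th, and obese at or above the 95th percentile.  Percentiles follow the
sorted-order linear-interpolation convention (numpy's default, R's type 7).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

#: 2019 EMDHS categorical frequencies (children n = 5,323) used both as the
#: reference for the frequency-table round trip and to parameterize the
#: synthetic-data schema.
EMDHS_2019_FREQUENCIES: dict[str, dict[str, int]] = {
    "toilet_facility": {"improved": 1072, "unimproved": 4251},
    "water_source": {"improved": 3272, "unimproved": 2051},
    "birth_type": {"singleton": 5200, "multiple": 123},
    "sex": {"male": 2719, "female": 2604},
    "maternal_education": {"no_formal": 2914, "primary": 1672, "secondary_plus": 737},
    "wealth_index": {
        "poorest": 1806,
        "poorer": 924,
        "middle": 742,
        "richer": 691,
        "richest": 1160,
    },
    "religion": {"orthodox": 1518, "protestant": 987, "muslim": 2714, "others": 104},
    "residence": {"urban": 1230, "rural": 4093},
    "marital_status": {"not_married": 361, "married": 4962},
    "breastfeeding": {"ever_not_current": 2893, "never": 225, "still": 2205},
    "n_under_five": {"lt2": 2023, "two": 2380, "three_plus": 920},
    "household_size": {"le4": 1454, "5_9": 3485, "ge10": 384},
}

#: EMDHS household fieldwork counts: occupied and successfully interviewed.
EMDHS_HOUSEHOLDS_OCCUPIED = 8794
EMDHS_HOUSEHOLDS_INTERVIEWED = 8663

PERCENTILE_LEVELS = (5, 25, 50, 75, 85, 95)

WEIGHT_STATUS_CATEGORIES = ("underweight", "normal", "overweight", "obese")


@dataclass(frozen=True)
class PercentileTable:
    """BMI-style percentile table at the six reporting levels."""

    levels: tuple[int, ...]
    values: np.ndarray


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round a nonnegative number half-up (0.05 -> 0.1 at one decimal)."""
    scale = 10.0**decimals
    return math.floor(float(x) * scale + 0.5) / scale


def compute_bmi(weight_kg, height_m):
    """BMI = weight (kg) / height (m) squared; inputs must be positive."""
    w = np.asarray(weight_kg, dtype=float)
    h = np.asarray(height_m, dtype=float)
    if np.any(w <= 0) or np.any(h <= 0):
        raise ValueError("weight and height must be positive")
    out = w / h**2
    return out if out.ndim else float(out)


def frequency_table(column) -> "pd.DataFrame":
    """Counts and one-decimal percentages of a categorical column.

    Percentages are 100 * count / n rounded half-up to one decimal, the
    convention under which the reference survey's printed table reproduces.
    Categories keep first-appearance order.
    """
    import pandas as pd

    values = list(column)
    if len(values) == 0:
        raise ValueError("cannot tabulate an empty column")
    counts: dict[object, int] = {}
    for v in values:
        counts[v] = counts.get(v, 0) + 1
    n = len(values)
    return pd.DataFrame(
        {
            "category": list(counts.keys()),
            "count": list(counts.values()),
            "percentage": [round_half_up(100.0 * c / n, 1) for c in counts.values()],
        }
    )


def response_rate_percent(interviewed: int, occupied: int) -> int:
    """Response rate 100 * interviewed / occupied, rounded half-up to an integer."""
    if occupied <= 0 or interviewed < 0 or interviewed > occupied:
        raise ValueError("need 0 <= interviewed <= occupied with occupied > 0")
    return int(round_half_up(100.0 * interviewed / occupied, 0))


def percentile_table(values) -> PercentileTable:
    """Empirical 5/25/50/75/85/95th percentiles by linear interpolation."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two values for a percentile table")
    vals = np.percentile(x, PERCENTILE_LEVELS, method="linear")
    return PercentileTable(levels=PERCENTILE_LEVELS, values=vals)


def classify_weight_status(values) -> tuple[list[str], tuple[float, float, float]]:
    """Within-sample weight-status labels plus the (p5, p85, p95) cutoffs.

    underweight: BMI < p5;  normal: p5 <= BMI < p85;
    overweight: p85 <= BMI < p95;  obese: BMI >= p95.
    Every observation receives exactly one label.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 20:
        raise ValueError("need at least 20 observations for meaningful percentiles")
    p5, p85, p95 = np.percentile(x, [5, 85, 95], method="linear")
    labels = classify_with_cutoffs(x, (float(p5), float(p85), float(p95)))
    return labels, (float(p5), float(p85), float(p95))


def classify_with_cutoffs(values, cutoffs: tuple[float, float, float]) -> list[str]:
    """Apply the half-open weight-status rule at explicit (p5, p85, p95) cutoffs."""
    p5, p85, p95 = cutoffs
    if not p5 <= p85 <= p95:
        raise ValueError("cutoffs must be ordered p5 <= p85 <= p95")
    out = []
    for v in np.asarray(values, dtype=float):
        if v < p5:
            out.append("underweight")
        elif v < p85:
            out.append("normal")
        elif v < p95:
            out.append("overweight")
        else:
            out.append("obese")
    return out


def normality_report(values, bins: int = 30) -> dict:
    """Histogram, normal Q-Q pairs and moment skewness for a continuous sample.

    Returns the data needed to redraw a histogram and a normal Q-Q plot:
    bin edges/counts, theoretical standard-normal quantiles paired with the
    standardized order statistics, and the standard moment estimator of
    skewness (right-skewed data give a positive value).
    """
    from scipy import stats

    x = np.asarray(values, dtype=float)
    if x.size < 20:
        raise ValueError("need at least 20 observations")
    sd = x.std()
    if sd == 0:
        raise ValueError("normality report undefined for zero-variance data")
    counts, edges = np.histogram(x, bins=bins)
    order = np.sort((x - x.mean()) / sd)
    probs = (np.arange(1, x.size + 1) - 0.5) / x.size
    theoretical = stats.norm.ppf(probs)
    return {
        "bin_edges": edges,
        "bin_counts": counts,
        "qq_theoretical": theoretical,
        "qq_sample": order,
        "skewness": float(stats.skew(x)),
    }
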