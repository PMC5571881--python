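"""Aneurysm growth rates from serial ultrasound and their predictors.

Each patient's growth rate is the ordinary-least-squares slope of maximum
anteroposterior diameter (mm) against time (years), fitted to all available
measurements including the baseline scan at t=0.  Patients with fewer than
two distinct measurement times carry no growth estimate and drop out of the
predictor regression, which models the slope on current smoking, baseline
diameter, systolic blood pressure and USPIO enhancement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "UltrasoundSeries",
    "GrowthEstimate",
    "growth_rate",
    "growth_rates_by_patient",
    "growth_predictor_model",
    "RankDeficientDesignError",
]


class RankDeficientDesignError(ValueError):
    """Raised when predictor columns are collinear; names the offenders."""


@dataclass
class UltrasoundSeries:
    times: np.ndarray  # years from baseline
    diameters: np.ndarray  # mm

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.diameters = np.asarray(self.diameters, dtype=float)
        if self.times.size != self.diameters.size or self.times.size < 1:
            raise ValueError("times and diameters must be equal length, >= 1")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("times must be nondecreasing")
        if np.any(self.diameters <= 0):
            raise ValueError("diameters must be positive")


@dataclass
class GrowthEstimate:
    slope: float  # mm / year
    intercept: float  # mm
    slope_se: float  # mm / year; NaN when only 2 points
    n_points: int


def growth_rate(series: UltrasoundSeries) -> GrowthEstimate | None:
    """OLS slope of diameter on time; ``None`` when fewer than two distinct
    measurement times are available (no estimable growth)."""
    t, d = series.times, series.diameters
    if np.unique(t).size < 2:
        return None
    slope, intercept = np.polyfit(t, d, 1)
    n = t.size
    if n > 2:
        resid = d - (intercept + slope * t)
        sigma2 = float(resid @ resid) / (n - 2)
        sxx = float(np.sum((t - t.mean()) ** 2))
        se = float(np.sqrt(sigma2 / sxx))
    else:
        se = float("nan")
    return GrowthEstimate(float(slope), float(intercept), se, int(n))


def growth_rates_by_patient(ultrasound: pd.DataFrame) -> pd.DataFrame:
    """Per-patient growth estimates from a long-format ultrasound table
    (columns patient_id, time_years, diameter_mm).  Patients without an
    estimable slope appear with NaN."""
    rows = []
    for pid, grp in ultrasound.groupby("patient_id"):
        est = growth_rate(UltrasoundSeries(grp["time_years"], grp["diameter_mm"]))
        rows.append(
            (
                pid,
                est.slope if est else np.nan,
                est.slope_se if est else np.nan,
                est.n_points if est else len(grp),
            )
        )
    return pd.DataFrame(
        rows, columns=["patient_id", "growth_mm_per_yr", "slope_se", "n_points"]
    )


DEFAULT_PREDICTORS = (
    "current_smoker",
    "baseline_diameter_mm",
    "sbp_mmhg",
    "enhanced",
)


def growth_predictor_model(
    cohort: pd.DataFrame,
    slope_column: str = "growth_mm_per_yr",
    predictors=DEFAULT_PREDICTORS,
) -> pd.DataFrame:
    """Multiple linear regression of growth rate on the four baseline
    predictors, with two-sided coefficient t-tests.

    Returns a table with one row per term (including the intercept):
    estimate, se, t, p.
    """
    data = cohort.dropna(subset=[slope_column, *predictors])
    if len(data) < 10:
        raise ValueError(f"need >= 10 patients with defined slopes, have {len(data)}")
    x = data[list(predictors)].astype(float)
    design = sm.add_constant(x, has_constant="add")
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        # identify columns in the span of the others
        bad = []
        mat = design.to_numpy()
        for j, name in enumerate(design.columns):
            if name == "const":
                continue
            others = np.delete(mat, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                bad.append(name)
        raise RankDeficientDesignError(
            f"collinear predictor columns: {', '.join(bad) or 'unknown'}"
        )
    fit = sm.OLS(data[slope_column].astype(float), design).fit()
    return pd.DataFrame(
        {
            "estimate": fit.params,
            "se": fit.bse,
            "t": fit.tvalues,
            "p": fit.pvalues,
        }
    )
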