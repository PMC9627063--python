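"""Per-unit OLS trends and their unweighted fixed-effects pooling.

Each taxon (or station) contributes one ordinary-least-squares slope of its
annual response on either calendar year or mean annual temperature, with the
usual residual-variance standard error.  Slopes within one response are then
pooled *unweighted*: the units are different taxa rather than replicate
estimates of a common parameter, so inverse-variance weights would let a
well-sampled species dominate the regional signal.  The pooled estimate is
the arithmetic mean of the slopes,

    pooled = (1/k) sum(b_i),    se = sqrt(sum se_i^2) / k,

with a 95% interval pooled +/- 1.96 se.  An alternative empirical-variance
standard error (sd of the slopes / sqrt(k)) is available via ``se_mode``.

For cross-response synthesis, slopes are recomputed on centered and scaled
responses (z-scores) and reported as the natural log of the absolute
standardized slope, so responses in days, individuals and degrees latitude
become comparable; the synthesis regression asks how that magnitude varies
with dataset duration.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .ingest import AnnualSeries
from .responses import ResponseSeries

logger = logging.getLogger(__name__)

__all__ = [
    "SlopeEstimate",
    "MetaEstimate",
    "EstimationError",
    "fit_trend",
    "pool_slopes",
    "scaled_effect_size",
    "duration_effect_regression",
]

Z95 = 1.96  # normal 97.5% quantile, conventional fixed-effect CI multiplier


class EstimationError(RuntimeError):
    """Too few points or a rank-deficient design."""


@dataclass
class SlopeEstimate:
    """One unit's OLS slope against year or temperature."""

    unit_label: str
    predictor: str  # "year" or "temperature"
    slope: float
    se: float
    n: int
    first_year: int
    last_year: int
    kind: str = ""
    scaled_abs_log: float | None = None

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("se must be non-negative")
        if self.n < 3:
            raise ValueError("need at least 3 observations")

    @property
    def duration(self) -> int:
        return self.last_year - self.first_year

    @property
    def ci(self) -> tuple[float, float]:
        return (self.slope - Z95 * self.se, self.slope + Z95 * self.se)


@dataclass
class MetaEstimate:
    pooled: float
    se: float
    ci_low: float
    ci_high: float
    k: int

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not self.ci_low <= self.pooled <= self.ci_high:
            raise ValueError("CI must bracket the pooled estimate")


def _align(series: AnnualSeries, predictor: AnnualSeries | None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Match response years to predictor values; returns (years, x, y)."""
    if predictor is None:
        return series.years, series.years.astype(float), series.values
    common, idx_r, idx_p = np.intersect1d(series.years, predictor.years, return_indices=True)
    return common, predictor.values[idx_p], series.values[idx_r]


def fit_trend(
    series: ResponseSeries | AnnualSeries,
    predictor: AnnualSeries | None = None,
    covariates: dict[int, str] | None = None,
) -> SlopeEstimate:
    """OLS of one unit's annual response on year (default) or a predictor series.

    With ``predictor`` given (e.g. annual mean temperature), only years
    present in both series are used, pairing each response year with the same
    calendar year's predictor value (no lag).  Categorical covariates enter as
    dummy-coded fixed effects; the returned coefficient is always the
    predictor's, with its standard error from the usual residual-variance
    formula.
    """
    if isinstance(series, ResponseSeries):
        annual = series.series
        if covariates is None:
            covariates = series.covariates
        unit, kind = series.unit_label, series.kind
    else:
        annual, unit, kind = series, series.label, ""
    years, x, y = _align(annual, predictor)
    if years.size < 3:
        raise EstimationError(f"{unit}: only {years.size} matched points (need >= 3)")

    X = pd.DataFrame({"x": x}, index=years)
    if covariates:
        levels = pd.Series([covariates[int(yr)] for yr in years], index=years, dtype="object")
        dummies = pd.get_dummies(levels, prefix="cov", drop_first=True, dtype=float)
        X = pd.concat([X, dummies], axis=1)
    X = sm.add_constant(X)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise EstimationError(f"{unit}: design matrix is rank-deficient")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # perfect fits trigger harmless divide warnings
        res = sm.OLS(y, X).fit()
    se = float(res.bse["x"])
    if not np.isfinite(se):
        se = 0.0
    return SlopeEstimate(
        unit_label=unit,
        predictor="year" if predictor is None else predictor.label or "temperature",
        slope=float(res.params["x"]),
        se=se,
        n=int(years.size),
        first_year=int(years[0]),
        last_year=int(years[-1]),
        kind=kind,
    )


def pool_slopes(estimates: Sequence[SlopeEstimate], se_mode: str = "sampling") -> MetaEstimate:
    """Unweighted fixed-effects pooling of per-unit slopes.

    ``se_mode='sampling'`` (default) propagates the per-unit sampling
    variances: se = sqrt(sum se_i^2)/k.  ``se_mode='empirical'`` uses the
    spread of the slopes themselves: sd(b_i)/sqrt(k).
    """
    if not estimates:
        raise ValueError("no estimates to pool")
    predictors = {e.predictor for e in estimates}
    if len(predictors) > 1:
        raise ValueError(f"mixed predictors cannot be pooled: {sorted(predictors)}")
    slopes = np.array([e.slope for e in estimates])
    ses = np.array([e.se for e in estimates])
    k = slopes.size
    pooled = float(slopes.mean())
    if se_mode == "sampling":
        se = float(np.sqrt(np.sum(ses**2)) / k)
    elif se_mode == "empirical":
        se = float(slopes.std(ddof=1) / np.sqrt(k)) if k > 1 else float(ses[0])
    else:
        raise ValueError(f"unknown se_mode {se_mode!r}")
    return MetaEstimate(pooled=pooled, se=se, ci_low=pooled - Z95 * se,
                        ci_high=pooled + Z95 * se, k=int(k))


def scaled_effect_size(
    series: ResponseSeries | AnnualSeries,
    predictor: AnnualSeries | None = None,
    covariates: dict[int, str] | None = None,
    noise_floor: float = 1e-12,
) -> float | None:
    """Natural log of the absolute slope after standardizing the response.

    Centering on the mean and dividing by the standard deviation puts every
    response on a common standard-deviation scale, so the absolute log slope
    is comparable across days, counts and degrees.  Returns ``None`` (with a
    warning) for zero-variance responses or slopes at the numerical noise
    floor, which carry no interpretable magnitude.
    """
    annual = series.series if isinstance(series, ResponseSeries) else series
    sd = float(np.std(annual.values, ddof=1)) if len(annual) > 1 else 0.0
    label = series.unit_label if isinstance(series, ResponseSeries) else annual.label
    if not np.isfinite(sd) or sd <= 0:
        warnings.warn(f"{label}: zero response variance; effect size undefined")
        return None
    z = AnnualSeries(annual.label, annual.years, (annual.values - annual.values.mean()) / sd,
                     "sd units")
    if isinstance(series, ResponseSeries):
        z_series: ResponseSeries | AnnualSeries = ResponseSeries(
            series.response_id, series.unit_label, series.kind, z, series.covariates
        )
    else:
        z_series = z
    est = fit_trend(z_series, predictor, covariates)
    if abs(est.slope) < noise_floor:
        warnings.warn(f"{label}: standardized slope below noise floor; excluded")
        return None
    return float(np.log(abs(est.slope)))


def duration_effect_regression(
    effects: Sequence[SlopeEstimate], kind: str | None = None
) -> tuple[float, float, float]:
    """OLS of log absolute scaled effect size on dataset duration.

    ``kind`` restricts the fit to one response kind (e.g. only distribution
    series).  Returns (slope per year of duration, se, F statistic of the
    regression).  All effects must carry ``scaled_abs_log``.
    """
    subset = [e for e in effects if e.scaled_abs_log is not None
              and (kind is None or e.kind == kind)]
    if len(subset) < 3:
        raise EstimationError("need at least 3 effects with scaled_abs_log")
    dur = np.array([float(e.duration) for e in subset])
    if np.ptp(dur) == 0:
        raise EstimationError("all durations equal; slope is unidentifiable")
    y = np.array([e.scaled_abs_log for e in subset])
    X = sm.add_constant(pd.DataFrame({"duration": dur}))
    res = sm.OLS(y, X).fit()
    return float(res.params["duration"]), float(res.bse["duration"]), float(res.fvalue)
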