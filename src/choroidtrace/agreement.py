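"""Agreement statistics between paired manual and automated measurements.

Implements the method-comparison battery: residuals (automated minus
manual), mean absolute error, Pearson correlation, ICC(3,1) (two-way
mixed-effects, single-rater, consistency), Passing-Bablok regression with
rank-based confidence intervals, Bland-Altman limits of agreement,
major-discrepancy flagging against a fixed threshold, and unsigned
within-patient angular deviation series relative to baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import DegenerateTestError, InvalidParameterError

MAJOR_DISCREPANCY_UM = 32.0  # interobserver-variability threshold


@dataclass
class PairedMeasurements:
    """Paired reference (manual, x) and test (automated, y) values."""

    x: np.ndarray
    y: np.ndarray
    ids: list | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise InvalidParameterError("x and y must be 1-D and equally long")
        if self.ids is not None and len(self.ids) != len(self.x):
            raise InvalidParameterError("ids length mismatch")

    def __len__(self) -> int:
        return len(self.x)


@dataclass
class AgreementReport:
    residual_mean: float
    residual_sd: float
    mae_mean: float
    mae_sd: float
    pearson_r: float
    icc_3_1: float
    pb_slope: float
    pb_slope_ci: tuple[float, float]
    pb_intercept: float
    pb_intercept_ci: tuple[float, float]
    ba_mean: float
    ba_loa: tuple[float, float]
    n_flagged: int
    flag_threshold: float
    n_pairs: int

    def to_dict(self) -> dict:
        d = {}
        for k, v in self.__dict__.items():
            d[k] = list(v) if isinstance(v, tuple) else v
        return d


def residuals(pairs: PairedMeasurements) -> np.ndarray:
    """Elementwise automated minus manual (y - x); positive when automated larger."""
    if len(pairs) == 0:
        raise InvalidParameterError("no pairs")
    return pairs.y - pairs.x


def icc_3_1(x: np.ndarray, y: np.ndarray) -> float:
    """ICC(3,1): two-way mixed effects, single rater, consistency.

    Computed from the two-way ANOVA mean squares with k = 2 raters:
    (MSR - MSE) / (MSR + (k - 1) MSE).
    """
    data = np.column_stack([np.asarray(x, float), np.asarray(y, float)])
    n, k = data.shape
    if n < 3:
        raise InvalidParameterError("ICC requires at least 3 pairs")
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((data - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse
    if denom == 0:
        raise DegenerateTestError("zero variance: ICC undefined")
    return float((msr - mse) / denom)


def summary_stats(pairs: PairedMeasurements) -> dict:
    """Residual and MAE mean +- SD, Pearson r, and ICC(3,1)."""
    if len(pairs) < 3:
        raise InvalidParameterError("need at least 3 pairs")
    res = residuals(pairs)
    if np.std(pairs.x) == 0 or np.std(pairs.y) == 0:
        raise DegenerateTestError("zero variance: correlation undefined")
    r, _ = stats.pearsonr(pairs.x, pairs.y)
    return {
        "residual_mean": float(np.mean(res)),
        "residual_sd": float(np.std(res, ddof=1)),
        "mae_mean": float(np.mean(np.abs(res))),
        "mae_sd": float(np.std(np.abs(res), ddof=1)),
        "pearson_r": float(r),
        "icc_3_1": icc_3_1(pairs.x, pairs.y),
    }


def _pairwise_slopes(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, int]:
    """All Passing-Bablok pairwise slopes (sorted) and the offset K.

    Slopes of exactly -1 are excluded; vertical pairs contribute signed
    infinities; K counts slopes below -1.
    """
    n = len(x)
    i, j = np.triu_indices(n, k=1)
    dx = x[j] - x[i]
    dy = y[j] - y[i]
    keep = ~((dx == 0) & (dy == 0))
    dx, dy = dx[keep], dy[keep]
    s = np.empty(len(dx))
    nz = dx != 0
    s[nz] = dy[nz] / dx[nz]
    s[~nz] = np.sign(dy[~nz]) * np.inf
    s = s[s != -1.0]
    s.sort()
    k_offset = int(np.sum(s < -1.0))
    return s, k_offset


def passing_bablok(pairs: PairedMeasurements, alpha: float = 0.05):
    """Passing-Bablok regression with rank-based confidence intervals.

    The slope is the K-shifted median of all pairwise slopes; the intercept
    is ``median(y - slope * x)``. Confidence bounds use the method's
    rank-based formula; intercept bounds reuse the slope bounds.
    Returns (slope, (slope_lo, slope_hi), intercept, (int_lo, int_hi)).
    """
    x, y = pairs.x, pairs.y
    if len(x) < 3:
        raise InvalidParameterError("Passing-Bablok requires n >= 3")
    if np.all(x == x[0]):
        raise InvalidParameterError("all x identical")
    s, k_off = _pairwise_slopes(x, y)
    big_n = len(s)
    if big_n == 0:
        raise InvalidParameterError("no valid pairwise slopes")

    def shifted_median(offset: int) -> float:
        if big_n % 2:
            return float(s[np.clip((big_n + 1) // 2 + offset - 1, 0, big_n - 1)])
        lo = np.clip(big_n // 2 + offset - 1, 0, big_n - 1)
        hi = np.clip(big_n // 2 + offset, 0, big_n - 1)
        return float(0.5 * (s[lo] + s[hi]))

    slope = shifted_median(k_off)
    n = len(x)
    z = stats.norm.ppf(1 - alpha / 2)
    w = z * np.sqrt(n * (n - 1) * (2 * n + 5) / 18.0)
    m1 = int(np.round((big_n - w) / 2.0))
    m2 = big_n - m1 + 1
    lo_idx = np.clip(m1 + k_off - 1, 0, big_n - 1)
    hi_idx = np.clip(m2 + k_off - 1, 0, big_n - 1)
    slope_ci = (float(s[lo_idx]), float(s[hi_idx]))
    intercept = float(np.median(y - slope * x))
    intercept_ci = (
        float(np.median(y - slope_ci[1] * x)),
        float(np.median(y - slope_ci[0] * x)),
    )
    return slope, slope_ci, intercept, intercept_ci


def bland_altman(res: np.ndarray, k: float = 1.96) -> tuple[float, tuple[float, float]]:
    """Mean residual and mean +- k SD limits of agreement (n-1 denominator)."""
    res = np.asarray(res, dtype=float)
    if len(res) < 3:
        raise InvalidParameterError("Bland-Altman requires n >= 3")
    mean = float(np.mean(res))
    sd = float(np.std(res, ddof=1))
    return mean, (mean - k * sd, mean + k * sd)


def flag_major(
    res: np.ndarray, threshold: float = MAJOR_DISCREPANCY_UM
) -> tuple[np.ndarray, int]:
    """Flag residuals strictly greater than the threshold in absolute value."""
    if threshold <= 0:
        raise InvalidParameterError("threshold must be positive")
    res = np.asarray(res, dtype=float)
    flags = np.abs(res) > threshold
    return flags, int(flags.sum())


def evaluate_pairs(
    pairs: PairedMeasurements, threshold: float = MAJOR_DISCREPANCY_UM
) -> AgreementReport:
    """Full agreement battery on one set of paired measurements."""
    res = residuals(pairs)
    stats_d = summary_stats(pairs)
    slope, slope_ci, intercept, intercept_ci = passing_bablok(pairs)
    ba_mean, loa = bland_altman(res)
    _, n_flagged = flag_major(res, threshold)
    return AgreementReport(
        residual_mean=stats_d["residual_mean"],
        residual_sd=stats_d["residual_sd"],
        mae_mean=stats_d["mae_mean"],
        mae_sd=stats_d["mae_sd"],
        pearson_r=stats_d["pearson_r"],
        icc_3_1=stats_d["icc_3_1"],
        pb_slope=slope,
        pb_slope_ci=slope_ci,
        pb_intercept=intercept,
        pb_intercept_ci=intercept_ci,
        ba_mean=ba_mean,
        ba_loa=loa,
        n_flagged=n_flagged,
        flag_threshold=threshold,
        n_pairs=len(pairs),
    )


def angular_deviation_series(
    angles: pd.DataFrame, baseline_visit=0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Unsigned within-patient angular deviations from baseline.

    ``angles`` must have columns (patient, visit, location, angle_deg) with
    the baseline visit present for every patient. Returns the per-row
    deviation table (follow-up visits only) and a per-visit summary with
    empirical mean and SD across patients/locations.
    """
    required = {"patient", "visit", "location", "angle_deg"}
    if not required.issubset(angles.columns):
        raise InvalidParameterError(f"angle table needs columns {sorted(required)}")
    base = angles[angles["visit"] == baseline_visit]
    missing = set(angles["patient"]) - set(base["patient"])
    if missing:
        raise InvalidParameterError(f"patients missing baseline visit: {sorted(missing)}")
    base_map = base.set_index(["patient", "location"])["angle_deg"]
    follow = angles[angles["visit"] != baseline_visit].copy()
    keys = list(zip(follow["patient"], follow["location"]))
    follow["deviation_deg"] = np.abs(
        follow["angle_deg"].to_numpy() - base_map.loc[keys].to_numpy()
    )
    summary = (
        follow.groupby("visit")["deviation_deg"]
        .agg(mean="mean", sd=lambda v: np.std(v, ddof=1) if len(v) > 1 else 0.0)
        .reset_index()
    )
    return follow, summary
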