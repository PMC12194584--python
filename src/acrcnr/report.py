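"""Batch summaries, automatic-vs-manual comparison, and serialization.

QC practice reports each scan condition as mean ± SD of contrast, noise and
CNR over the repeat slices, checks the mean CNR against the accreditation
tolerance (CNR ≥ 1.0), and compares measurement methods with a percent
difference of the means and a two-sided Mann-Whitney U rank-sum test at
α = 0.05.

Percent difference is defined as |mean_a − mean_b| / mean_b × 100 with the
second (reference, e.g. manual) series in the denominator; every report
header states this definition.

The Mann-Whitney U statistic uses midranks for ties.  For pooled sample
sizes ≤ 12 the two-sided p-value is exact, by full enumeration of the
C(n, n_x) label assignments; beyond that a normal approximation with tie
correction and continuity correction is used.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata, norm

from .core import CNRResult, ROIStats
from .errors import StatisticsError, ValidationError

ACR_CNR_TOLERANCE = 1.0
ALPHA = 0.05
EXACT_ENUMERATION_LIMIT = 12

PERCENT_DIFFERENCE_DEFINITION = (
    "percent difference = |mean_a - mean_b| / mean_b * 100 (b = reference)"
)

_FIELDS = ("contrast_hu", "noise_hu", "cnr")


@dataclass(frozen=True)
class MeasurementSeries:
    """Per-slice CNR results for one condition, with mean ± SD summaries.

    SDs use the sample (n−1) convention; for a single slice they are
    reported as 0.0 and ``single_slice`` is True.
    """

    label: str
    per_slice: tuple[CNRResult, ...]
    mean_contrast: float
    sd_contrast: float
    mean_noise: float
    sd_noise: float
    mean_cnr: float
    sd_cnr: float

    @property
    def n(self) -> int:
        return len(self.per_slice)

    @property
    def single_slice(self) -> bool:
        return self.n == 1

    def values(self, field: str) -> list[float]:
        if field not in _FIELDS:
            raise ValidationError(f"unknown field {field!r}; expected one of {_FIELDS}")
        return [getattr(r, field) for r in self.per_slice]


def summarize(results, label: str = "") -> MeasurementSeries:
    """Mean ± sample SD of contrast, noise and CNR across slices."""
    results = tuple(results)
    if not results:
        raise StatisticsError("cannot summarize an empty result list")

    def _mean_sd(vals):
        a = np.asarray(vals, dtype=float)
        return float(a.mean()), (float(a.std(ddof=1)) if a.size > 1 else 0.0)

    mc, sc = _mean_sd([r.contrast_hu for r in results])
    mn, sn = _mean_sd([r.noise_hu for r in results])
    mr, sr = _mean_sd([r.cnr for r in results])
    return MeasurementSeries(
        label=label, per_slice=results,
        mean_contrast=mc, sd_contrast=sc,
        mean_noise=mn, sd_noise=sn,
        mean_cnr=mr, sd_cnr=sr,
    )


def percent_difference(a: MeasurementSeries, b: MeasurementSeries, field: str) -> float:
    """|mean_a − mean_b| / mean_b × 100, with ``b`` the reference series."""
    means = {
        "contrast_hu": (a.mean_contrast, b.mean_contrast),
        "noise_hu": (a.mean_noise, b.mean_noise),
        "cnr": (a.mean_cnr, b.mean_cnr),
    }
    if field not in means:
        raise ValidationError(f"unknown field {field!r}; expected one of {_FIELDS}")
    ma, mb = means[field]
    if mb == 0:
        raise StatisticsError("percent difference undefined: reference mean is zero")
    return abs(ma - mb) / abs(mb) * 100.0


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U rank-sum test.

    Returns (U, p) where U is the statistic for the first sample computed
    from midranks.  Exact p by full enumeration of label assignments when
    n_x + n_y ≤ 12; otherwise normal approximation with tie and continuity
    corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx < 2 or ny < 2:
        raise StatisticsError("each sample needs at least 2 values")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)  # midranks for ties
    u_obs = float(ranks[:nx].sum() - nx * (nx + 1) / 2)

    if nx + ny <= EXACT_ENUMERATION_LIMIT:
        return u_obs, _exact_p_two_sided(ranks, nx, u_obs)
    return u_obs, _normal_approx_p(pooled, nx, ny, u_obs)


def _exact_p_two_sided(ranks: np.ndarray, nx: int, u_obs: float) -> float:
    """Exact two-sided p: fraction of the C(n, nx) label assignments whose
    U deviates from the null mean at least as much as the observed U."""
    n = ranks.size
    ny = n - nx
    mu = nx * ny / 2.0
    dev = abs(u_obs - mu) - 1e-12
    hits = total = 0
    base = nx * (nx + 1) / 2
    for combo in itertools.combinations(range(n), nx):
        u = ranks[list(combo)].sum() - base
        hits += abs(u - mu) >= dev
        total += 1
    return hits / total


def _normal_approx_p(pooled: np.ndarray, nx: int, ny: int, u_obs: float) -> float:
    """Two-sided normal approximation with tie and continuity corrections."""
    n = nx + ny
    mu = nx * ny / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float((counts**3 - counts).sum()) / (n * (n - 1))
    sigma2 = nx * ny / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return 1.0  # all values tied
    z = (abs(u_obs - mu) - 0.5) / math.sqrt(sigma2)
    return min(1.0, 2.0 * float(norm.sf(max(z, 0.0))))


def acr_tolerance_check(series: MeasurementSeries) -> bool:
    """Accreditation pass/fail: mean CNR ≥ 1.0 (boundary inclusive)."""
    return series.mean_cnr >= ACR_CNR_TOLERANCE


@dataclass(frozen=True)
class ComparisonReport:
    """Two-series comparison on one field: percent difference + rank-sum test."""

    series_a: MeasurementSeries
    series_b: MeasurementSeries
    field: str
    percent_difference: float
    u_statistic: float
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA

    def describe(self) -> str:
        verdict = (
            "significantly different"
            if self.significant
            else "not significantly different"
        )
        return (
            f"{self.series_a.label or 'a'} vs {self.series_b.label or 'b'} "
            f"[{self.field}]: {PERCENT_DIFFERENCE_DEFINITION}; "
            f"difference = {self.percent_difference:.1f}%, "
            f"U = {self.u_statistic:g}, p = {self.p_value:.3f} "
            f"({verdict} at alpha = {ALPHA})"
        )


def compare_series(
    a: MeasurementSeries, b: MeasurementSeries, field: str = "cnr"
) -> ComparisonReport:
    """Compare two measurement series (``b`` is the reference, e.g. manual)."""
    u, p = mann_whitney_u(a.values(field), b.values(field))
    return ComparisonReport(
        series_a=a, series_b=b, field=field,
        percent_difference=percent_difference(a, b, field),
        u_statistic=u, p_value=p,
    )


def series_to_frame(series: MeasurementSeries) -> pd.DataFrame:
    """Per-slice rows plus a trailing summary row, full precision."""
    rows = [
        {
            "label": series.label,
            "row": "slice",
            "index": k + 1,
            "contrast_hu": r.contrast_hu,
            "noise_hu": r.noise_hu,
            "cnr": r.cnr,
            "object_mean_hu": r.object_stats.mean_hu,
            "background_mean_hu": r.background_stats.mean_hu,
            "object_n_pixels": r.object_stats.n_pixels,
            "background_n_pixels": r.background_stats.n_pixels,
        }
        for k, r in enumerate(series.per_slice)
    ]
    rows.append(
        {
            "label": series.label,
            "row": "mean",
            "index": series.n,
            "contrast_hu": series.mean_contrast,
            "noise_hu": series.mean_noise,
            "cnr": series.mean_cnr,
            "object_mean_hu": np.nan,
            "background_mean_hu": np.nan,
            "object_n_pixels": 0,
            "background_n_pixels": 0,
        }
    )
    rows.append(
        {
            "label": series.label,
            "row": "sd",
            "index": series.n,
            "contrast_hu": series.sd_contrast,
            "noise_hu": series.sd_noise,
            "cnr": series.sd_cnr,
            "object_mean_hu": np.nan,
            "background_mean_hu": np.nan,
            "object_n_pixels": 0,
            "background_n_pixels": 0,
        }
    )
    return pd.DataFrame(rows)


def write_series_csv(series: MeasurementSeries, path) -> None:
    series_to_frame(series).to_csv(path, index=False, float_format="%.17g")


def read_series_csv(path) -> pd.DataFrame:
    # round_trip parsing so write -> read is lossless at stored precision
    return pd.read_csv(path, float_precision="round_trip")


def series_from_csv(path) -> MeasurementSeries:
    """Rebuild a :class:`MeasurementSeries` from a written series CSV.

    Per-slice ROI pixel counts and means are restored where present; the
    ROI SDs other than noise are not serialized and come back as NaN-free
    zeros (they do not enter any summary).
    """
    df = read_series_csv(path)
    sl = df[df["row"] == "slice"]
    if sl.empty:
        raise ValidationError(f"{path} contains no per-slice rows")
    results = []
    for _, row in sl.iterrows():
        contrast = float(row["contrast_hu"])
        noise = float(row["noise_hu"])
        obj = ROIStats(
            mean_hu=float(row.get("object_mean_hu", np.nan)),
            sd_hu=0.0,
            n_pixels=int(row.get("object_n_pixels", 0) or 0),
        )
        bg = ROIStats(
            mean_hu=float(row.get("background_mean_hu", np.nan)),
            sd_hu=noise,
            n_pixels=int(row.get("background_n_pixels", 0) or 0),
        )
        results.append(
            CNRResult(
                contrast_hu=contrast,
                noise_hu=noise,
                cnr=float(row["cnr"]),
                object_stats=obj,
                background_stats=bg,
            )
        )
    return summarize(results, label=str(sl["label"].iloc[0]))
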