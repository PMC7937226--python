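"""Projected-biomass-area distribution statistics.

The morphology readout is the *projected biomass area*: the 2-D silhouette
area (µm²) of each detected fungal particle.  Per cultivation time point,
areas from all replicate images are pooled into one distribution, which is
summarised by its median and interquartile range (IQR) — the IQR serves
as the dispersion/heterogeneity measure.  Distributions from two
conditions or from the automated vs. the manual workflow are compared by
paired quantiles and a two-sided Welch t-test.

Quantiles use linear interpolation between order statistics (the common
scientific-software default).  Summaries with fewer than
``LOW_N_THRESHOLD`` = 30 particles are flagged as low-n.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptyDistributionError, ValidationError
from .image_io import RawImage, SampleManifest, read_image, resolve_image_path
from .segmentation import ParticleTable, SegParams, segment_auto

#: Minimum number of analysed instances below which a summary is flagged.
LOW_N_THRESHOLD = 30

#: Default quantile levels for distribution comparisons (deciles).
DEFAULT_QUANTILE_LEVELS = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)

SUMMARY_CSV_COLUMNS = (
    "sample_id", "time_h", "n_images", "n_particles",
    "median_um2", "q1_um2", "q3_um2", "iqr_um2", "low_n_flag",
)


@dataclass
class AreaDistribution:
    """Pooled particle areas of one sample at one time point."""

    sample_id: str
    time_h: float
    areas_um2: np.ndarray
    n_images: int

    def __post_init__(self) -> None:
        areas = np.asarray(self.areas_um2, dtype=float)
        if areas.size and areas.min() <= 0:
            raise ValidationError("particle areas must be positive")
        self.areas_um2 = areas

    @property
    def n_particles(self) -> int:
        return int(self.areas_um2.size)


@dataclass(frozen=True)
class DistributionSummary:
    """Median/quartile summary of an area distribution."""

    median_um2: float
    q1_um2: float
    q3_um2: float
    iqr_um2: float
    n_particles: int
    low_n_flag: bool
    full_range: tuple[float, float]


@dataclass(frozen=True)
class ComparisonResult:
    """Paired-quantile and Welch-t comparison of two area distributions."""

    paired_quantiles: list[tuple[float, float, float]]  # (level, value_a, value_b)
    t_statistic: float
    p_value: float
    median_bias: float  # value_b - value_a at the median


def pool_distribution(
    tables: Sequence[ParticleTable],
    sample_id: str,
    time_h: float,
    min_area_um2: float | None = None,
) -> AreaDistribution:
    """Pool particle areas from all replicate images of one time point.

    Replicates are concatenated, not averaged, so every particle carries
    equal weight.  ``min_area_um2`` optionally applies a post-hoc µm²
    lower limit at pooling time (off by default).
    """
    if not tables:
        raise ValidationError("pool_distribution needs at least one particle table")
    areas = np.concatenate([t.areas_um2 for t in tables]) if tables else np.array([])
    if min_area_um2 is not None:
        areas = areas[areas >= min_area_um2]
    return AreaDistribution(
        sample_id=sample_id, time_h=float(time_h),
        areas_um2=areas, n_images=len(tables),
    )


def summarize(dist: AreaDistribution) -> DistributionSummary:
    """Median, quartiles and IQR of a pooled distribution.

    Raises :class:`EmptyDistributionError` on an empty distribution; the
    caller decides whether that aborts a run or becomes a marker row.
    """
    areas = dist.areas_um2
    if areas.size == 0:
        raise EmptyDistributionError(
            f"no particles for sample {dist.sample_id!r} at {dist.time_h} h"
        )
    q1, med, q3 = np.quantile(areas, [0.25, 0.5, 0.75])  # linear interpolation
    return DistributionSummary(
        median_um2=float(med),
        q1_um2=float(q1),
        q3_um2=float(q3),
        iqr_um2=float(q3 - q1),
        n_particles=dist.n_particles,
        low_n_flag=dist.n_particles < LOW_N_THRESHOLD,
        full_range=(float(areas.min()), float(areas.max())),
    )


def _summary_row(sample_id: str, time_h: float, n_images: int,
                 summary: DistributionSummary | None) -> dict:
    if summary is None:  # empty time point: keep the row, mark it
        return {
            "sample_id": sample_id, "time_h": time_h, "n_images": n_images,
            "n_particles": 0, "median_um2": np.nan, "q1_um2": np.nan,
            "q3_um2": np.nan, "iqr_um2": np.nan, "low_n_flag": True,
        }
    return {
        "sample_id": sample_id, "time_h": time_h, "n_images": n_images,
        "n_particles": summary.n_particles, "median_um2": summary.median_um2,
        "q1_um2": summary.q1_um2, "q3_um2": summary.q3_um2,
        "iqr_um2": summary.iqr_um2, "low_n_flag": summary.low_n_flag,
    }


def timeseries_summary(
    manifest: SampleManifest,
    params: SegParams | None = None,
    manifest_path: str | Path | None = None,
    segment: Callable[[RawImage, SegParams], ParticleTable] = segment_auto,
    min_area_um2: float | None = None,
) -> pd.DataFrame:
    """Segment every manifest image and summarise per (sample_id, time_h).

    Returns one row per time point, sorted by sample then time.  A time
    point where no particle survives filtering yields a marker row with
    ``n_particles`` 0 and NaN statistics; the run continues.
    """
    params = params or SegParams()
    rows = []
    for (sample_id, time_h), grp in manifest.groups():
        tables = []
        for p in grp["image_path"]:
            img_path = resolve_image_path(manifest_path, p) if manifest_path else Path(p)
            img = read_image(img_path, pixel_area_um2=params.pixel_area_um2)
            tables.append(segment(img, params))
        dist = pool_distribution(tables, sample_id, time_h, min_area_um2=min_area_um2)
        try:
            summary = summarize(dist)
        except EmptyDistributionError:
            summary = None
        rows.append(_summary_row(sample_id, time_h, len(grp), summary))
    df = pd.DataFrame(rows, columns=list(SUMMARY_CSV_COLUMNS))
    return df.sort_values(["sample_id", "time_h"], kind="mergesort").reset_index(drop=True)


def summaries_from_distributions(dists: Sequence[AreaDistribution]) -> pd.DataFrame:
    """Summary table straight from pre-pooled distributions (no segmentation)."""
    rows = []
    for d in dists:
        try:
            summary = summarize(d)
        except EmptyDistributionError:
            summary = None
        rows.append(_summary_row(d.sample_id, d.time_h, d.n_images, summary))
    df = pd.DataFrame(rows, columns=list(SUMMARY_CSV_COLUMNS))
    return df.sort_values(["sample_id", "time_h"], kind="mergesort").reset_index(drop=True)


def write_summary(df: pd.DataFrame, csv_path: str | Path,
                  json_path: str | Path | None = None,
                  params: SegParams | None = None) -> None:
    """Write a summary table as CSV and an optional JSON mirror with params."""
    df.to_csv(csv_path, index=False)
    if json_path is not None:
        payload = {
            "params": asdict(params) if params is not None else None,
            "summaries": json.loads(df.to_json(orient="records")),
        }
        Path(json_path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def compare_distributions(
    a: AreaDistribution,
    b: AreaDistribution,
    levels: Sequence[float] = DEFAULT_QUANTILE_LEVELS,
) -> ComparisonResult:
    """Compare two area distributions (e.g. automated vs. manual workflow).

    Welch's unequal-variance two-sided t-test on the raw areas, plus
    paired quantiles at ``levels`` and the bias at the median
    (``b`` − ``a``; negative when ``b`` underestimates ``a``).
    """
    if a.n_particles < 2 or b.n_particles < 2:
        raise ValidationError("t-test needs at least 2 particles per distribution")
    levels = list(levels)
    if any(not 0 < lv < 1 for lv in levels) or any(
        l2 <= l1 for l1, l2 in zip(levels, levels[1:])
    ):
        raise ValidationError("quantile levels must be strictly increasing in (0,1)")
    qa = np.quantile(a.areas_um2, levels)
    qb = np.quantile(b.areas_um2, levels)
    t_stat, p_value = stats.ttest_ind(a.areas_um2, b.areas_um2, equal_var=False)
    median_a, median_b = (np.quantile(x.areas_um2, 0.5) for x in (a, b))
    return ComparisonResult(
        paired_quantiles=[(float(l), float(x), float(y))
                          for l, x, y in zip(levels, qa, qb)],
        t_statistic=float(t_stat),
        p_value=float(p_value),
        median_bias=float(median_b - median_a),
    )
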