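"""Reproducibility statistics for microbioreactor backscatter time series.

Backscatter (scattered light) is a non-invasive proxy for biomass
concentration, measured every cultivation cycle (typically every 10 min)
in each replicate well.  Reproducibility across biological replicates is
quantified per cycle *i* by the coefficient of variation

    c_v,i = s_i / x̄_i

(sample standard deviation over arithmetic mean across wells), and over a
whole cultivation by the *relative mean coefficient of variation*

    rmcv = (Σ_i c_v,i) / m

averaged over the m cycles from the first cycle whose signal rises above
the limit of detection (LOD, one-sided α = 0.01) to the end of the
cultivation.  Outliers in replicate values are flagged by the
3-scaled-MAD rule, and the module also houses the backscatter-driven
dilution planner used to bring harvested samples to a target biomass
concentration before imaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import NoGrowthError, ParameterError, UndefinedCVError, ValidationError

#: Normal-consistency scaling of the median absolute deviation.
MAD_SCALE = 1.4826

#: Number of scaled MADs beyond which a value is an outlier.
MAD_K = 3.0


@dataclass
class BackscatterSeries:
    """Backscatter signal matrix: cycles × replicate wells.

    ``values[i, j]`` is the signal of well ``well_ids[j]`` at cycle ``i``
    (time ``time_h[i]``); missing measurements are NaN.
    """

    time_h: np.ndarray
    values: np.ndarray
    well_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        t = np.asarray(self.time_h, dtype=float)
        v = np.atleast_2d(np.asarray(self.values, dtype=float))
        if v.shape[0] != t.size:
            raise ValidationError(
                f"{t.size} time stamps but {v.shape[0]} value rows"
            )
        if v.shape[1] < 2:
            raise ValidationError("need >= 2 replicate wells for CV statistics")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValidationError("cycle times must be strictly increasing")
        if not self.well_ids:
            self.well_ids = [f"W{j + 1}" for j in range(v.shape[1])]
        if len(self.well_ids) != v.shape[1]:
            raise ValidationError("well_ids length must match value columns")
        self.time_h, self.values = t, v

    @property
    def n_cycles(self) -> int:
        return self.values.shape[0]

    @property
    def n_wells(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_long_csv(cls, path: str | Path) -> "BackscatterSeries":
        """Read the long-format dialect: columns cycle,time_h,well_id,value."""
        df = pd.read_csv(path)
        required = {"cycle", "time_h", "well_id", "value"}
        if not required.issubset(df.columns):
            raise ValidationError(
                f"backscatter CSV needs columns {sorted(required)}, "
                f"got {list(df.columns)}"
            )
        bad = df.index[df[["cycle", "time_h"]].isna().any(axis=1)]
        if len(bad):
            raise ValidationError(f"malformed rows (NaN cycle/time) at {list(bad + 2)}")
        wide = df.pivot_table(index=["cycle", "time_h"], columns="well_id",
                              values="value", aggfunc="first")
        wide = wide.sort_index()
        times = np.array([t for _, t in wide.index], dtype=float)
        return cls(time_h=times, values=wide.to_numpy(),
                   well_ids=[str(w) for w in wide.columns])

    def to_long_csv(self, path: str | Path) -> None:
        rows = []
        for i, t in enumerate(self.time_h):
            for j, well in enumerate(self.well_ids):
                v = self.values[i, j]
                if not np.isnan(v):
                    rows.append((i + 1, t, well, v))
        pd.DataFrame(rows, columns=["cycle", "time_h", "well_id", "value"]).to_csv(
            path, index=False
        )


@dataclass(frozen=True)
class RMCVResult:
    """Relative mean coefficient of variation over an onset-to-end window."""

    cv_per_cycle: np.ndarray
    start_cycle: int
    end_cycle: int
    m: int
    rmcv: float


@dataclass(frozen=True)
class OutlierFlags:
    """Boolean outlier flags (same shape as the input) plus a method note."""

    flags: np.ndarray
    method: str = f"|x - median| > {MAD_K:g} x {MAD_SCALE} x MAD"


@dataclass(frozen=True)
class DilutionPlan:
    """Dilution bringing a sample to a target backscatter-equivalent level."""

    current_signal: float
    target_signal: float
    dilution_factor: float
    sample_volume_uL: float
    diluent_volume_uL: float
    diluent: str = "0.9 % (w/v) NaCl"


def cv_per_cycle(series: BackscatterSeries) -> np.ndarray:
    """Per-cycle coefficient of variation s_i / x̄_i across replicate wells.

    Uses the sample (n−1) standard deviation.  Cycles with fewer than two
    non-missing replicates yield NaN (they are skipped downstream, with m
    reduced accordingly).  A cycle whose mean is ≤ 0 raises
    :class:`UndefinedCVError` naming the cycle.
    """
    values = series.values
    cvs = np.full(series.n_cycles, np.nan)
    for i in range(series.n_cycles):
        row = values[i][~np.isnan(values[i])]
        if row.size < 2:
            continue
        mean = row.mean()
        if mean <= 0:
            raise UndefinedCVError(
                f"cycle {i + 1}: mean {mean:g} <= 0, CV undefined"
            )
        cvs[i] = row.std(ddof=1) / mean
    return cvs


def detect_signal_start(
    series: BackscatterSeries,
    blank_cycles: int = 5,
    alpha: float = 0.01,
    persistence: int = 3,
) -> int:
    """First cycle (0-based) whose signal rises durably above the LOD.

    The LOD is estimated from the pooled values of the first
    ``blank_cycles`` cycles as mean + z_(1−α) × SD (one-sided normal
    quantile).  The start cycle is the first whose replicate mean exceeds
    the LOD and stays above it for ``persistence`` consecutive cycles.
    """
    if blank_cycles < 3:
        raise ParameterError("need >= 3 blank cycles to estimate the LOD")
    if series.n_cycles < blank_cycles:
        raise ParameterError("series shorter than the blank window")
    blank = series.values[:blank_cycles]
    blank = blank[~np.isnan(blank)]
    lod = blank.mean() + stats.norm.ppf(1 - alpha) * blank.std(ddof=1)
    means = np.nanmean(series.values, axis=1)
    above = means > lod
    run_end = series.n_cycles - persistence + 1
    for i in range(run_end):
        if above[i : i + persistence].all():
            return i
    raise NoGrowthError(
        f"no {persistence}-cycle run above the LOD ({lod:.4g}) found"
    )


def rmcv(
    series: BackscatterSeries,
    start_cycle: int | None = None,
    end_cycle: int | None = None,
    blank_cycles: int = 5,
    alpha: float = 0.01,
) -> RMCVResult:
    """Relative mean CV over cycles ``start_cycle``..``end_cycle`` (0-based,
    inclusive).

    When ``start_cycle`` is None it is detected with
    :func:`detect_signal_start`; ``end_cycle`` defaults to the last cycle.
    Cycles without a computable CV (fewer than two replicates) are skipped
    and ``m`` reduced.
    """
    if start_cycle is None:
        start_cycle = detect_signal_start(series, blank_cycles=blank_cycles, alpha=alpha)
    if end_cycle is None:
        end_cycle = series.n_cycles - 1
    if not (0 <= start_cycle <= end_cycle < series.n_cycles):
        raise ParameterError(
            f"invalid cycle range [{start_cycle}, {end_cycle}] "
            f"for {series.n_cycles} cycles"
        )
    cvs = cv_per_cycle(series)
    window = cvs[start_cycle : end_cycle + 1]
    included = window[~np.isnan(window)]
    if included.size == 0:
        raise UndefinedCVError("no computable CV in the requested cycle range")
    return RMCVResult(
        cv_per_cycle=cvs,
        start_cycle=int(start_cycle),
        end_cycle=int(end_cycle),
        m=int(included.size),
        rmcv=float(included.mean()),
    )


def detect_outliers(values: Sequence[float]) -> OutlierFlags:
    """3-scaled-MAD outlier rule.

    A value is flagged when it lies more than three scaled median absolute
    deviations (MAD × 1.4826) from the median.  When the MAD is zero the
    rule degenerates to flagging every value off the median, which leaves
    all-equal vectors unflagged.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValidationError("detect_outliers needs at least one value")
    med = np.median(x)
    scaled_mad = MAD_SCALE * np.median(np.abs(x - med))
    flags = np.abs(x - med) > MAD_K * scaled_mad
    return OutlierFlags(flags=flags)


def plan_dilution(
    current_signal: float,
    target_signal: float,
    sample_volume_uL: float = 350.0,
) -> DilutionPlan:
    """Plan the saline dilution bringing a sample to the target signal.

    Assumes signal ∝ biomass concentration, so
    ``factor = max(1, current / target)`` and the diluent volume is
    ``sample_volume × (factor − 1)``.  Samples already at or below the
    target are left undiluted.
    """
    if current_signal <= 0 or target_signal <= 0 or sample_volume_uL <= 0:
        raise ParameterError("signals and sample volume must be positive")
    factor = max(1.0, current_signal / target_signal)
    return DilutionPlan(
        current_signal=float(current_signal),
        target_signal=float(target_signal),
        dilution_factor=float(factor),
        sample_volume_uL=float(sample_volume_uL),
        diluent_volume_uL=float(sample_volume_uL * (factor - 1.0)),
    )
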