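"""Cumulative major-mistake-average (MMA) curves, period segmentation, and
trend fitting.

The MMA after attempt *n* is the proportion of attempts 1..n classified as
containing a major mistake:

    MMA(n) = (# major-mistake attempts among 1..n) / n

Plotted against the accumulated attempt count (NOA) it forms the learning
curve.  A *period* is a contiguous attempt range; its *absolute drop* is the
decrease in cumulative MMA from the previous period's endpoint to its own
endpoint, and its *drop rate* is that drop divided by the period's attempt
count.  A flat drop rate together with Poisson-conforming mistake counts
(see :mod:`lcgate.poisson_gate`) marks the skill plateau.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .records_io import AttemptRecord, MistakeRubric, is_major

__all__ = [
    "MMASeries",
    "PeriodSummary",
    "TrendFit",
    "major_indicators",
    "mma_series",
    "segment_periods",
    "tct_series",
    "fit_trend",
]


@dataclass(frozen=True)
class MMASeries:
    """Cumulative MMA indexed by attempt number (1-based)."""

    values: np.ndarray  # values[i] = MMA after attempt i+1

    def __len__(self) -> int:
        return len(self.values)

    def at(self, attempt: int) -> float:
        """Cumulative MMA after the given attempt number (1-based)."""
        if not 1 <= attempt <= len(self.values):
            raise IndexError(f"attempt {attempt} outside 1..{len(self.values)}")
        return float(self.values[attempt - 1])


@dataclass(frozen=True)
class PeriodSummary:
    """One learning-curve period and its drop statistics."""

    period: int
    start_attempt: int
    end_attempt: int
    mma_start: float  # cumulative MMA at the previous period's last attempt
    mma_end: float  # cumulative MMA at this period's last attempt
    n_major_in_period: int
    tct_average: float | None = None

    @property
    def noa(self) -> int:
        return self.end_attempt - self.start_attempt + 1

    @property
    def absolute_drop(self) -> float:
        return self.mma_start - self.mma_end

    @property
    def drop_rate(self) -> float:
        return self.absolute_drop / self.noa


@dataclass(frozen=True)
class TrendFit:
    """A fitted trend line.  For the exponential model the coefficients are
    on the log scale (``y ≈ exp(intercept + slope·x)``) while ``r_squared``
    is evaluated on the original y scale from back-transformed fits.
    ``r_squared`` is NaN when y is constant (zero total variance)."""

    model: str  # "linear" | "exponential"
    intercept: float
    slope: float
    r_squared: float

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        yhat = self.intercept + self.slope * x
        return np.exp(yhat) if self.model == "exponential" else yhat


def major_indicators(
    records: Sequence[AttemptRecord], rubric: MistakeRubric = MistakeRubric()
) -> np.ndarray:
    """Binary array whose n-th element (0-based n-1) is 1 iff attempt n is a
    major-mistake attempt.  Requires attempt indices contiguous from 1."""
    indices = [r.attempt_index for r in records]
    if sorted(indices) != list(range(1, len(records) + 1)):
        raise ValueError(
            "attempt indices are not contiguous from 1; run validate_attempts "
            "and repair the log first"
        )
    out = np.zeros(len(records), dtype=np.int64)
    for r in records:
        out[r.attempt_index - 1] = 1 if is_major(r, rubric) else 0
    return out


def mma_series(indicators: Sequence[int] | np.ndarray) -> MMASeries:
    """Cumulative MMA from a binary major-mistake indicator sequence."""
    ind = np.asarray(indicators, dtype=np.int64)
    if ind.ndim != 1 or len(ind) == 0:
        raise ValueError("indicators must be a non-empty 1-d sequence")
    if not np.isin(ind, (0, 1)).all():
        raise ValueError("indicators must be binary")
    n = np.arange(1, len(ind) + 1, dtype=float)
    return MMASeries(values=np.cumsum(ind) / n)


def segment_periods(
    series: MMASeries,
    indicators: Sequence[int] | np.ndarray,
    breakpoints: Sequence[int],
    records: Sequence[AttemptRecord] | None = None,
) -> list[PeriodSummary]:
    """Partition attempts 1..N into periods at the given breakpoints.

    ``breakpoints`` lists the *last* attempt of every period except the final
    one (e.g. ``[5, 12, 19, 36, 85]`` over 132 attempts yields six periods).
    An empty list yields a single whole-range period.

    ``mma_start`` of period k is the cumulative MMA at the last attempt of
    period k-1 (0.0 for the first period, before any attempt); ``mma_end`` is
    the cumulative MMA at period k's own last attempt.  When ``records`` are
    supplied, ``tct_average`` is the mean total time over *all* attempts of
    the period — untimed (aborted) attempts enter as 0 seconds, matching the
    convention of published period tables.
    """
    ind = np.asarray(indicators, dtype=np.int64)
    n = len(series)
    if len(ind) != n:
        raise ValueError("indicators and series lengths differ")
    bps = list(breakpoints)
    if bps != sorted(set(bps)):
        raise ValueError("breakpoints must be strictly increasing")
    if bps and not (1 <= bps[0] and bps[-1] < n):
        raise ValueError(f"breakpoints must lie within 1..{n - 1}")
    if records is not None and len(records) != n:
        raise ValueError("records and series lengths differ")

    edges = [0, *bps, n]  # period k spans attempts edges[k-1]+1 .. edges[k]
    periods: list[PeriodSummary] = []
    for k in range(1, len(edges)):
        start, end = edges[k - 1] + 1, edges[k]
        tct = None
        if records is not None:
            tct = float(np.mean([r.total_time for r in records[start - 1 : end]]))
        periods.append(
            PeriodSummary(
                period=k,
                start_attempt=start,
                end_attempt=end,
                mma_start=series.at(start - 1) if start > 1 else 0.0,
                mma_end=series.at(end),
                n_major_in_period=int(ind[start - 1 : end].sum()),
                tct_average=tct,
            )
        )
    return periods


def tct_series(
    records: Sequence[AttemptRecord],
) -> list[tuple[int, int]]:
    """(attempt_index, total_time) pairs for timed attempts, in attempt order.

    Attempts with ``total_time == 0`` (aborted by a major mistake, hence never
    timed) are excluded: they are missing observations of completion time, not
    instantaneous completions.
    """
    return [(r.attempt_index, r.total_time) for r in records if r.timed]


def fit_trend(
    x: Sequence[float], y: Sequence[float], model: str = "linear"
) -> TrendFit:
    """Least-squares trend of y on x.

    ``linear`` is ordinary least squares.  ``exponential`` fits log y on x by
    OLS (requires y > 0) and reports R² on the original scale, i.e.
    ``1 − SS_res/SS_tot`` with residuals of the back-transformed fitted
    values.  Constant y yields a valid fit with ``r_squared = NaN``.
    """
    if model not in ("linear", "exponential"):
        raise ValueError(f"model must be 'linear' or 'exponential', got {model!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d sequences of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points to fit a trend")

    if model == "exponential":
        if (y <= 0).any():
            raise ValueError("exponential model requires strictly positive y")
        target = np.log(y)
    else:
        target = y

    design = np.column_stack([np.ones_like(x), x])
    (intercept, slope), *_ = np.linalg.lstsq(design, target, rcond=None)

    fitted = design @ (intercept, slope)
    if model == "exponential":
        fitted = np.exp(fitted)
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else math.nan
    return TrendFit(model=model, intercept=float(intercept), slope=float(slope), r_squared=r2)


# ---------------------------------------------------------------------------
# presentation


def round_half_up(value: float, decimals: int) -> float:
    """Decimal rounding with ties away from zero, as in printed tables."""
    q = 10.0**decimals
    return math.floor(abs(value) * q + 0.5) / q * (1 if value >= 0 else -1)


def periods_table(periods: Sequence[PeriodSummary]) -> "pd.DataFrame":
    """Period summaries as a DataFrame in presentation form (MMA to 3
    decimals, drop rate to 4)."""
    import pandas as pd

    rows = [
        {
            "period": p.period,
            "start": p.start_attempt,
            "end": p.end_attempt,
            "noa": p.noa,
            "mma_end": round_half_up(p.mma_end, 3),
            "absolute_drop": round_half_up(p.absolute_drop, 3),
            "drop_rate": round_half_up(p.drop_rate, 4),
            "n_major": p.n_major_in_period,
            "tct_average": None if p.tct_average is None else round_half_up(p.tct_average, 2),
        }
        for p in periods
    ]
    return pd.DataFrame(rows)
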