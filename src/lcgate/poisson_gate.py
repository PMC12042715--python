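"""Poisson conformity testing of major-mistake occurrence.

Rationale: once a trainee's residual mistakes occur purely at random, their
counts over fixed-size blocks of attempts should be Poisson — variance equal
to mean.  Systematic influences (residual skill deficits, a still-decaying
hazard) inflate the variance.  The classical index-of-dispersion test

    D = (n − 1) · s² / x̄     over n block counts

is compared to the upper (1 − α) quantile of chi-squared(n − 1); D beyond the
threshold rejects Poisson ("negative" verdict = systematic errors), D within
it is a "positive" verdict = errors compatible with randomness.  The first
period of a learning curve with a positive verdict is read as the *efficient
skill threshold*: the attempt range from which mistakes no longer reflect a
skill deficit.

Per-attempt major-mistake indicators are Bernoulli and therefore structurally
underdispersed (variance ≤ mean); counts are accumulated over blocks of
consecutive attempts before testing.  The default block of 4 attempts mirrors
the typical training-session size of the protocol the method was developed
on.  A binned chi-squared goodness-of-fit variant is provided as an
alternative gate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from pydantic import BaseModel, Field
from scipy import stats

from .learning_curve import PeriodSummary

__all__ = [
    "DispersionResult",
    "GateConfig",
    "PlateauDecision",
    "bin_counts",
    "estimate_lambda",
    "chi2_critical",
    "dispersion_test",
    "gof_test",
    "detect_plateau",
]

POSITIVE = "positive"  # fails to reject Poisson → errors look random
NEGATIVE = "negative"  # rejects Poisson → systematic error structure
UNTESTABLE = "untestable"


class GateConfig(BaseModel):
    """Configuration of the Poisson gate."""

    block_size: int = Field(default=4, ge=2, description="attempts per count block")
    alpha: float = Field(default=0.05, gt=0.0, lt=1.0)
    test: str = Field(default="dispersion", pattern="^(dispersion|gof)$")


@dataclass(frozen=True)
class DispersionResult:
    """Outcome of one Poisson conformity test.

    ``lambda_hat`` is the mean count per block; ``verdict`` is ``positive``
    when the statistic does not exceed the critical value (Poisson not
    rejected), ``negative`` otherwise.  ``degenerate`` marks all-zero or
    zero-variance inputs where the verdict is trivially positive.
    """

    lambda_hat: float
    statistic: float
    df: int
    critical_value: float
    alpha: float
    verdict: str
    test: str = "dispersion"
    degenerate: bool = False


@dataclass(frozen=True)
class PlateauDecision:
    """Per-period gate results and the detected plateau.

    ``plateau_period`` is the 1-based position (within the supplied period
    list) of the first period whose verdict is positive, or None when no
    period conforms.  ``verdicts`` aligns with the input periods and includes
    ``untestable`` entries for periods too short to block.
    """

    results: tuple[DispersionResult | None, ...]
    verdicts: tuple[str, ...]
    plateau_period: int | None


def bin_counts(indicators: Sequence[int] | np.ndarray, block_size: int) -> np.ndarray:
    """Counts of events in consecutive non-overlapping blocks.

    A trailing short block (< ``block_size`` attempts) is dropped so block
    counts stay identically distributed under the Poisson null.  Requires at
    least two full blocks.
    """
    ind = np.asarray(indicators, dtype=np.int64)
    if block_size < 2:
        raise ValueError("block_size must be >= 2")
    n_blocks = len(ind) // block_size
    if n_blocks < 2:
        raise ValueError(
            f"period of {len(ind)} attempts yields {n_blocks} block(s) of "
            f"{block_size}; use a smaller block size or pool periods"
        )
    return ind[: n_blocks * block_size].reshape(n_blocks, block_size).sum(axis=1)


def estimate_lambda(indicators: Sequence[int] | np.ndarray) -> float:
    """Per-attempt major-mistake rate: events / attempts in the period."""
    ind = np.asarray(indicators, dtype=np.int64)
    if len(ind) == 0:
        raise ValueError("period must be non-empty")
    return float(ind.sum()) / len(ind)


def chi2_critical(df: int, alpha: float = 0.05) -> float:
    """Upper-tail (1 − alpha) quantile of the chi-squared distribution."""
    if df < 1:
        raise ValueError("df must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    return float(stats.chi2.ppf(1.0 - alpha, df))


def dispersion_test(
    counts: Sequence[int] | np.ndarray, alpha: float = 0.05
) -> DispersionResult:
    """Index-of-dispersion test of block counts against Poisson.

    D = (n−1)·s²/x̄ with s² the sample variance (ddof=1) and x̄ the mean over
    n ≥ 2 blocks; upper-tail comparison against chi-squared(n−1), since
    overdispersion is the signature of systematic error.  All-zero counts are
    a degenerate, trivially positive case.
    """
    c = np.asarray(counts, dtype=float)
    if len(c) < 2:
        raise ValueError("need at least 2 block counts")
    n = len(c)
    mean = c.mean()
    crit = chi2_critical(n - 1, alpha)
    if mean == 0.0:
        return DispersionResult(
            lambda_hat=0.0,
            statistic=0.0,
            df=n - 1,
            critical_value=crit,
            alpha=alpha,
            verdict=POSITIVE,
            degenerate=True,
        )
    stat = float(np.sum((c - mean) ** 2) / mean)  # == (n-1)·s²/x̄
    return DispersionResult(
        lambda_hat=float(mean),
        statistic=stat,
        df=n - 1,
        critical_value=crit,
        alpha=alpha,
        verdict=POSITIVE if stat <= crit else NEGATIVE,
        degenerate=bool(np.allclose(stat, 0.0) and mean > 0),
    )


def gof_test(
    counts: Sequence[int] | np.ndarray, alpha: float = 0.05
) -> DispersionResult:
    """Chi-squared goodness-of-fit of block-count frequencies to Poisson(λ̂).

    Counts are classed as 0, 1, ..., with the upper tail merged until every
    expected class count is ≥ 1; df = (#classes − 2), floored at 1 (one df
    spent on λ̂).  Falls back to :func:`dispersion_test` with a warning when
    fewer than 3 usable classes remain.
    """
    c = np.asarray(counts, dtype=np.int64)
    if len(c) < 5:
        raise ValueError("goodness-of-fit needs at least 5 block counts")
    n = len(c)
    lam = c.mean()
    if lam == 0.0:
        return DispersionResult(
            lambda_hat=0.0,
            statistic=0.0,
            df=1,
            critical_value=chi2_critical(1, alpha),
            alpha=alpha,
            verdict=POSITIVE,
            test="gof",
            degenerate=True,
        )

    # class k = count value k, last class = ">= kmax"; merge the tail upward
    # while its expected mass is < 1, but never below two classes
    kmax = int(c.max()) + 1
    while kmax > 1:
        tail_expected = n * (1.0 - stats.poisson.cdf(kmax - 1, lam))
        if tail_expected >= 1.0:
            break
        kmax -= 1
    expected = np.array(
        [n * stats.poisson.pmf(k, lam) for k in range(kmax)]
        + [n * (1.0 - stats.poisson.cdf(kmax - 1, lam))]
    )
    observed = np.array(
        [(c == k).sum() for k in range(kmax)] + [(c >= kmax).sum()], dtype=float
    )
    if len(observed) < 3:
        warnings.warn(
            "only two usable count classes after merging; the fit statistic "
            "reduces to a one-df presence/absence check",
            stacklevel=2,
        )

    stat = float(np.sum((observed - expected) ** 2 / expected))
    df = max(len(observed) - 2, 1)
    crit = chi2_critical(df, alpha)
    return DispersionResult(
        lambda_hat=float(lam),
        statistic=stat,
        df=df,
        critical_value=crit,
        alpha=alpha,
        verdict=POSITIVE if stat <= crit else NEGATIVE,
        test="gof",
    )


def _run_gate(
    indicators: np.ndarray, config: GateConfig
) -> DispersionResult | None:
    """One period through the configured test; None when untestable."""
    try:
        counts = bin_counts(indicators, config.block_size)
    except ValueError:
        return None
    try:
        if config.test == "gof":
            return gof_test(counts, config.alpha)
        return dispersion_test(counts, config.alpha)
    except ValueError:
        return None


def detect_plateau(
    periods: Sequence[tuple[PeriodSummary, Sequence[int] | np.ndarray]],
    config: GateConfig = GateConfig(),
) -> PlateauDecision:
    """Gate every period in chronological order and locate the plateau.

    Each item pairs a :class:`PeriodSummary` with that period's per-attempt
    major indicators.  Periods too short to form two blocks are reported as
    ``untestable`` rather than silently skipped.  The plateau (efficient
    skill threshold) is the first period with a positive verdict.
    """
    if not periods:
        raise ValueError("need at least one period")
    results: list[DispersionResult | None] = []
    verdicts: list[str] = []
    for _summary, ind in periods:
        res = _run_gate(np.asarray(ind, dtype=np.int64), config)
        results.append(res)
        verdicts.append(UNTESTABLE if res is None else res.verdict)
    if all(r is None for r in results):
        raise ValueError(
            "no period is long enough to test; reduce block_size or pool periods"
        )
    plateau = next(
        (i + 1 for i, v in enumerate(verdicts) if v == POSITIVE), None
    )
    return PlateauDecision(
        results=tuple(results), verdicts=tuple(verdicts), plateau_period=plateau
    )
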