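"""Synthetic attempt-log generation and study of the gate's behaviour.

The generator emulates the statistical structure the learning-curve method
assumes for a single trainee:

* an *unstable* early phase with a constant (typically high) per-attempt
  major-mistake probability — early performance is erratic and carries no
  usable trend;
* a *learning* phase in which the major-mistake hazard decays exponentially
  from ``p0`` toward an asymptote,
  ``p(t) = p_plateau + (p0 − p_plateau)·exp(−decay·(t − t1))``;
* a *plateau* with constant residual hazard ``p_plateau`` — the regime in
  which mistakes are Bernoulli at a fixed rate and block counts are
  (approximately) Poisson, which is exactly what the dispersion gate is
  meant to certify.

Task-completion time declines exponentially toward a floor with
multiplicative lognormal noise; attempts aborted by a major mistake record
time 0, matching real logs.  Majors are assigned to task stages with
configurable probabilities (adventitial dissection is the most error-prone
stage in practice).

All randomness flows from one seed through independent sub-streams, so e.g.
the mistake sequence is unchanged if only the time-noise settings move.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.optimize import minimize

from .poisson_gate import NEGATIVE, GateConfig, bin_counts, dispersion_test, gof_test
from .records_io import AttemptRecord

__all__ = [
    "SimConfig",
    "HazardFit",
    "hazard_profile",
    "simulate_indicators",
    "simulate_attempts",
    "operating_characteristics",
    "recover_parameters",
]


class SimConfig(BaseModel):
    """Parameters of the three-phase synthetic trainee.

    Defaults depict a 132-attempt single-operator trial: an unstable first 19
    attempts at a high constant hazard, a learning phase to attempt 85, then
    a plateau with a ~4% residual major-mistake rate; task time falls from
    about 2,500 s toward a 1,200 s floor with 25% session-to-session noise.
    """

    n_attempts: int = Field(default=132, ge=1)
    phase_bounds: tuple[int, int] = (19, 85)  # last attempt of phases 1 and 2
    p_unstable: float = Field(default=0.25, ge=0.0, le=1.0)
    p0: float = Field(default=0.10, ge=0.0, le=1.0)
    p_plateau: float = Field(default=0.04, ge=0.0, le=1.0)
    decay: float = Field(default=0.05, ge=0.0)
    tct_start: float = Field(default=2500.0, gt=0.0)
    tct_floor: float = Field(default=1200.0, gt=0.0)
    tct_decay: float = Field(default=0.02, ge=0.0)
    tct_cv: float = Field(default=0.25, ge=0.0)
    minor_score_probs: tuple[float, float, float] = (0.50, 0.35, 0.15)
    stage_time_props: tuple[float, float, float] = (0.30, 0.25, 0.45)
    major_stage_probs: tuple[float, float, float] = (2 / 11, 8 / 11, 1 / 11)
    attempts_per_session: int = Field(default=4, ge=1)
    session_gap_days: int = Field(default=4, ge=0)
    start_date: _dt.date = _dt.date(2024, 4, 18)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SimConfig":
        t1, t2 = self.phase_bounds
        if not (0 <= t1 < t2 <= self.n_attempts):
            raise ValueError(
                "phase_bounds must satisfy 0 <= end_unstable < end_learning "
                "<= n_attempts"
            )
        if self.p_plateau > self.p0:
            raise ValueError("p_plateau must not exceed p0")
        for name in ("minor_score_probs", "stage_time_props", "major_stage_probs"):
            v = getattr(self, name)
            if any(p < 0 for p in v) or abs(sum(v) - 1.0) > 1e-9:
                raise ValueError(f"{name} must be non-negative and sum to 1")
        return self


def hazard_profile(config: SimConfig) -> np.ndarray:
    """Per-attempt major-mistake probability p(t), t = 1..n_attempts."""
    t1, t2 = config.phase_bounds
    t = np.arange(1, config.n_attempts + 1, dtype=float)
    p = np.full(config.n_attempts, config.p_plateau)
    p[t <= t1] = config.p_unstable
    learning = (t > t1) & (t <= t2)
    p[learning] = config.p_plateau + (config.p0 - config.p_plateau) * np.exp(
        -config.decay * (t[learning] - t1)
    )
    return p


def simulate_indicators(config: SimConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Binary major-mistake sequence drawn from the phase hazard."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[0])
    return (rng.random(config.n_attempts) < hazard_profile(config)).astype(np.int64)


def _mean_one_lognormal(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    if cv == 0.0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def simulate_attempts(config: SimConfig) -> list[AttemptRecord]:
    """Draw a full synthetic attempt log.

    Major attempts get total score 5 on one stage and total time 0 (aborted,
    never timed); other attempts get a minor score in {0, 1, 2} and a timed
    record whose stage times sum exactly to the total.  Byte-identical output
    for identical config (the seed included).
    """
    streams = np.random.SeedSequence(config.seed).spawn(3)
    rng_major = np.random.default_rng(streams[0])
    rng_score = np.random.default_rng(streams[1])
    rng_time = np.random.default_rng(streams[2])

    majors = simulate_indicators(config, rng_major)
    n = config.n_attempts
    mu = config.tct_floor + (config.tct_start - config.tct_floor) * np.exp(
        -config.tct_decay * np.arange(1, n + 1)
    )
    times = np.maximum(1, np.rint(mu * _mean_one_lognormal(rng_time, config.tct_cv, n))).astype(int)

    records: list[AttemptRecord] = []
    for i in range(n):
        attempt = i + 1
        session = i // config.attempts_per_session
        date = config.start_date + _dt.timedelta(days=session * config.session_gap_days)
        if majors[i]:
            stage = rng_score.choice(3, p=config.major_stage_probs)
            mistakes: list[int | None] = [None, None, None]
            mistakes[stage] = 5
            records.append(
                AttemptRecord(
                    attempt_index=attempt,
                    date=date,
                    stage_mistakes=tuple(mistakes),
                    total_score=5,
                    stage_times=(None, None, None),
                    total_time=0,
                )
            )
            continue
        score = int(rng_score.choice(3, p=config.minor_score_probs))
        mistakes = [None, None, None]
        for _ in range(score):  # each minor point lands on one stage
            stage = rng_score.choice(3, p=(0.10, 0.45, 0.45))
            mistakes[stage] = (mistakes[stage] or 0) + 1
        total = int(times[i])
        s1 = int(round(config.stage_time_props[0] * total))
        s2 = int(round(config.stage_time_props[1] * total))
        s3 = total - s1 - s2
        records.append(
            AttemptRecord(
                attempt_index=attempt,
                date=date,
                stage_mistakes=tuple(mistakes),
                total_score=score,
                stage_times=(s1, s2, s3),
                total_time=total,
            )
        )
    return records


# ---------------------------------------------------------------------------
# operating characteristics of the gate


def _scenario_hazard(name: str, length: int, mean_rate: float) -> np.ndarray:
    """Per-attempt hazard for a named scenario, normalised to ``mean_rate``.

    ``stationary``: constant. ``decaying``: exponentially halving from start
    to end of the period. ``mixed``: halving over the first half, constant at
    its endpoint thereafter.
    """
    t = np.arange(length, dtype=float)
    if name == "stationary":
        raw = np.ones(length)
    elif name == "decaying":
        raw = 0.5 ** (t / max(length - 1, 1))
    elif name == "mixed":
        half = max(length // 2 - 1, 1)
        raw = 0.5 ** (np.minimum(t, half) / half)
    else:
        raise ValueError(f"unknown scenario {name!r}")
    p = raw * (mean_rate / raw.mean())
    if p.max() > 1.0:
        raise ValueError("scenario rate exceeds 1; lower mean_rate")
    return p


def operating_characteristics(
    config: SimConfig,
    gate: GateConfig = GateConfig(),
    n_reps: int = 1000,
    seed: int = 0,
    scenarios: Sequence[str] = ("stationary", "decaying", "mixed"),
) -> pd.DataFrame:
    """Monte-Carlo rejection rates of the gate under named hazard scenarios.

    Each scenario runs over a period the length of the config's plateau with
    the same mean per-attempt rate (``p_plateau``), so the stationary row
    estimates the type-I error and the others estimate power against
    still-improving trainees.  Rows carry the Monte-Carlo standard error of
    the rejection-rate estimate.
    """
    if n_reps < 100:
        raise ValueError("n_reps must be >= 100")
    length = config.n_attempts - config.phase_bounds[1]
    rows = []
    streams = np.random.SeedSequence(seed).spawn(len(scenarios))
    for scen, stream in zip(scenarios, streams):
        p = _scenario_hazard(scen, length, config.p_plateau)
        rng = np.random.default_rng(stream)
        draws = rng.random((n_reps, length)) < p  # shared draws per scenario seed
        rejected = 0
        for rep in range(n_reps):
            counts = bin_counts(draws[rep].astype(np.int64), gate.block_size)
            test = gof_test if gate.test == "gof" else dispersion_test
            rejected += test(counts, gate.alpha).verdict == NEGATIVE
        rate = rejected / n_reps
        rows.append(
            {
                "scenario": scen,
                "alpha": gate.alpha,
                "block_size": gate.block_size,
                "n_reps": n_reps,
                "reject_rate": rate,
                "mc_se": float(np.sqrt(rate * (1 - rate) / n_reps)),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# parameter recovery


@dataclass(frozen=True)
class HazardFit:
    """Maximum-likelihood fit of the plateau-hazard model
    ``p(t) = p_plateau + (p0 − p_plateau)·exp(−decay·(t − 1))``."""

    p0: float
    p_plateau: float
    decay: float
    log_likelihood: float
    converged: bool
    boundary: bool  # estimate pinned at a parameter bound (e.g. no majors)


def _nll(theta: np.ndarray, t: np.ndarray, y: np.ndarray) -> float:
    # theta = (p_plateau, delta, k) with p0 = p_plateau + delta, so the fitted
    # hazard is decaying by construction (delta >= 0)
    pp, delta, k = theta
    p = pp + delta * np.exp(-k * (t - 1.0))
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return -float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))


def recover_parameters(
    data: Sequence[AttemptRecord] | Sequence[int] | np.ndarray,
    n_starts: int = 8,
    seed: int = 0,
) -> HazardFit:
    """Fit the decaying Bernoulli hazard to an attempt log by exact MLE.

    ``data`` is either a record list (majors derived with the default rubric)
    or a binary indicator sequence of at least 100 attempts.  The exact
    Bernoulli log-likelihood is maximised numerically (L-BFGS-B, multiple
    deterministic starts).  With no majors at all the likelihood is maximised
    on the p→0 boundary; the fit is returned with ``boundary=True``.
    """
    if len(data) and isinstance(data[0], AttemptRecord):
        from .learning_curve import major_indicators

        y = major_indicators(data)  # type: ignore[arg-type]
    else:
        y = np.asarray(data, dtype=float)
    if len(y) < 100:
        raise ValueError("need at least 100 attempts for recovery")
    t = np.arange(1, len(y) + 1, dtype=float)

    if y.sum() == 0:
        return HazardFit(
            p0=0.0, p_plateau=0.0, decay=0.0,
            log_likelihood=0.0, converged=True, boundary=True,
        )

    rate = y.mean()
    rng = np.random.default_rng(seed)
    starts = [np.array([rate, 2 * rate, 0.05])]
    for _ in range(n_starts - 1):
        starts.append(
            np.array(
                [rng.uniform(1e-3, rate + 0.05), rng.uniform(0.0, 0.5),
                 10 ** rng.uniform(-3, 0)]
            )
        )
    bounds = [(1e-6, 1 - 1e-6), (0.0, 1 - 1e-6), (0.0, 10.0)]
    best = None
    for x0 in starts:
        res = minimize(_nll, x0, args=(t, y), method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    pp, delta, k = best.x
    if delta <= 1e-8:  # no decaying component: decay rate is unidentified
        delta, k = 0.0, 0.0
    p0 = min(pp + delta, 1.0)
    on_boundary = bool(pp <= 2e-6 or p0 >= 1 - 2e-6 or k >= 10.0 - 1e-6)
    return HazardFit(
        p0=float(p0),
        p_plateau=float(pp),
        decay=float(k),
        log_likelihood=-float(best.fun),
        converged=bool(best.success),
        boundary=on_boundary,
    )
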