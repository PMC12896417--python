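"""Stage-structured offspring survival and rank-based group comparison.

Offspring are tracked through discrete developmental stages
(egg -> hatchling -> juvenile -> adult) with death or abnormal development
as the event; nobody is lost to follow-up, so the Kaplan--Meier product of
per-stage survival probabilities equals final survivors / initial count.
Two cohorts are compared with a log-rank test over stage-indexed event
times.  Count comparisons between sublines use the Mann--Whitney U test
with the plain normal approximation z = (U - n1*n2/2) / sqrt(n1*n2*(N+1)/12)
and effect size r = |z| / sqrt(N).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from lifelines.statistics import logrank_test
from scipy import stats

from .errors import InputError

DEFAULT_STAGES = ("hatchling", "juvenile", "adult")


@dataclass
class StageCohort:
    """One subline's offspring cohort with per-stage event (death/abnormal) counts.

    ``events[k]`` individuals fail at the transition into ``stages[k]``;
    survivors of the last stage are normal adults.
    """

    subline: str
    n_start: int
    events: Sequence[int]
    stages: Sequence[str] = DEFAULT_STAGES

    def __post_init__(self) -> None:
        if len(self.events) != len(self.stages):
            raise InputError("one event count per stage is required")
        if any(e < 0 for e in self.events):
            raise InputError("event counts must be non-negative")
        if sum(self.events) > self.n_start:
            raise InputError("more events than individuals at risk")

    @property
    def at_risk(self) -> list[int]:
        out, n = [], self.n_start
        for e in self.events:
            out.append(n)
            n -= e
        return out

    @property
    def survivors(self) -> int:
        return self.n_start - sum(self.events)


@dataclass
class SurvivalResult:
    stage_probabilities: list[float]
    cumulative: float
    percent_alive: float
    stages: Sequence[str] = field(default_factory=list)


def stage_survival(cohort: StageCohort) -> SurvivalResult:
    """Kaplan--Meier product over stages.

    Each stage's conditional survival is survivors/at-risk; with no
    censoring the product telescopes to final survivors / n_start.
    """
    probs = []
    for n, e in zip(cohort.at_risk, cohort.events):
        if n == 0:
            probs.append(0.0)
            continue
        if e > n:
            raise InputError("events exceed at-risk count")
        probs.append((n - e) / n)
    cumulative = float(np.prod(probs)) if probs else 1.0
    return SurvivalResult(
        stage_probabilities=probs,
        cumulative=cumulative,
        percent_alive=100.0 * cumulative,
        stages=list(cohort.stages),
    )


def _flatten(cohort: StageCohort) -> tuple[np.ndarray, np.ndarray]:
    n_stages = len(cohort.stages)
    durations, observed = [], []
    for k, e in enumerate(cohort.events, start=1):
        durations.extend([k] * e)
        observed.extend([1] * e)
    durations.extend([n_stages] * cohort.survivors)
    observed.extend([0] * cohort.survivors)
    return np.array(durations), np.array(observed)


def log_rank(a: StageCohort, b: StageCohort) -> tuple[float, float]:
    """Two-group log-rank test over stage-indexed event times -> (chi2, p)."""
    if list(a.stages) != list(b.stages):
        raise InputError("cohorts must share the same stage structure")
    if a.n_start == 0 or b.n_start == 0:
        raise InputError("empty cohort")
    da, oa = _flatten(a)
    db, ob = _flatten(b)
    res = logrank_test(da, db, event_observed_A=oa, event_observed_B=ob)
    return float(res.test_statistic), float(res.p_value)


@dataclass
class MWResult:
    u: float
    z: float
    pvalue: float
    r: float
    n1: int
    n2: int


def mann_whitney(
    x: Sequence[float] | None = None,
    y: Sequence[float] | None = None,
    *,
    u: float | None = None,
    n1: int | None = None,
    n2: int | None = None,
) -> MWResult:
    """Mann--Whitney U with normal-approximation z, two-sided p and effect size r.

    Either raw samples ``x``/``y`` (U computed by rank summation with
    midranks for ties) or a precomputed ``u`` with group sizes.  z is signed
    negative when the first group has the smaller rank sum; no tie or
    continuity correction is applied (the convention the reproduced summary
    statistics follow), and r = |z| / sqrt(n1 + n2).
    """
    if x is not None and y is not None:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        n1, n2 = len(x), len(y)
        if n1 < 1 or n2 < 1:
            raise InputError("both samples must be non-empty")
        u = float(stats.mannwhitneyu(x, y, alternative="two-sided").statistic)
    elif u is None or n1 is None or n2 is None:
        raise InputError("provide either two samples or (u, n1, n2)")
    if n1 < 1 or n2 < 1:
        raise InputError("group sizes must be >= 1")
    if not 0 <= u <= n1 * n2:
        raise InputError(f"U = {u} outside [0, {n1 * n2}]")
    mean_u = n1 * n2 / 2.0
    sd_u = np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
    z = (u - mean_u) / sd_u
    p = 2.0 * stats.norm.sf(abs(z))
    r = abs(z) / np.sqrt(n1 + n2)
    return MWResult(u=float(u), z=float(z), pvalue=float(p), r=float(r), n1=int(n1), n2=int(n2))
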