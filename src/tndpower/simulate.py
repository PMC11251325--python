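"""Monte-Carlo generator for TND and case-control study data.

The generator emulates a care-seeking source population of ``N``
individuals observed over a study period ``tau``:

* vaccination is assigned to an exact count ``round(N p_N)`` of randomly
  chosen individuals; an all-or-none vaccine fully protects an exact count
  ``round(round(N p_N) VE)`` of the vaccinated (half-up rounding);
* each unprotected individual may test positive at most once, at an
  exponential(``lambda_i``) time retained if it falls within ``tau``
  (short-term immunity after infection with the target pathogen);
* every individual tests negative at the arrival times of a homogeneous
  Poisson process of rate ``lambda_n``, truncated to the first three
  arrivals (additional negative tests are disregarded); testing positive
  does not remove an individual from negative-test risk;
* diagnostic testing has perfect sensitivity and specificity.

Two sampling designs turn an event log into a 2x2 table: the passive TND
takes the first ``n`` tests in time order; the case-control design fixes
the column margin, taking the first ``round(n pi)`` positives in time
order and a simple random sample of negatives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .design_core import (
    DesignParams,
    InvalidParameterError,
    NumericFailureError,
    derive,
    source_population_size,
    unit_cell_counts,
)
from .tests_2x2 import Table2x2

__all__ = [
    "InsufficientEventsError",
    "Cohort",
    "EventLog",
    "SampledStudy",
    "build_cohort",
    "generate_test_events",
    "sample_tnd",
    "sample_case_control",
    "simulate_study",
]

MAX_NEGATIVE_TESTS = 3


class InsufficientEventsError(RuntimeError):
    """A case-control replicate did not accrue enough positive or negative
    events by the end of the study period; the caller redraws."""


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


@dataclass(frozen=True)
class Cohort:
    """Source population with per-individual vaccination and protection
    indicators; protection implies vaccination."""

    vaccinated: np.ndarray  # bool, shape (N,)
    protected: np.ndarray   # bool, shape (N,)

    @property
    def size(self) -> int:
        return self.vaccinated.shape[0]


@dataclass(frozen=True)
class EventLog:
    """All test events of a cohort over one study period, unordered."""

    time: np.ndarray        # float days in (0, tau]
    positive: np.ndarray    # bool: True = positive test
    vaccinated: np.ndarray  # bool: vaccination status of the tested person
    individual: np.ndarray  # int: index into the cohort
    tau: float

    def __len__(self) -> int:
        return self.time.shape[0]


@dataclass(frozen=True)
class SampledStudy:
    """A 2x2 table sampled from an event log under one design."""

    table: Table2x2
    design: str                # "tnd" or "case_control"
    realized_duration: float   # time of the last included event
    realized_pi: float         # (a+c) / n
    truncated: bool = False    # TND only: fewer than n events by tau
    redraws: int = 0           # case-control only: invalid replicates redrawn


def build_cohort(n_population: int, coverage: float, ve: float,
                 rng: np.random.Generator) -> Cohort:
    """Randomly assign vaccination and all-or-none protection to exact
    counts (half-up rounding) of a population of ``n_population``."""
    if n_population < 2:
        raise InvalidParameterError(
            f"population must have at least 2 members, got {n_population}")
    n_vacc = _round_half_up(n_population * coverage)
    if n_vacc < 1 or n_vacc > n_population - 1:
        raise InvalidParameterError(
            "population too small to contain both a vaccinated and an "
            f"unvaccinated member (N={n_population}, coverage={coverage})")
    n_prot = _round_half_up(n_vacc * ve)
    order = rng.permutation(n_population)
    vaccinated = np.zeros(n_population, dtype=bool)
    vaccinated[order[:n_vacc]] = True
    protected = np.zeros(n_population, dtype=bool)
    protected[order[:n_prot]] = True  # a random subset of the vaccinated
    return Cohort(vaccinated=vaccinated, protected=protected)


def generate_test_events(cohort: Cohort, lambda_i: float, lambda_n: float,
                         tau: float, rng: np.random.Generator,
                         max_negatives: int = MAX_NEGATIVE_TESTS) -> EventLog:
    """Draw one study period of test events for every cohort member.

    Positive-test times are exponential(``lambda_i``) for unprotected
    individuals, kept if within ``tau`` (so the per-person probability of a
    positive test is ``1 - e^{-lambda_i tau}``). Negative-test times are
    the first ``max_negatives`` arrivals of a rate-``lambda_n`` Poisson
    process on ``(0, tau]``, built from cumulative exponential
    inter-arrival gaps.
    """
    if lambda_i < 0.0 or lambda_n < 0.0:
        raise InvalidParameterError("hazards must be non-negative")
    if tau <= 0.0:
        raise InvalidParameterError(f"tau must be > 0, got {tau}")
    n = cohort.size
    parts_t, parts_pos, parts_ind = [], [], []

    if lambda_i > 0.0:
        t_pos = rng.exponential(1.0 / lambda_i, size=n)
        keep = (t_pos <= tau) & ~cohort.protected
        idx = np.nonzero(keep)[0]
        parts_t.append(t_pos[idx])
        parts_pos.append(np.ones(idx.size, dtype=bool))
        parts_ind.append(idx)

    if lambda_n > 0.0:
        gaps = rng.exponential(1.0 / lambda_n, size=(n, max_negatives))
        arrivals = np.cumsum(gaps, axis=1)
        keep = arrivals <= tau
        ind, _ = np.nonzero(keep)
        parts_t.append(arrivals[keep])
        parts_pos.append(np.zeros(ind.size, dtype=bool))
        parts_ind.append(ind)

    if parts_t:
        time = np.concatenate(parts_t)
        positive = np.concatenate(parts_pos)
        individual = np.concatenate(parts_ind)
    else:  # both hazards zero is rejected upstream, but stay defensive
        time = np.empty(0)
        positive = np.empty(0, dtype=bool)
        individual = np.empty(0, dtype=np.intp)
    return EventLog(time=time, positive=positive,
                    vaccinated=cohort.vaccinated[individual],
                    individual=individual, tau=tau)


def _tabulate(positive: np.ndarray, vaccinated: np.ndarray) -> Table2x2:
    a = int(np.count_nonzero(positive & vaccinated))
    b = int(np.count_nonzero(~positive & vaccinated))
    c = int(np.count_nonzero(positive & ~vaccinated))
    d = int(np.count_nonzero(~positive & ~vaccinated))
    return Table2x2(a=a, b=b, c=c, d=d)


def _time_order(time: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    # ties (possible in floating point) broken by an independent uniform draw
    return np.lexsort((rng.random(time.shape[0]), time))


def sample_tnd(log: EventLog, n: int,
               rng: np.random.Generator) -> SampledStudy:
    """Passive TND sampling: the first ``n`` tests in time order.

    If fewer than ``n`` events accrued by ``tau`` the study is returned
    with all events and ``truncated=True``.
    """
    if n < 1:
        raise InvalidParameterError(f"n must be >= 1, got {n}")
    order = _time_order(log.time, rng)
    truncated = len(log) < n
    take = order if truncated else order[:n]
    positive = log.positive[take]
    vaccinated = log.vaccinated[take]
    table = _tabulate(positive, vaccinated)
    duration = float(log.time[take].max()) if take.size else 0.0
    return SampledStudy(table=table, design="tnd",
                        realized_duration=duration,
                        realized_pi=table.n_positive / max(table.n, 1),
                        truncated=truncated)


def sample_case_control(log: EventLog, n: int, pi: float,
                        rng: np.random.Generator) -> SampledStudy:
    """Case-control sampling with the column margin fixed by design.

    Takes the first ``round(n pi)`` positive tests in time order and a
    simple random sample (without replacement) of ``n - round(n pi)``
    negative tests from all negatives on ``(0, tau]``.
    """
    if n < 1:
        raise InvalidParameterError(f"n must be >= 1, got {n}")
    if not 0.0 < pi < 1.0:
        raise InvalidParameterError(f"pi must be in (0, 1), got {pi}")
    n_pos = _round_half_up(n * pi)
    n_neg = n - n_pos
    pos_idx = np.nonzero(log.positive)[0]
    neg_idx = np.nonzero(~log.positive)[0]
    if pos_idx.size < n_pos:
        raise InsufficientEventsError(
            f"needed {n_pos} positive tests, saw {pos_idx.size}")
    if neg_idx.size < n_neg:
        raise InsufficientEventsError(
            f"needed {n_neg} negative tests, saw {neg_idx.size}")
    pos_order = _time_order(log.time[pos_idx], rng)
    pos_take = pos_idx[pos_order[:n_pos]]
    neg_take = rng.choice(neg_idx, size=n_neg, replace=False)
    take = np.concatenate([pos_take, neg_take])
    table = _tabulate(log.positive[take], log.vaccinated[take])
    duration = float(log.time[take].max()) if take.size else 0.0
    return SampledStudy(table=table, design="case_control",
                        realized_duration=duration,
                        realized_pi=table.n_positive / table.n)


def simulate_study(params: DesignParams, n: int, design: str,
                   rng: np.random.Generator,
                   max_redraws: int = 1000) -> SampledStudy:
    """Generate one replicate of a study of total size ``n``.

    The source-population size is set so that ``n`` tests are expected
    within the study period. For the case-control design, replicates with
    too few positive or negative events are redrawn with fresh randomness
    (the redraw count is recorded on the result).
    """
    if design not in ("tnd", "case_control"):
        raise InvalidParameterError(f"unknown design {design!r}")
    if not params.has_hazards:
        raise InvalidParameterError(
            "simulation requires the hazard parameterization")
    units = unit_cell_counts(params)
    n_population = source_population_size(n, units)
    if design == "tnd":
        cohort = build_cohort(n_population, params.coverage, params.ve, rng)
        log = generate_test_events(cohort, params.lambda_i, params.lambda_n,
                                   params.tau, rng)
        return sample_tnd(log, n, rng)
    pi = derive(params).pi
    for attempt in range(max_redraws + 1):
        cohort = build_cohort(n_population, params.coverage, params.ve, rng)
        log = generate_test_events(cohort, params.lambda_i, params.lambda_n,
                                   params.tau, rng)
        try:
            study = sample_case_control(log, n, pi, rng)
        except InsufficientEventsError:
            continue
        return replace(study, redraws=attempt)
    raise NumericFailureError(
        f"case-control replicate invalid after {max_redraws} redraws "
        f"(scenario {params})")
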