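"""Monte-Carlo evaluation: power, type-I error, zero-cell frequency and the
continuity-correction bias scan.

Each summary is computed over independent replicates of
:func:`tndpower.simulate.simulate_study`, with a per-replicate RNG stream
spawned from a single root seed so any replicate is reproducible in
isolation. Intractable Wald outcomes count as non-rejections unless the
fallback mode re-tests them with the Yates-corrected statistic; intractable
score outcomes (zero margins) count as non-rejections.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as dc_replace

import numpy as np

from .design_core import DesignParams, InvalidParameterError
from .simulate import simulate_study
from .tests_2x2 import Table2x2, score_test, wald_cc_test, wald_test

__all__ = [
    "MonteCarloSummary",
    "BiasScanResult",
    "estimate_rejection_rate",
    "zero_cell_frequency",
    "continuity_scan",
]

DESIGNS = ("tnd", "case_control")
TESTS = ("wald", "wald_cc", "score")


@dataclass(frozen=True)
class MonteCarloSummary:
    """A Monte-Carlo rate (rejection or zero-cell proportion) with its
    binomial standard error ``sqrt(p(1-p)/reps)``."""

    metric: str          # "power", "type1" or "zero_cell"
    design: str
    method: str | None   # test used; None for zero-cell counts
    n: int
    reps: int
    rate: float
    mc_se: float
    seed: int
    truncated_rate: float = 0.0   # TND replicates short of n events
    redraw_total: int = 0         # case-control replicates redrawn


@dataclass(frozen=True)
class BiasScanResult:
    """Bias and spread of the log odds ratio across a continuity-correction
    grid.

    ``bias[j]`` is the mean of ``log_odds_ratio(table, deltas[j])`` minus
    the true log odds ratio ``ln(1 - VE)``; ``se[j]`` the standard
    deviation of the estimates across replicates. Entries at ``delta = 0``
    are NaN (flagged intractable) whenever any replicate has a zero cell.
    """

    deltas: np.ndarray
    bias: np.ndarray
    se: np.ndarray
    n_intractable_at_zero: int
    reps: int
    seed: int
    true_log_or: float


def _replicate_rngs(seed: int, reps: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s)
            for s in np.random.SeedSequence(seed).spawn(reps)]


def _run_test(test: str, table: Table2x2, theta0: float, alpha: float,
              wald_fallback: bool, delta: float) -> bool:
    if test == "wald":
        result = wald_test(table, theta0, alpha)
        if not result.tractable and wald_fallback:
            result = wald_cc_test(table, theta0, alpha, delta)
        return result.reject
    if test == "wald_cc":
        return wald_cc_test(table, theta0, alpha, delta).reject
    if test == "score":
        return score_test(table, theta0, alpha).reject
    raise InvalidParameterError(f"unknown test {test!r}")


def _check_config(design: str, reps: int) -> None:
    if design not in DESIGNS:
        raise InvalidParameterError(f"unknown design {design!r}")
    if reps < 100:
        raise InvalidParameterError(f"reps must be >= 100, got {reps}")


def estimate_rejection_rate(params: DesignParams, design: str, test: str,
                            n: int, reps: int, seed: int, *,
                            wald_fallback: bool = False,
                            under_null: bool = False,
                            delta: float = 0.5) -> MonteCarloSummary:
    """Simulated rejection proportion of a one-sided test.

    With ``under_null=True`` the data are generated at the null boundary
    ``VE = 1 - theta0`` (type-I error mode; ``VE = 0`` for ``theta0 = 1``)
    while the test itself is unchanged; otherwise the scenario VE is used
    (power mode). ``wald_fallback`` substitutes the continuity-corrected
    statistic when the standard Wald statistic is intractable.
    """
    _check_config(design, reps)
    if test not in TESTS:
        raise InvalidParameterError(f"unknown test {test!r}")
    if under_null:
        if params.theta0 > 1.0:
            raise InvalidParameterError(
                "type-I mode requires theta0 <= 1 so VE = 1 - theta0 is a "
                "valid effectiveness")
        params = dc_replace(params, ve=1.0 - params.theta0)
    rejections = truncated = redraws = 0
    for rng in _replicate_rngs(seed, reps):
        study = simulate_study(params, n, design, rng)
        truncated += study.truncated
        redraws += study.redraws
        rejections += _run_test(test, study.table, params.theta0,
                                params.alpha, wald_fallback, delta)
    rate = rejections / reps
    return MonteCarloSummary(
        metric="type1" if under_null else "power", design=design,
        method=test, n=n, reps=reps, rate=rate,
        mc_se=math.sqrt(rate * (1.0 - rate) / reps), seed=seed,
        truncated_rate=truncated / reps, redraw_total=redraws)


def zero_cell_frequency(params: DesignParams, design: str, n: int, reps: int,
                        seed: int) -> MonteCarloSummary:
    """Proportion of replicates with zero vaccinated test-positives
    (cell ``a = 0``), the cell that makes the Wald statistic intractable
    under high VE."""
    _check_config(design, reps)
    zeros = truncated = redraws = 0
    for rng in _replicate_rngs(seed, reps):
        study = simulate_study(params, n, design, rng)
        truncated += study.truncated
        redraws += study.redraws
        zeros += study.table.a == 0
    rate = zeros / reps
    return MonteCarloSummary(
        metric="zero_cell", design=design, method=None, n=n, reps=reps,
        rate=rate, mc_se=math.sqrt(rate * (1.0 - rate) / reps), seed=seed,
        truncated_rate=truncated / reps, redraw_total=redraws)


def continuity_scan(params: DesignParams, design: str, n: int,
                    deltas, reps: int, seed: int) -> BiasScanResult:
    """Bias and standard error of the log odds ratio over a grid of
    continuity corrections in ``[0, 2]``.

    The true log odds ratio is ``ln(1 - VE)``, exact under the all-or-none
    construction of ``p_I``. At ``delta = 0`` the estimator is intractable
    whenever a replicate contains a zero cell; those grid entries are
    flagged with NaN and the count of affected replicates is reported.
    """
    _check_config(design, reps)
    deltas = np.asarray(deltas, dtype=float)
    if deltas.size == 0 or deltas.min() < 0.0 or deltas.max() > 2.0:
        raise InvalidParameterError("deltas must lie in [0, 2]")
    if params.ve >= 1.0:
        raise InvalidParameterError("true log OR undefined at ve = 1")
    tables: list[Table2x2] = []
    for rng in _replicate_rngs(seed, reps):
        tables.append(simulate_study(params, n, design, rng).table)
    true_log_or = math.log(1.0 - params.ve)
    n_zero = sum(t.has_zero_cell for t in tables)
    bias = np.empty_like(deltas)
    se = np.empty_like(deltas)
    a, b, c, d = (np.array([getattr(t, f) for t in tables], dtype=float)
                  for f in "abcd")
    for j, delta in enumerate(deltas):
        if delta == 0.0 and n_zero > 0:
            bias[j] = np.nan
            se[j] = np.nan
            continue
        log_or = np.log((a + delta) * (d + delta)
                        / ((b + delta) * (c + delta)))
        bias[j] = log_or.mean() - true_log_or
        se[j] = log_or.std(ddof=1)
    return BiasScanResult(deltas=deltas, bias=bias, se=se,
                          n_intractable_at_zero=int(n_zero), reps=reps,
                          seed=seed, true_log_or=true_log_or)
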