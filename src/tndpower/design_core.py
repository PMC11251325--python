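"""Design parameters and closed-form derived quantities for TND studies.

A test-negative design (TND) enrolls symptomatic care-seekers, tests them
for the vaccine-targeted pathogen, and compares vaccination odds between
test-positives and test-negatives; vaccine effectiveness is ``VE = 1 - OR``.
This module holds the scenario parameters and every closed-form quantity
shared by the sample-size formulas and the simulator:

* ``p_I`` — expected fraction vaccinated among test-positives,
  ``p_N (1 - VE) / (1 - p_N VE)``, where ``p_N`` is the vaccination
  coverage observed among test-negatives;
* ``pi`` — expected percent positivity (fraction of positives among all
  tests), derived from the cumulative hazards of test-positive and
  test-negative illness over the study period, or supplied directly from
  surveillance data;
* the null/alternative variance components ``sigma0^2`` / ``sigma1^2``
  of ``p_I_hat - p_N_hat`` under the score (pooled-null) likelihood, and
  the multinomial-based alternative variance used by the TND-adjusted
  power calculation;
* expected per-capita 2x2 cell counts, which size the source population
  so that ``n`` tests accrue within the study period.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "InvalidParameterError",
    "UndefinedVarianceError",
    "NumericFailureError",
    "DesignParams",
    "DerivedDesign",
    "derive_p_i",
    "derive_pi",
    "unit_cell_counts",
    "source_population_size",
    "variance_components",
    "multinomial_variance",
    "derive",
]


class InvalidParameterError(ValueError):
    """A design parameter is outside its valid domain."""


class UndefinedVarianceError(InvalidParameterError):
    """The multinomial alternative variance diverges (``pi_hat`` is 0 or 1)."""


class NumericFailureError(RuntimeError):
    """An iterative numeric routine failed to converge."""


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise InvalidParameterError(msg)


@dataclass(frozen=True)
class DesignParams:
    """A TND study scenario.

    Parameters
    ----------
    ve : float
        Assumed vaccine effectiveness, ``1 - OR``, in ``[0, 1]``.
    coverage : float
        Expected fraction vaccinated among test-negatives (``p_N``), a
        proxy for population vaccination coverage; strictly in ``(0, 1)``.
    lambda_i, lambda_n : float, optional
        Constant hazards (per day) of test-positive and test-negative
        illness. Together with ``tau`` they define the cumulative hazards
        ``Lambda_I = lambda_i * tau`` and ``Lambda_N = lambda_n * tau``.
    tau : float, optional
        Study period in days.
    pi : float, optional
        Percent positivity supplied directly (e.g. from historical
        surveillance). Mutually exclusive with the hazard path: a scenario
        specifies either ``(lambda_i, lambda_n, tau)`` or ``pi``, never both.
    theta0 : float
        Null odds ratio of the one-sided test ``H0: OR >= theta0``.
    alpha : float
        One-sided significance level, in ``(0, 0.5)``.
    gamma : float
        One minus the target power.
    """

    ve: float
    coverage: float
    lambda_i: float | None = None
    lambda_n: float | None = None
    tau: float | None = None
    pi: float | None = None
    theta0: float = 1.0
    alpha: float = 0.025
    gamma: float = 0.2

    def __post_init__(self) -> None:
        _check(0.0 <= self.ve <= 1.0, f"ve must be in [0, 1], got {self.ve}")
        _check(0.0 < self.coverage < 1.0,
               f"coverage must be in (0, 1), got {self.coverage}")
        _check(self.theta0 > 0.0, f"theta0 must be > 0, got {self.theta0}")
        _check(0.0 < self.alpha < 0.5,
               f"alpha must be in (0, 0.5), got {self.alpha}")
        _check(0.0 < self.gamma < 1.0,
               f"gamma must be in (0, 1), got {self.gamma}")
        hazard_fields = (self.lambda_i, self.lambda_n, self.tau)
        if self.pi is not None:
            _check(all(f is None for f in hazard_fields),
                   "pi and (lambda_i, lambda_n, tau) are mutually exclusive; "
                   "supply exactly one path")
            _check(0.0 < self.pi < 1.0, f"pi must be in (0, 1), got {self.pi}")
        else:
            _check(all(f is not None for f in hazard_fields),
                   "supply either pi or all of (lambda_i, lambda_n, tau)")
            _check(self.lambda_i >= 0.0, "lambda_i must be >= 0")
            _check(self.lambda_n >= 0.0, "lambda_n must be >= 0")
            _check(self.tau > 0.0, "tau must be > 0")
            _check(self.lambda_i > 0.0 or self.lambda_n > 0.0,
                   "lambda_i and lambda_n cannot both be zero")

    @classmethod
    def from_cumulative_hazards(cls, ve: float, coverage: float,
                                cum_hazard_pos: float, cum_hazard_neg: float,
                                **kwargs) -> "DesignParams":
        """Build a scenario from cumulative hazards ``Lambda_I(tau)``,
        ``Lambda_N(tau)`` directly (a unit study period is used internally;
        all derived quantities depend on the hazards only through their
        cumulative values)."""
        return cls(ve=ve, coverage=coverage, lambda_i=cum_hazard_pos,
                   lambda_n=cum_hazard_neg, tau=1.0, **kwargs)

    @property
    def has_hazards(self) -> bool:
        return self.lambda_i is not None

    @property
    def cum_hazard_pos(self) -> float:
        """Cumulative hazard of test-positive illness, ``Lambda_I(tau)``."""
        _check(self.has_hazards, "scenario has no hazard path")
        return self.lambda_i * self.tau

    @property
    def cum_hazard_neg(self) -> float:
        """Cumulative hazard of test-negative illness, ``Lambda_N(tau)``."""
        _check(self.has_hazards, "scenario has no hazard path")
        return self.lambda_n * self.tau


def derive_p_i(p_n: float, ve: float) -> float:
    """Expected fraction vaccinated among test-positives.

    ``p_I = p_N (1 - VE) / (1 - p_N VE)``. The implied odds ratio
    ``[p_I/(1-p_I)] / [p_N/(1-p_N)]`` equals ``1 - VE`` exactly.
    """
    _check(0.0 < p_n < 1.0, f"p_n must be in (0, 1), got {p_n}")
    _check(0.0 <= ve <= 1.0, f"ve must be in [0, 1], got {ve}")
    return p_n * (1.0 - ve) / (1.0 - p_n * ve)


def derive_pi(p_n: float, ve: float, cum_hazard_pos: float,
              cum_hazard_neg: float) -> float:
    """Expected percent positivity among all tests.

    ``pi = (1 - p_N VE)(1 - e^{-Lambda_I}) /
    [(1 - p_N VE)(1 - e^{-Lambda_I}) + Lambda_N]``: the numerator is the
    per-capita expected number of positive tests (at most one per person),
    the added ``Lambda_N`` the per-capita expected number of negative tests
    (a recurrent event).
    """
    _check(0.0 < p_n < 1.0, f"p_n must be in (0, 1), got {p_n}")
    _check(0.0 <= ve <= 1.0, f"ve must be in [0, 1], got {ve}")
    _check(cum_hazard_pos >= 0.0 and cum_hazard_neg >= 0.0,
           "cumulative hazards must be non-negative")
    _check(cum_hazard_pos > 0.0 or cum_hazard_neg > 0.0,
           "cumulative hazards cannot both be zero")
    pos = (1.0 - p_n * ve) * (-math.expm1(-cum_hazard_pos))
    return pos / (pos + cum_hazard_neg)


def unit_cell_counts(params: DesignParams) -> tuple[float, float, float, float]:
    """Expected 2x2 cell counts per member of the source population.

    Returns ``(u_a, u_b, u_c, u_d)`` for vaccinated/unvaccinated (rows) by
    test-positive/test-negative (columns) under the all-or-none vaccine
    model with constant hazards:

    * ``u_a = p_N (1 - VE)(1 - e^{-Lambda_I})``
    * ``u_b = p_N Lambda_N``
    * ``u_c = (1 - p_N)(1 - e^{-Lambda_I})``
    * ``u_d = (1 - p_N) Lambda_N``
    """
    _check(params.has_hazards,
           "unit cell counts require the hazard parameterization")
    p_n, ve = params.coverage, params.ve
    cum_pos, cum_neg = params.cum_hazard_pos, params.cum_hazard_neg
    attack = -math.expm1(-cum_pos)  # cumulative incidence if unprotected
    return (p_n * (1.0 - ve) * attack,
            p_n * cum_neg,
            (1.0 - p_n) * attack,
            (1.0 - p_n) * cum_neg)


def source_population_size(n: int,
                           units: tuple[float, float, float, float]) -> int:
    """Source-population size yielding ``n`` expected tests over the study.

    ``N = ceil(n / (u_a + u_b + u_c + u_d))``, so that the preset number of
    tests accrues in roughly one study period.
    """
    _check(n >= 1, f"n must be >= 1, got {n}")
    total = float(sum(units))
    _check(total > 0.0, "unit cell counts sum to zero")
    return math.ceil(n / total)


def variance_components(p_i: float, p_n: float, pi: float) -> tuple[float, float]:
    """Null and alternative variance components of ``p_I_hat - p_N_hat``.

    Derived from the likelihood of a simple logistic regression with binary
    vaccination status; the null variance pools the two test-result groups.

    Returns ``(sigma0_sq, sigma1_sq)`` where::

        sigma0^2 = [pi p_I + (1-pi) p_N][pi (1-p_I) + (1-pi)(1-p_N)]
                   / (pi (1-pi))
        sigma1^2 = p_I p_N (1-p_I)(1-p_N)
                   / {pi (1-pi) [pi p_I (1-p_I) + (1-pi) p_N (1-p_N)]}
    """
    _check(0.0 < pi < 1.0, f"pi must be in (0, 1), got {pi}")
    _check(0.0 <= p_i <= 1.0 and 0.0 <= p_n <= 1.0,
           "p_i and p_n must be in [0, 1]")
    pooled = pi * p_i + (1.0 - pi) * p_n
    sigma0_sq = pooled * (1.0 - pooled) / (pi * (1.0 - pi))
    denom = pi * p_i * (1.0 - p_i) + (1.0 - pi) * p_n * (1.0 - p_n)
    _check(denom > 0.0,
           "alternative variance undefined: both proportions degenerate")
    sigma1_sq = (p_i * p_n * (1.0 - p_i) * (1.0 - p_n)
                 / (pi * (1.0 - pi) * denom))
    return sigma0_sq, sigma1_sq


def multinomial_variance(p_i: float, p_n: float, pi_hat: float) -> float:
    """Alternative variance of ``p_I_hat - p_N_hat`` at a realized positivity.

    In a TND the positives:negatives split is random, so the cell counts are
    multinomial rather than two independent binomials. Conditional on the
    realized positivity ``pi_hat`` the alternative variance is::

        sigma1_tilde^2(pi_hat) = p_I(1-p_I)/pi_hat + p_N(1-p_N)/(1-pi_hat)
                                 + 2 p_I p_N

    Raises
    ------
    UndefinedVarianceError
        If ``pi_hat`` is 0 or 1 (a degenerate table with an empty column).
    """
    if not 0.0 < pi_hat < 1.0:
        raise UndefinedVarianceError(
            f"variance diverges at pi_hat={pi_hat}")
    return (p_i * (1.0 - p_i) / pi_hat
            + p_n * (1.0 - p_n) / (1.0 - pi_hat)
            + 2.0 * p_i * p_n)


@dataclass(frozen=True)
class DerivedDesign:
    """All closed-form quantities computed from one scenario."""

    params: DesignParams
    p_i: float
    p_n: float
    pi: float
    sigma0_sq: float
    sigma1_sq: float
    units: tuple[float, float, float, float] | None  # None for the pi path


def derive(params: DesignParams) -> DerivedDesign:
    """Compute every derived design quantity for a scenario.

    ``pi`` comes from the hazard formula unless the scenario supplies it
    directly; unit cell counts are only available on the hazard path.
    """
    p_n = params.coverage
    p_i = derive_p_i(p_n, params.ve)
    if params.pi is not None:
        pi = params.pi
        units = None
    else:
        pi = derive_pi(p_n, params.ve, params.cum_hazard_pos,
                       params.cum_hazard_neg)
        units = unit_cell_counts(params)
    sigma0_sq, sigma1_sq = variance_components(p_i, p_n, pi)
    return DerivedDesign(params=params, p_i=p_i, p_n=p_n, pi=pi,
                         sigma0_sq=sigma0_sq, sigma1_sq=sigma1_sq,
                         units=units)
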