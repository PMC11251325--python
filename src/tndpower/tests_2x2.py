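"""One-sided hypothesis tests on a 2x2 vaccination-by-test-result table.

Tests of ``H0: OR >= theta0`` against ``H1: OR < theta0`` (equivalently
``VE > 1 - theta0``), rejecting in the lower tail of a standard normal:

* Wald test on the log odds ratio (intractable when any cell is zero);
* continuity-corrected Wald test, adding a constant ``delta`` (Yates'
  correction is ``delta = 0.5``) to every cell;
* score test from the simple logistic likelihood with the vaccination
  coefficient fixed at ``ln(theta0)``, which pools groups under the null
  and stays tractable with single zero cells as long as all margins are
  positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import norm

from .design_core import InvalidParameterError, NumericFailureError

__all__ = [
    "IntractableError",
    "Table2x2",
    "TestResult",
    "log_odds_ratio",
    "wald_test",
    "wald_cc_test",
    "score_test",
]


class IntractableError(ArithmeticError):
    """The requested statistic is undefined for this table (zero cell or
    zero margin), as opposed to a floating-point NaN."""


@dataclass(frozen=True)
class Table2x2:
    """Observed counts: rows vaccinated/unvaccinated, columns test-positive
    /test-negative.

    ``a`` vaccinated positives, ``b`` vaccinated negatives, ``c``
    unvaccinated positives, ``d`` unvaccinated negatives.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool):
                # numpy integer scalars are accepted and normalized
                try:
                    iv = int(v)
                except (TypeError, ValueError):
                    raise InvalidParameterError(
                        f"cell {name} must be an integer, got {v!r}")
                if iv != v:
                    raise InvalidParameterError(
                        f"cell {name} must be an integer, got {v!r}")
                object.__setattr__(self, name, iv)
            if getattr(self, name) < 0:
                raise InvalidParameterError(
                    f"cell {name} must be non-negative, got {v}")
        if self.n < 1:
            raise InvalidParameterError("table must contain at least one count")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def n_positive(self) -> int:
        return self.a + self.c

    @property
    def n_negative(self) -> int:
        return self.b + self.d

    @property
    def n_vaccinated(self) -> int:
        return self.a + self.b

    @property
    def n_unvaccinated(self) -> int:
        return self.c + self.d

    @property
    def has_zero_cell(self) -> bool:
        return min(self.a, self.b, self.c, self.d) == 0

    @property
    def has_zero_margin(self) -> bool:
        return min(self.n_positive, self.n_negative,
                   self.n_vaccinated, self.n_unvaccinated) == 0


@dataclass(frozen=True)
class TestResult:
    """Outcome of a one-sided test on a :class:`Table2x2`.

    ``reject`` is True only if ``tractable`` and the statistic falls below
    the lower-tail critical value ``z_alpha`` (the alpha-quantile of the
    standard normal, negative for alpha < 0.5). ``p_value`` is the
    lower-tail normal probability, reported for convenience; the decision
    rule uses the statistic directly.
    """

    method: str
    statistic: float
    tractable: bool
    reject: bool
    p_value: float
    theta0: float
    alpha: float


def log_odds_ratio(table: Table2x2, delta: float = 0.0) -> float:
    """Log odds ratio ``ln[(a+d')(d+d') / ((b+d')(c+d'))]`` with an optional
    continuity correction ``delta`` added to every cell.

    Raises :class:`IntractableError` for ``delta = 0`` with any zero cell.
    """
    if delta < 0.0:
        raise InvalidParameterError(f"delta must be >= 0, got {delta}")
    if delta == 0.0 and table.has_zero_cell:
        raise IntractableError("zero cell with no continuity correction")
    a, b, c, d = (table.a + delta, table.b + delta,
                  table.c + delta, table.d + delta)
    return math.log(a * d / (b * c))


def _decide(method: str, statistic: float, theta0: float,
            alpha: float) -> TestResult:
    z_crit = norm.ppf(alpha)
    return TestResult(method=method, statistic=statistic, tractable=True,
                      reject=bool(statistic < z_crit),
                      p_value=float(norm.cdf(statistic)),
                      theta0=theta0, alpha=alpha)


def _intractable(method: str, theta0: float, alpha: float) -> TestResult:
    return TestResult(method=method, statistic=math.nan, tractable=False,
                      reject=False, p_value=math.nan,
                      theta0=theta0, alpha=alpha)


def wald_test(table: Table2x2, theta0: float = 1.0,
              alpha: float = 0.025) -> TestResult:
    """Standard Wald test of the log odds ratio, delta-method variance
    ``1/a + 1/b + 1/c + 1/d``.

    A zero cell makes the statistic intractable; this is a defined outcome
    (``tractable=False``, ``reject=False``), not an exception.
    """
    if table.has_zero_cell:
        return _intractable("wald", theta0, alpha)
    se = math.sqrt(1.0 / table.a + 1.0 / table.b
                   + 1.0 / table.c + 1.0 / table.d)
    stat = (log_odds_ratio(table) - math.log(theta0)) / se
    return _decide("wald", stat, theta0, alpha)


def wald_cc_test(table: Table2x2, theta0: float = 1.0, alpha: float = 0.025,
                 delta: float = 0.5) -> TestResult:
    """Continuity-corrected Wald test; always tractable for ``delta > 0``."""
    if delta <= 0.0:
        raise InvalidParameterError(f"delta must be > 0, got {delta}")
    a, b, c, d = (table.a + delta, table.b + delta,
                  table.c + delta, table.d + delta)
    se = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    stat = (log_odds_ratio(table, delta) - math.log(theta0)) / se
    return _decide("wald_cc", stat, theta0, alpha)


def _score_statistic_null_or1(table: Table2x2) -> float:
    # closed form at theta0 = 1: pooled-null variance of p_I_hat - p_N_hat
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.n
    return ((a * d - b * c) * math.sqrt(n)
            / math.sqrt(table.n_positive * table.n_negative
                        * table.n_vaccinated * table.n_unvaccinated))


def _score_statistic_general(table: Table2x2, theta0: float) -> float:
    # Score test for the vaccination coefficient fixed at ln(theta0) in a
    # simple logistic model for P(vaccinated | test result); the intercept
    # is profiled out at its constrained maximum (1-D root finding), and the
    # variance comes from the information matrix at that optimum.
    m_pos, m_neg = table.n_positive, table.n_negative
    s = table.n_vaccinated  # total vaccinated
    log_t0 = math.log(theta0)

    def constraint(beta0: float) -> float:
        return m_pos * expit(beta0 + log_t0) + m_neg * expit(beta0) - s

    try:
        beta0 = brentq(constraint, -500.0, 500.0, xtol=1e-10, maxiter=200)
    except (ValueError, RuntimeError) as exc:  # pragma: no cover - guard
        raise NumericFailureError(
            f"constrained intercept did not converge for table "
            f"({table.a},{table.b},{table.c},{table.d}), theta0={theta0}: "
            f"{exc}") from exc
    p_pos = expit(beta0 + log_t0)
    p_neg = expit(beta0)
    score = table.a - m_pos * p_pos
    w_pos = m_pos * p_pos * (1.0 - p_pos)
    w_neg = m_neg * p_neg * (1.0 - p_neg)
    var = w_pos * w_neg / (w_pos + w_neg)
    return score / math.sqrt(var)


def score_test(table: Table2x2, theta0: float = 1.0,
               alpha: float = 0.025) -> TestResult:
    """Score test of ``H0: OR >= theta0`` with variance estimated under the
    null.

    At ``theta0 = 1`` the statistic reduces to the closed form
    ``(ad - bc) sqrt(n) / sqrt((a+c)(b+d)(a+b)(c+d))``, i.e.
    ``(p_I_hat - p_N_hat) / (sigma0_hat / sqrt(n))``; tables with a single
    zero cell remain tractable as long as every margin is positive. For
    general ``theta0`` the statistic is computed from the constrained
    logistic likelihood (see :func:`_score_statistic_general`); the two
    paths coincide at ``theta0 = 1``.
    """
    if table.has_zero_margin:
        return _intractable("score", theta0, alpha)
    if theta0 == 1.0:
        stat = _score_statistic_null_or1(table)
    else:
        stat = _score_statistic_general(table, theta0)
    return _decide("score", stat, theta0, alpha)
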