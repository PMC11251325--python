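"""Sample-size calculators for TND and case-control vaccine studies.

Four calculators, each returning the required total number of tests ``n``:

* ``wald_sample_size`` — the standard (Breslow-style) Wald size expressed
  in TND parameters;
* ``wald_cc_sample_size`` — the Fleiss correction of the Wald size
  matching the Yates continuity-corrected test;
* ``score_sample_size`` — the case-control score size built from the
  null/alternative variance components of ``p_I_hat - p_N_hat``;
* ``tnd_score_sample_size`` — the TND-adjusted score size: the smallest
  ``n`` whose unconditional power, averaged over the binomial distribution
  of the realized positivity ``pi_hat = (a+c)/n``, reaches the target.
  This accounts for the extra variability of the positives:negatives ratio
  in the TND, where that ratio is random rather than fixed by design.

Fractional sizes are rounded up; the continuity-corrected size is built
from the unrounded Wald size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import binom, norm

from .design_core import DerivedDesign, InvalidParameterError

__all__ = [
    "SampleSizeResult",
    "wald_sample_size",
    "wald_cc_sample_size",
    "score_sample_size",
    "weighted_power",
    "tnd_score_sample_size",
]


@dataclass(frozen=True)
class SampleSizeResult:
    """A computed sample size.

    ``achieved_power`` is populated for the TND-adjusted score size (the
    binomial-weighted power at the returned ``n``); for the closed-form
    calculators it is None.
    """

    method: str
    n: int
    derived: DerivedDesign
    achieved_power: float | None = None


def _resolve(derived: DerivedDesign, alpha: float | None,
             gamma: float | None) -> tuple[float, float]:
    alpha = derived.params.alpha if alpha is None else alpha
    gamma = derived.params.gamma if gamma is None else gamma
    return alpha, gamma


def _check_effect(derived: DerivedDesign) -> None:
    if derived.p_i == derived.p_n:
        raise InvalidParameterError(
            "p_i equals p_n (zero effect); sample size is undefined")


def _wald_size_exact(derived: DerivedDesign, alpha: float,
                     gamma: float) -> float:
    _check_effect(derived)
    p_i, p_n, pi = derived.p_i, derived.p_n, derived.pi
    z_a = norm.ppf(1.0 - alpha)
    z_g = norm.ppf(1.0 - gamma)
    pooled = pi * p_i + (1.0 - pi) * p_n
    term_null = z_a * math.sqrt(pooled * (1.0 - pooled))
    term_alt = z_g * math.sqrt((1.0 - pi) * p_i * (1.0 - p_i)
                               + pi * p_n * (1.0 - p_n))
    return ((term_null + term_alt) ** 2
            / (pi * (1.0 - pi) * (p_i - p_n) ** 2))


def wald_sample_size(derived: DerivedDesign, alpha: float | None = None,
                     gamma: float | None = None) -> SampleSizeResult:
    """Standard Wald total number of tests, rounded up."""
    alpha, gamma = _resolve(derived, alpha, gamma)
    n = math.ceil(_wald_size_exact(derived, alpha, gamma))
    return SampleSizeResult(method="wald", n=n, derived=derived)


def wald_cc_sample_size(derived: DerivedDesign, alpha: float | None = None,
                        gamma: float | None = None) -> SampleSizeResult:
    """Fleiss continuity-corrected size, built from the unrounded Wald size.

    ``n_C = (n_W/4) {1 + sqrt(1 + 2 / (pi(1-pi) n_W |p_I - p_N|))}^2``;
    always at least as large as the Wald size.
    """
    alpha, gamma = _resolve(derived, alpha, gamma)
    n_w = _wald_size_exact(derived, alpha, gamma)
    pi = derived.pi
    factor = (1.0 + math.sqrt(
        1.0 + 2.0 / (pi * (1.0 - pi) * n_w * abs(derived.p_i - derived.p_n)))
    ) ** 2
    return SampleSizeResult(method="wald_cc", n=math.ceil(n_w / 4.0 * factor),
                            derived=derived)


def _score_size_exact(derived: DerivedDesign, alpha: float,
                      gamma: float) -> float:
    _check_effect(derived)
    z_a = norm.ppf(1.0 - alpha)
    z_g = norm.ppf(1.0 - gamma)
    sigma0 = math.sqrt(derived.sigma0_sq)
    sigma1 = math.sqrt(derived.sigma1_sq)
    return ((z_g * sigma1 + z_a * sigma0) ** 2
            / (derived.p_i - derived.p_n) ** 2)


def score_sample_size(derived: DerivedDesign, alpha: float | None = None,
                      gamma: float | None = None) -> SampleSizeResult:
    """Case-control score total number of tests, rounded up."""
    alpha, gamma = _resolve(derived, alpha, gamma)
    n = math.ceil(_score_size_exact(derived, alpha, gamma))
    return SampleSizeResult(method="score", n=n, derived=derived)


def _binomial_weights(n: int, pi: float) -> np.ndarray:
    """Binomial(n, pi) pmf over k = 0..n (the distribution of the number of
    positive tests among n total tests)."""
    return binom.pmf(np.arange(n + 1), n, pi)


def weighted_power(n: int, derived: DerivedDesign,
                   alpha: float | None = None) -> float:
    """Unconditional power of the score test at total size ``n`` in a TND.

    Sums the conditional rejection probability over the binomial
    distribution of the number of positive tests::

        sum_k Phi( (z_alpha sigma0 - (p_I - p_N) sqrt(n))
                   / sigma1_tilde(k/n) ) C(n,k) pi^k (1-pi)^(n-k)

    ``sigma0`` is held at the design ``pi`` (the null variance is roughly
    constant across realized positivities) while the multinomial
    alternative deviation ``sigma1_tilde`` varies with ``pi_hat = k/n``.
    The degenerate ``k = 0`` and ``k = n`` tables cannot reject and
    contribute rejection probability zero.
    """
    if n < 1:
        raise InvalidParameterError(f"n must be >= 1, got {n}")
    alpha, _ = _resolve(derived, alpha, None)
    p_i, p_n, pi = derived.p_i, derived.p_n, derived.pi
    z_a = norm.ppf(alpha)
    sigma0 = math.sqrt(derived.sigma0_sq)
    weights = _binomial_weights(n, pi)
    if n < 2:
        return 0.0
    k = np.arange(1, n)
    pi_hat = k / n
    sigma1_tilde = np.sqrt(p_i * (1.0 - p_i) / pi_hat
                           + p_n * (1.0 - p_n) / (1.0 - pi_hat)
                           + 2.0 * p_i * p_n)
    args = (z_a * sigma0 - (p_i - p_n) * math.sqrt(n)) / sigma1_tilde
    return float(np.sum(norm.cdf(args) * weights[1:-1]))


def tnd_score_sample_size(derived: DerivedDesign, alpha: float | None = None,
                          gamma: float | None = None,
                          n_max: int | None = None) -> SampleSizeResult:
    """TND-adjusted score size: grid search upward from the case-control
    score size until the binomial-weighted power reaches ``1 - gamma``.

    Raises :class:`InvalidParameterError` if the target power is not
    reached by ``n_max`` (default ten times the case-control score size);
    the exception carries the evaluated power profile.
    """
    alpha, gamma = _resolve(derived, alpha, gamma)
    start = math.ceil(_score_size_exact(derived, alpha, gamma))
    if n_max is None:
        n_max = 10 * start
    target = 1.0 - gamma
    profile: list[tuple[int, float]] = []
    for n in range(start, n_max + 1):
        power = weighted_power(n, derived, alpha)
        profile.append((n, power))
        if power >= target:
            return SampleSizeResult(method="tnd_score", n=n, derived=derived,
                                    achieved_power=power)
    err = InvalidParameterError(
        f"target power {target} not reached by n_max={n_max}")
    err.power_profile = profile  # type: ignore[attr-defined]
    raise err
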