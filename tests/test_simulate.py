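import math

import numpy as np
import pytest
from scipy.stats import poisson

from tndpower import (
    InsufficientEventsError,
    InvalidParameterError,
    build_cohort,
    derive,
    generate_test_events,
    sample_case_control,
    sample_tnd,
    simulate_study,
    source_population_size,
    unit_cell_counts,
)

from conftest import scenario


def rng_for(seed):
    return np.random.default_rng(seed)


class TestCohort:
    def test_exact_counts_with_half_up_rounding(self):
        cohort = build_cohort(100, 0.3, 0.95, rng_for(0))
        assert cohort.vaccinated.sum() == 30
        assert cohort.protected.sum() == 29  # round(28.5) half-up
        assert np.all(cohort.vaccinated[cohort.protected])

    def test_zero_effectiveness_protects_nobody(self):
        assert build_cohort(100, 0.3, 0.0, rng_for(0)).protected.sum() == 0

    def test_same_seed_reproduces_assignment(self):
        a = build_cohort(500, 0.4, 0.8, rng_for(42))
        b = build_cohort(500, 0.4, 0.8, rng_for(42))
        assert np.array_equal(a.vaccinated, b.vaccinated)
        assert np.array_equal(a.protected, b.protected)

    def test_degenerate_population_rejected(self):
        with pytest.raises(InvalidParameterError):
            build_cohort(1, 0.5, 0.5, rng_for(0))
        with pytest.raises(InvalidParameterError):
            build_cohort(100, 0.001, 0.5, rng_for(0))  # zero vaccinated


class TestEventGeneration:
    def test_protected_never_test_positive(self):
        cohort = build_cohort(5000, 0.5, 0.9, rng_for(1))
        log = generate_test_events(cohort, 0.01, 0.002, 100.0, rng_for(2))
        positives = log.individual[log.positive]
        assert not cohort.protected[positives].any()
        assert log.time.min() > 0.0 and log.time.max() <= 100.0

    def test_positive_attack_rate_matches_exponential_survival(self):
        n = 100_000
        cohort = build_cohort(n, 0.3, 0.0, rng_for(3))
        log = generate_test_events(cohort, 0.001, 0.002, 100.0, rng_for(4))
        hit = np.zeros(n, dtype=bool)
        hit[log.individual[log.positive]] = True
        expected = 1 - math.exp(-0.1)
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(hit.mean() - expected) < 3 * se

    def test_negative_test_count_matches_truncated_poisson(self):
        n = 100_000
        cohort = build_cohort(n, 0.3, 0.95, rng_for(5))
        log = generate_test_events(cohort, 0.0, 0.002, 100.0, rng_for(6))
        per_person = np.bincount(log.individual, minlength=n)
        assert per_person.max() <= 3
        # E[min(K, 3)] for K ~ Poisson(0.2): the cumulative hazard minus the
        # (tiny) mass disregarded above three tests
        k = np.arange(0, 50)
        expected = float(np.sum(np.minimum(k, 3) * poisson.pmf(k, 0.2)))
        se = math.sqrt(0.2 / n)
        assert abs(per_person.mean() - expected) < 3 * se
        assert expected == pytest.approx(0.2, abs=2e-4)  # truncation loss <1%

    def test_positive_events_unique_per_individual(self):
        cohort = build_cohort(10_000, 0.3, 0.0, rng_for(7))
        log = generate_test_events(cohort, 0.02, 0.0, 100.0, rng_for(8))
        positives = log.individual[log.positive]
        assert len(positives) == len(np.unique(positives))


class TestTndSampling:
    def test_takes_exactly_n_in_time_order(self, ve95_cov30):
        units = unit_cell_counts(ve95_cov30)
        n_pop = source_population_size(74, units)
        cohort = build_cohort(n_pop, 0.3, 0.95, rng_for(9))
        log = generate_test_events(cohort, 0.001, 0.002, 100.0, rng_for(10))
        study = sample_tnd(log, 30, rng_for(11))
        assert study.table.n == 30
        assert not study.truncated
        assert study.realized_duration <= 100.0

    def test_truncates_when_events_run_out(self, ve95_cov30):
        cohort = build_cohort(50, 0.3, 0.95, rng_for(12))
        log = generate_test_events(cohort, 0.001, 0.002, 100.0, rng_for(13))
        study = sample_tnd(log, 10_000, rng_for(14))
        assert study.truncated
        assert study.table.n == len(log)

    def test_mean_realized_positivity_matches_formula(self, ve95_cov30):
        reps = 2000
        streams = np.random.SeedSequence(15).spawn(reps)
        pis = np.array([
            simulate_study(ve95_cov30, 74, "tnd",
                           np.random.default_rng(s)).realized_pi
            for s in streams])
        target = derive(ve95_cov30).pi
        mc_se = pis.std(ddof=1) / math.sqrt(reps)
        assert abs(pis.mean() - target) < 3 * mc_se
        assert pis.var() > 0  # the positives:negatives split is random


class TestCaseControlSampling:
    def test_fixed_column_margin(self, ve95_cov30):
        pi = derive(ve95_cov30).pi
        counts = set()
        for seed in range(20):
            study = simulate_study(ve95_cov30, 74, "case_control",
                                   rng_for(seed))
            counts.add(study.table.n_positive)
            assert study.table.n == 74
        assert counts == {round(74 * pi)}  # zero variance across replicates

    def test_insufficient_events_signalled(self):
        cohort = build_cohort(30, 0.3, 0.95, rng_for(16))
        log = generate_test_events(cohort, 0.001, 0.002, 100.0, rng_for(17))
        with pytest.raises(InsufficientEventsError):
            sample_case_control(log, 1000, 0.25, rng_for(18))


class TestSimulateStudy:
    def test_identical_seed_identical_study(self, ve95_cov30):
        a = simulate_study(ve95_cov30, 74, "tnd", rng_for(19))
        b = simulate_study(ve95_cov30, 74, "tnd", rng_for(19))
        assert a == b

    def test_expected_cell_counts_match_units(self, ve95_cov30):
        # tabulate full event logs (no stopping rule): per-capita means must
        # match the closed-form unit cell counts
        units = np.array(unit_cell_counts(ve95_cov30))
        n_pop = source_population_size(74, unit_cell_counts(ve95_cov30))
        reps = 2000
        cells = np.zeros((reps, 4))
        for r, s in enumerate(np.random.SeedSequence(20).spawn(reps)):
            rng = np.random.default_rng(s)
            cohort = build_cohort(n_pop, 0.3, 0.95, rng)
            log = generate_test_events(cohort, 0.001, 0.002, 100.0, rng)
            pos, vac = log.positive, log.vaccinated
            cells[r] = [np.sum(pos & vac), np.sum(~pos & vac),
                        np.sum(pos & ~vac), np.sum(~pos & ~vac)]
        means = cells.mean(axis=0) / n_pop
        ses = cells.std(axis=0, ddof=1) / math.sqrt(reps) / n_pop
        # the recurrent negative process is truncated at three tests per
        # person, deflating u_b and u_d by well under 1%
        assert np.all(np.abs(means - units) < 3 * ses + 0.01 * units)

    def test_tnd_margin_more_dispersed_than_case_control(self, ve95_cov30):
        streams = np.random.SeedSequence(21).spawn(1000)
        tnd = [simulate_study(ve95_cov30, 63, "tnd",
                              np.random.default_rng(s)).table.n_positive
               for s in streams]
        cc = [simulate_study(ve95_cov30, 63, "case_control",
                             np.random.default_rng(s)).table.n_positive
              for s in streams]
        assert np.var(tnd) > np.var(cc)

    def test_unknown_design_rejected(self, ve95_cov30):
        with pytest.raises(InvalidParameterError):
            simulate_study(ve95_cov30, 74, "cohort", rng_for(22))
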