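"""Sampling distributions, stream independence and determinism."""

import math

import numpy as np
import pytest

from audsim import (
    BinaryOutcomeParams,
    ConfigError,
    CountOutcomeParams,
    expected_total,
    run_simulation,
    sample_binary_total,
    sample_count_total,
    simulate_scenario_outcome,
    substream,
)
from audsim.parameters import ScenarioAllocation


def per_patient_sum_oracle(n_patients, params, replicates, rng):
    """Brute-force group total: sum n_patients individual NB draws."""
    p = params.dispersion / (params.dispersion + params.mean_per_patient)
    draws = rng.negative_binomial(params.dispersion, p, size=(replicates, n_patients))
    return draws.sum(axis=1)


def group_total_moments(n, params):
    mean = n * params.mean_per_patient
    var = n * params.variance
    return mean, var


class TestCountSampling:
    def test_swt_baseline_mean_matches_expectation(self, params):
        swt = params["hospitalisation_count"].swt
        x = sample_count_total(1881, swt, 10_000, substream(1, "t"))
        mean, var = group_total_moments(1881, swt)
        assert mean == pytest.approx(1881 * 7.3)
        se = math.sqrt(var / 10_000)
        assert abs(x.mean() - mean) < 3 * se

    def test_qwt_baseline_mean_and_variance(self, params):
        qwt = params["hospitalisation_count"].qwt
        x = sample_count_total(170, qwt, 10_000, substream(2, "t"))
        mean, var = group_total_moments(170, qwt)
        assert mean == pytest.approx(595.0)
        assert abs(x.mean() - mean) < 3 * math.sqrt(var / 10_000)
        # variance of the sample variance of an NB total, via 4th central moment
        assert x.var(ddof=1) == pytest.approx(var, rel=0.15)

    @pytest.mark.parametrize(
        "n,mean,sd",
        [
            (50, 3.5, 4.4),
            (50, 7.3, 11.3),
            (50, 55.7, 75.4),
            (50, 135.8, 167.3),
            (25, 2.0, 3.0),
        ],
    )
    def test_aggregate_matches_per_patient_oracle(self, n, mean, sd):
        """A single NB(n*mu, n*k) draw equals the sum of n iid NB(mu, k) draws
        in distribution; checked on mean and variance at 2000 replicates."""
        p = CountOutcomeParams.from_moments(mean, sd)
        reps = 2000
        agg = sample_count_total(n, p, reps, substream(3, f"agg{n}{mean}"))
        oracle = per_patient_sum_oracle(n, p, reps, substream(4, f"orc{n}{mean}"))
        mu, var = group_total_moments(n, p)
        se_mean = math.sqrt(var / reps)
        assert abs(agg.mean() - mu) < 3 * se_mean
        assert abs(oracle.mean() - mu) < 3 * se_mean
        # SE of the sample variance ~ sqrt((m4 - var^2)/reps); use a generous
        # normal-theory surrogate scaled for NB heavy tails
        se_var = var * math.sqrt(2.0 / reps) * 4
        assert abs(agg.var(ddof=1) - var) < 3 * se_var
        assert abs(oracle.var(ddof=1) - var) < 3 * se_var

    def test_zero_patients_gives_zero_vector(self, params):
        x = sample_count_total(0, params["hospital_days"].qwt, 100, substream(5, "z"))
        assert (x == 0).all() and len(x) == 100

    def test_counts_are_nonnegative_integers(self, params):
        x = sample_count_total(17, params["hospital_days"].swt, 5000, substream(6, "i"))
        assert x.dtype == np.int64
        assert (x >= 0).all()


class TestBinarySampling:
    def test_mean_matches_binomial_expectation(self):
        p = BinaryOutcomeParams(29, 92)
        x = sample_binary_total(92, p, 10_000, substream(7, "b"))
        se = math.sqrt(92 * p.probability * (1 - p.probability) / 10_000)
        assert abs(x.mean() - 29.0) < 3 * se

    def test_degenerate_probabilities(self):
        zero = sample_binary_total(50, BinaryOutcomeParams(0, 10), 200, substream(8, "p0"))
        one = sample_binary_total(50, BinaryOutcomeParams(10, 10), 200, substream(9, "p1"))
        assert (zero == 0).all()
        assert (one == 50).all()

    def test_totals_bounded_by_group_size(self):
        x = sample_binary_total(37, BinaryOutcomeParams(13, 90), 5000, substream(10, "bd"))
        assert ((x >= 0) & (x <= 37)).all()


class TestScenarioOutcome:
    def test_baseline_abstinence_expectation(self, params, baseline):
        spec = params["abstinence"]
        ts = simulate_scenario_outcome(baseline, spec.qwt, spec.swt, 10_000, 11, "abstinence")
        expected = 170 * 29 / 92 + 1881 * 13 / 90
        assert expected == pytest.approx(325.3, abs=0.05)
        var = 170 * (29 / 92) * (1 - 29 / 92) + 1881 * (13 / 90) * (1 - 13 / 90)
        assert abs(ts.values.mean() - expected) < 3 * math.sqrt(var / 10_000)

    def test_fifty_percent_hospitalisation_expectation(self, params, scenarios):
        spec = params["hospitalisation_count"]
        alloc = next(s for s in scenarios if s.label == "qwt50")
        ts = simulate_scenario_outcome(alloc, spec.qwt, spec.swt, 10_000, 12, "hosp")
        expected = 1026 * 3.5 + 1025 * 7.3
        assert expected == pytest.approx(11_073.5)
        var = 1026 * spec.qwt.variance + 1025 * spec.swt.variance
        assert abs(ts.values.mean() - expected) < 3 * math.sqrt(var / 10_000)

    def test_all_qwt_with_zero_probability_gives_zeros(self):
        alloc = ScenarioAllocation("all", 40, 40, 0)
        p = BinaryOutcomeParams(0, 10)
        ts = simulate_scenario_outcome(alloc, p, p, 500, 13, "x")
        assert (ts.values == 0).all()

    def test_mismatched_arm_types_rejected(self, params):
        alloc = ScenarioAllocation("m", 10, 5, 5)
        with pytest.raises(ConfigError):
            simulate_scenario_outcome(
                alloc, params["abstinence"].qwt, params["hospital_days"].swt, 10, 14
            )


class TestRunSimulation:
    def test_full_grid_shape(self, params, scenarios):
        res = run_simulation(params, scenarios, 50, 99)
        assert len(res.samples) == 12
        assert all(ts.replicates == 50 for ts in res.samples.values())

    def test_single_replicate(self, params, scenarios):
        res = run_simulation(params, scenarios, 1, 99)
        assert all(ts.replicates == 1 for ts in res.samples.values())

    def test_seed_determinism_and_sensitivity(self, params, scenarios):
        a = run_simulation(params, scenarios, 200, 42)
        b = run_simulation(params, scenarios, 200, 42)
        c = run_simulation(params, scenarios, 200, 43)
        for key in a.samples:
            assert np.array_equal(a[key].values, b[key].values)
        assert any(
            not np.array_equal(a[key].values, c[key].values) for key in a.samples
        )

    def test_expectation_law_every_cell(self, params, scenarios):
        """Every (scenario, outcome) empirical mean sits within 3 SE of the
        closed-form expectation n_qwt*mu_qwt + n_swt*mu_swt."""
        res = run_simulation(params, scenarios, 10_000, 7)
        for alloc in scenarios:
            for spec in params.outcomes:
                ts = res[(alloc.label, spec.name)]
                expect = expected_total(alloc, spec.qwt, spec.swt)
                if spec.kind == "count":
                    var = alloc.n_qwt * spec.qwt.variance + alloc.n_swt * spec.swt.variance
                else:
                    var = alloc.n_qwt * spec.qwt.probability * (
                        1 - spec.qwt.probability
                    ) + alloc.n_swt * spec.swt.probability * (1 - spec.swt.probability)
                assert abs(ts.values.mean() - expect) < 3 * math.sqrt(var / 10_000), (
                    alloc.label,
                    spec.name,
                )

    def test_binary_totals_bounded_by_cohort(self, params, scenarios):
        res = run_simulation(params, scenarios, 1000, 3)
        for alloc in scenarios:
            for name in ("abstinence", "death"):
                v = res[(alloc.label, name)].values
                assert ((v >= 0) & (v <= alloc.total_n)).all()


class TestStreams:
    def test_distinct_keys_distinct_streams(self):
        a = substream(1, "s", "o", "QWT").random(8)
        for keys in [("s", "o", "SWT"), ("s", "x", "QWT"), ("t", "o", "QWT")]:
            assert not np.array_equal(a, substream(1, *keys).random(8))

    def test_same_keys_same_stream(self):
        assert np.array_equal(
            substream(5, "a", "b").random(8), substream(5, "a", "b").random(8)
        )
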