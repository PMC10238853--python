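"""Unit and property tests for the one-parameter empiric toxicity model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from procrmb import (
    CLINICIAN,
    PATIENT,
    CalibrationParams,
    EndpointSpec,
    QuadratureConfig,
    ToxicityCounts,
    calibrate_skeleton,
    log_likelihood,
    plugin_tox,
    posterior_mean_beta,
    posterior_mean_tox,
    working_model_prob,
)

GH = QuadratureConfig(method="gauss-hermite", nodes=100)


def trapezoid_posterior_means(spec, counts, lo=-15.0, hi=15.0, num=20001):
    """Brute-force quadrature oracle: trapezoid rule on a fixed beta grid."""
    beta = np.linspace(lo, hi, num)
    loglik = np.zeros_like(beta)
    for p, y, n in zip(spec.skeleton, counts.dlt, counts.evaluated):
        if n == 0:
            continue
        log_f = np.exp(beta) * math.log(p)  # finite even where p**exp(beta) underflows
        loglik += y * log_f + (n - y) * np.log1p(-np.exp(log_f))
    weights = np.exp(loglik) * np.exp(-(beta**2) / (2 * spec.prior_sd**2))
    z = np.trapezoid(weights, beta)
    return np.array(
        [np.trapezoid(p ** np.exp(beta) * weights, beta) / z for p in spec.skeleton]
    )


@pytest.mark.parametrize(
    "p, beta, expected",
    [
        (0.20, 0.0, 0.20),
        (0.20, math.log(2), 0.04),
        (0.55, -math.log(2), math.sqrt(0.55)),
    ],
)
def test_working_model_prob(p, beta, expected):
    assert working_model_prob(p, beta) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.7])
def test_working_model_prob_rejects_non_probabilities(bad):
    with pytest.raises(ValueError):
        working_model_prob(bad, 0.0)


class TestLogLikelihood:
    def test_no_data_contributes_zero(self, clinician_spec):
        counts = ToxicityCounts((0, 0), (0, 0))
        assert log_likelihood(clinician_spec, counts, 1.7) == 0.0

    def test_single_bernoulli(self, clinician_spec):
        counts = ToxicityCounts((1, 0), (1, 0))
        assert log_likelihood(clinician_spec, counts, 0.0) == pytest.approx(
            math.log(0.20), abs=1e-12
        )

    def test_matches_product_of_bernoullis(self):
        spec = EndpointSpec(CLINICIAN, 0.20, (0.20, 0.31), 1.0)
        counts = ToxicityCounts((0, 2), (3, 3))
        beta = 0.3
        expected = 1.0
        for p, y, n in zip(spec.skeleton, counts.dlt, counts.evaluated):
            F = p ** math.exp(beta)
            expected *= F**y * (1 - F) ** (n - y)
        assert log_likelihood(spec, counts, beta) == pytest.approx(
            math.log(expected), abs=1e-12
        )

    @pytest.mark.parametrize("beta", [-20.0, -5.0, 5.0, 20.0])
    def test_finite_at_extreme_beta(self, patient_spec, beta):
        counts = ToxicityCounts((3, 5), (10_000, 10_000))
        assert math.isfinite(log_likelihood(patient_spec, counts, beta))


class TestToxicityCountsInvariants:
    def test_rejects_dlt_exceeding_evaluated(self):
        with pytest.raises(ValueError):
            ToxicityCounts((4,), (3,))

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            ToxicityCounts((-1,), (3,))

    def test_rejects_length_mismatch(self):
        with pytest.raises(ValueError):
            ToxicityCounts((0, 0), (3,))


class TestEndpointSpecInvariants:
    def test_rejects_non_increasing_skeleton(self):
        with pytest.raises(ValueError):
            EndpointSpec(CLINICIAN, 0.2, (0.31, 0.20), 1.0)

    def test_rejects_bad_prior_sd(self):
        with pytest.raises(ValueError):
            EndpointSpec(CLINICIAN, 0.2, (0.20, 0.31), 0.0)


class TestCalibrateSkeleton:
    @pytest.mark.parametrize(
        "target, expected",
        [(0.20, (0.20, 0.31)), (0.55, (0.55, 0.64))],
    )
    def test_reproduces_published_two_level_skeletons(self, target, expected):
        got = calibrate_skeleton(target, CalibrationParams(0.05, 1), 2)
        assert tuple(round(p, 2) for p in got) == expected

    def test_zero_halfwidth_collapses_to_target(self):
        got = calibrate_skeleton(0.20, CalibrationParams(0.0, 1), 4)
        assert got == pytest.approx((0.20,) * 4)

    def test_rejects_halfwidth_at_least_target(self):
        with pytest.raises(ValueError):
            calibrate_skeleton(0.20, CalibrationParams(0.25, 1), 2)
        with pytest.raises(ValueError):
            calibrate_skeleton(0.90, CalibrationParams(0.15, 1), 2)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        target=st.floats(0.10, 0.60),
        halfwidth=st.floats(0.01, 0.09),
        nu=st.integers(1, 4),
        levels=st.integers(1, 6),
    )
    def test_strictly_increasing_and_anchored(self, target, halfwidth, nu, levels):
        nu = min(nu, levels)
        sk = calibrate_skeleton(target, CalibrationParams(halfwidth, nu), levels)
        assert sk[nu - 1] == pytest.approx(target)
        assert all(0 < p < 1 for p in sk)
        assert all(b > a for a, b in zip(sk, sk[1:]))

    def test_nested_truncation_invariance(self):
        # anchored at level 1, a longer grid extends the shorter one
        short = calibrate_skeleton(0.20, CalibrationParams(0.05, 1), 3)
        long = calibrate_skeleton(0.20, CalibrationParams(0.05, 1), 6)
        assert long[:3] == pytest.approx(short)


class TestPosteriorMean:
    def test_matches_trapezoid_oracle_on_trial_checkpoints(
        self, clinician_spec, patient_spec
    ):
        checkpoints = [
            (patient_spec, ToxicityCounts((1, 0), (3, 0))),
            (clinician_spec, ToxicityCounts((0, 0), (3, 0))),
            (clinician_spec, ToxicityCounts((0, 1), (3, 3))),
            (patient_spec, ToxicityCounts((1, 2), (3, 3))),
        ]
        for spec, counts in checkpoints:
            oracle = trapezoid_posterior_means(spec, counts)
            for quad in (QuadratureConfig(), GH):
                got = posterior_mean_tox(spec, counts, quad).mean_prob
                assert np.allclose(got, oracle, atol=1e-6)

    def test_no_data_equals_prior_mean(self, patient_spec):
        counts = ToxicityCounts((0, 0), (0, 0))
        oracle = trapezoid_posterior_means(patient_spec, counts)
        got = posterior_mean_tox(patient_spec, counts).mean_prob
        assert np.allclose(got, oracle, atol=1e-6)

    def test_degenerate_prior_pins_estimates_at_skeleton(self):
        spec = EndpointSpec(PATIENT, 0.55, (0.55, 0.64), 1e-6)
        got = posterior_mean_tox(spec, ToxicityCounts((0, 0), (0, 0))).mean_prob
        assert got == pytest.approx(spec.skeleton, abs=1e-4)

    def test_rejects_grid_mismatch(self, patient_spec):
        with pytest.raises(ValueError):
            posterior_mean_tox(patient_spec, ToxicityCounts((0,), (3,)))

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(data=st.data())
    def test_increasing_in_dose_and_monotone_in_data(self, data, patient_spec):
        """Estimates rise across doses; an extra DLT raises them, an extra
        DLT-free patient lowers them, at every dose."""
        evaluated = tuple(data.draw(st.integers(0, 9)) for _ in range(2))
        dlt = tuple(data.draw(st.integers(0, n)) for n in evaluated)
        counts = ToxicityCounts(dlt, evaluated)
        base = posterior_mean_tox(patient_spec, counts, GH).mean_prob
        assert all(0 < v < 1 for v in base)
        assert base[0] < base[1]
        j = data.draw(st.integers(0, 1))
        more_tox = ToxicityCounts(
            tuple(y + (1 if k == j else 0) for k, y in enumerate(dlt)),
            tuple(n + (1 if k == j else 0) for k, n in enumerate(evaluated)),
        )
        worse = posterior_mean_tox(patient_spec, more_tox, GH).mean_prob
        assert all(w >= b - 1e-12 for w, b in zip(worse, base))
        less_tox = ToxicityCounts(
            dlt, tuple(n + (1 if k == j else 0) for k, n in enumerate(evaluated))
        )
        better = posterior_mean_tox(patient_spec, less_tox, GH).mean_prob
        assert all(b2 <= b + 1e-12 for b2, b in zip(better, base))


class TestPluginEstimator:
    def test_common_power_structure(self, clinician_spec):
        counts = ToxicityCounts((0, 2), (6, 9))
        est = plugin_tox(clinician_spec, counts).mean_prob
        bhat = posterior_mean_beta(clinician_spec, counts)
        expected = tuple(p ** math.exp(bhat) for p in clinician_spec.skeleton)
        assert est == pytest.approx(expected, abs=1e-12)

    def test_quadrature_methods_agree(self, patient_spec):
        counts = ToxicityCounts((1, 2), (6, 6))
        gk = posterior_mean_beta(patient_spec, counts, QuadratureConfig())
        gh = posterior_mean_beta(patient_spec, counts, GH)
        assert gk == pytest.approx(gh, abs=1e-5)
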