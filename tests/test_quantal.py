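"""Quantal estimators: direct QC, failure analysis, variance-mean, trains."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nmjquant as nq
from nmjquant.detect import NoiseModel
from nmjquant.errors import (
    InsufficientDataError,
    UndefinedEstimateError,
    ValidationError,
)
from nmjquant.quantal import (
    VMFit,
    VarianceMeanSeries,
    classify_failures,
    cumulative_rrp,
    failure_qc,
    fit_parabola,
    qc_ratio,
    vm_params,
    vm_points,
)


def series(I, V, n=20, cv2=None):
    I = np.asarray(I, float)
    V = np.asarray(V, float)
    return VarianceMeanSeries(
        ca_mm=np.arange(1.0, len(I) + 1),
        mean_I_na=I,
        var_I_na2=V,
        n_events=np.full(len(I), n),
        cv2=V / I**2 if cv2 is None else np.asarray(cv2, float),
    )


class TestQCRatio:
    def test_direct_ratio(self):
        s = qc_ratio([50.0] * 10, [1.0] * 30)
        assert s.qc == pytest.approx(50.0)
        assert s.n_ejc == 10 and s.n_mejc == 30

    def test_identity_when_lists_equal(self):
        s = qc_ratio([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert s.qc == pytest.approx(1.0)

    def test_empty_inputs_rejected(self):
        with pytest.raises(InsufficientDataError):
            qc_ratio([], [1.0])

    def test_recovers_true_poisson_quantal_content(self):
        # simulator oracle: N*p = 2.0, QC estimated from 2000 stimuli
        truth = nq.calibrate_ca_half(
            nq.GroundTruth(n_rrp=400, nmj_cv=0.0), 0.25, 2.0 / 400
        )
        protos = [
            nq.Protocol(kind="failure", ca_mm=0.25, stim_freq_hz=1.0, n_stim=2000),
            nq.Protocol.spontaneous(120.0),
        ]
        ds = nq.simulate_cohort(truth, protos, 1, seed=21)
        ejc = ds.events.query("kind == 'ejc'")["amplitude_na"]
        mejc = ds.events.query("kind == 'mejc'")["amplitude_na"]
        s = qc_ratio(ejc, mejc)
        # s.e. of QC dominated by the EJC mean: sd(ejc)/mean(mejc)/sqrt(n)
        se = ejc.std() / mejc.mean() / np.sqrt(len(ejc))
        assert abs(s.qc - 2.0) < 3 * se


class TestClassifyFailures:
    def test_zero_amplitude_is_failure(self):
        nm = NoiseModel(0.0, 0.1, 0.1, 8)
        minis = np.linspace(0.5, 1.5, 40)
        cls = classify_failures([0.0], nm, minis)
        assert cls.is_failure[0]

    def test_mini_sized_response_is_release(self):
        nm = NoiseModel(0.0, 0.01, 0.01, 8)
        minis = np.linspace(0.5, 1.5, 40)
        cls = classify_failures([np.median(minis)], nm, minis)
        assert not cls.is_failure[0]

    def test_needs_mini_reference(self):
        with pytest.raises(InsufficientDataError):
            classify_failures([0.0], NoiseModel(0.0, 0.1, 0.1, 8), [1.0] * 19)

    def test_requires_noise_model(self):
        with pytest.raises(ValidationError):
            classify_failures([0.0], None, [1.0] * 30)

    def test_agrees_with_release_count_oracle(self):
        # SNR = q_mean / noise_sd = 8; classification should match the
        # simulator's hidden release counts for >= 98% of stimuli
        truth = nq.calibrate_ca_half(nq.GroundTruth(nmj_cv=0.0), 0.25, 1.8 / 300)
        protos = [nq.Protocol.failure(), nq.Protocol.spontaneous(60.0)]
        ds = nq.simulate_cohort(truth, protos, 10, seed=33)
        nm = NoiseModel(0.0, truth.noise_sd, truth.noise_sd, 8)
        agree = total = 0
        for nmj_id, g in ds.events.groupby("nmj_id"):
            amps = g.query("kind == 'ejc'").sort_values("stim_index")["amplitude_na"]
            minis = g.query("kind == 'mejc'")["amplitude_na"]
            cls = classify_failures(amps.to_numpy(), nm, minis.to_numpy())
            oracle = (
                ds.oracle_counts.query("nmj_id == @nmj_id")
                .sort_values("stim_index")["n_released"]
                .to_numpy()
                == 0
            )
            agree += (cls.is_failure == oracle).sum()
            total += oracle.size
        assert agree / total >= 0.98


class TestFailureQC:
    # counts from paired failure-analysis recordings: ln(total/failures)
    @pytest.mark.parametrize(
        "m,n0,expected",
        [(2572, 409, 1.8387), (3024, 152, 2.9905)],
    )
    def test_known_count_pairs(self, m, n0, expected):
        assert failure_qc(m, n0).qc_fail == pytest.approx(expected, abs=5e-4)

    def test_all_failures_zero_qc(self):
        assert failure_qc(300, 300).qc_fail == 0.0

    def test_zero_failures_undefined(self):
        with pytest.raises(UndefinedEstimateError):
            failure_qc(300, 0)

    def test_more_failures_than_trials_invalid(self):
        with pytest.raises(ValidationError):
            failure_qc(300, 301)

    def test_short_protocol_warns(self):
        with pytest.warns(UserWarning, match="300"):
            failure_qc(100, 10)

    @given(st.integers(1, 299), st.integers(2, 300))
    @settings(derandomize=True, max_examples=50)
    def test_strictly_decreasing_in_failures(self, n1, n2):
        lo, hi = sorted([n1, n2])
        if lo == hi:
            return
        assert failure_qc(300, hi).qc_fail < failure_qc(300, lo).qc_fail


class TestVMPoints:
    def test_constant_amplitudes_zero_variance(self):
        with pytest.warns(UserWarning):
            s = vm_points({0.5: [1.0] * 4, 1.0: [1.0] * 4})
        assert s.var_I_na2[0] == 0.0
        assert s.cv2[0] == 0.0

    def test_hand_computed_two_point_level(self):
        with pytest.warns(UserWarning):
            s = vm_points({0.5: [2.0, 4.0], 1.0: [2.0, 4.0]})
        assert s.mean_I_na[0] == pytest.approx(3.0)
        assert s.var_I_na2[0] == pytest.approx(2.0)  # (n-1) denominator
        assert s.cv2[0] == pytest.approx(2.0 / 9.0)

    def test_levels_ordered_by_calcium(self):
        s = vm_points({3.0: np.ones(20) * 2, 0.5: np.ones(20)})
        assert list(s.ca_mm) == [0.5, 3.0]

    def test_single_level_rejected(self):
        with pytest.raises(InsufficientDataError):
            vm_points({0.5: [1.0, 2.0]})

    def test_simulated_binomial_variance(self, clean_truth):
        # no quantal variance, no noise: Var = N p (1-p) q^2
        proto = nq.Protocol.low_freq_evoked(ca_mm=1.5, n_stim=5000)
        ds = nq.simulate_cohort(clean_truth, [proto, nq.Protocol.low_freq_evoked(ca_mm=0.5, n_stim=5000)], 1, seed=9)
        by_ca = {ca: g["amplitude_na"].to_numpy() for ca, g in ds.events.groupby("ca_mm")}
        s = vm_points(by_ca)
        p = nq.p_release(1.5, clean_truth)
        expected = clean_truth.n_rrp * p * (1 - p) * clean_truth.q_mean**2
        se = expected * np.sqrt(2 / 4999)
        assert abs(s.var_I_na2[1] - expected) < 3 * se


class TestFitParabola:
    def test_exact_recovery_machine_precision(self):
        # points generated from Var = I - I^2/100
        s = series([10, 20, 50, 80], [9, 16, 25, 16])
        fit = fit_parabola(s)
        assert fit.A == pytest.approx(1.0, rel=1e-12)
        assert fit.B == pytest.approx(0.01, rel=1e-12)
        assert fit.n_vm == pytest.approx(100.0, rel=1e-12)
        assert fit.n_constrained

    def test_straight_line_flags_unconstrained(self):
        s = series([10, 20, 40], [5, 10, 20])  # Var = 0.5 I, no curvature
        fit = fit_parabola(s)
        assert not fit.n_constrained
        assert np.isnan(fit.n_vm)
        assert "curvature" in fit.note or "constrain" in fit.note

    def test_too_few_levels_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_parabola(series([10, 20], [9, 16]))

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValidationError):
            fit_parabola(series([10, 10, 10], [9, 9, 9]))

    def test_ground_truth_recovery_median(self, truth, vm_protocols):
        truth0 = nq.GroundTruth(n_rrp=300, q_mean=0.8, q_cv=0.3, nmj_cv=0.0)
        ds = nq.simulate_cohort(truth0, vm_protocols, 50, seed=41)
        n_vms = []
        for _, g in ds.events.groupby("nmj_id"):
            by_ca = {ca: gg["amplitude_na"].to_numpy() for ca, gg in g.groupby("ca_mm")}
            fit = fit_parabola(vm_points(by_ca))
            if np.isfinite(fit.n_vm):
                n_vms.append(fit.n_vm)
        assert np.median(n_vms) == pytest.approx(300, rel=0.15)


class TestVMParams:
    def test_printed_equation_substitution(self):
        fit = VMFit(A=2.0, B=0.01, n_vm=100.0, rss=0, se_A=0, se_B=0, n_constrained=True)
        s = series([100.0], [0.0], cv2=[0.25])
        params = vm_params(fit, s)
        assert params["p_vr"].iloc[0] == pytest.approx(0.625, rel=1e-12)
        assert params["q_na"].iloc[0] == pytest.approx(1.6, rel=1e-12)

    def test_zero_cv_limit(self):
        fit = VMFit(A=2.0, B=0.01, n_vm=100.0, rss=0, se_A=0, se_B=0, n_constrained=True)
        s = series([100.0], [0.0], cv2=[0.0])
        params = vm_params(fit, s)
        assert params["q_na"].iloc[0] == pytest.approx(fit.A)
        assert params["p_vr"].iloc[0] == pytest.approx(100.0 * fit.B / fit.A)

    def test_half_release_probability_at_apex_point(self):
        # exact binomial points of the parabola Var = I - I^2/100 (N=100, q=1):
        # at I=50, P = 0.5; cv2 there is Var/I^2 = 25/2500
        s = series([10, 20, 50, 80], [9, 16, 25, 16], cv2=[0, 0, 0.01, 0])
        fit = fit_parabola(s)
        params = vm_params(fit, s)
        assert params["p_vr"].iloc[2] == pytest.approx(0.5, rel=0.02)

    def test_consistency_check_reproduces_mean(self):
        s = series([10, 20, 50, 80], [9, 16, 25, 16])
        fit = fit_parabola(s)
        params = vm_params(fit, s)
        # N * Pvr * q == I when cv2 is taken from the same fitted parabola
        np.testing.assert_allclose(params["predicted_I_na"], s.mean_I_na, rtol=1e-9)

    def test_invalid_fit_rejected(self):
        fit = VMFit(A=0.0, B=0.01, n_vm=100.0, rss=0, se_A=0, se_B=0, n_constrained=True)
        with pytest.raises(ValidationError):
            vm_params(fit, series([10.0], [1.0]))


class TestCumulativeRRP:
    def test_single_shot_depletion(self):
        amps = np.r_[100.0, np.zeros(29)]
        r = cumulative_rrp(amps, 1.0)
        assert r.intercept_na == pytest.approx(100.0)
        assert r.slope_na_per_stim == pytest.approx(0.0, abs=1e-9)
        assert r.n_rrp_train == pytest.approx(100.0)

    def test_steady_state_gives_zero_pool(self):
        r = cumulative_rrp(np.full(30, 2.0), 1.0)
        assert r.intercept_na == pytest.approx(0.0, abs=1e-9)
        assert r.n_rrp_train == pytest.approx(0.0, abs=1e-9)

    def test_expectation_train_recovers_pool(self):
        truth = nq.GroundTruth(n_rrp=100, q_mean=1.0, q_cv=0, noise_sd=0, replenish_frac=0.0, nmj_cv=0)
        sim = nq.simulate_train(truth, nq.Protocol.train(), mode="expectation", p=0.5)
        r = cumulative_rrp(sim.amplitudes_na, 1.0)
        assert r.n_rrp_train == pytest.approx(100.0, rel=0.01)

    def test_negative_intercept_floored(self):
        # accelerating amplitudes drive the tail-fit intercept negative
        amps = np.linspace(0.0, 10.0, 30)
        r = cumulative_rrp(amps, 1.0)
        assert r.floored
        assert r.n_rrp_train == 0.0

    def test_short_train_rejected(self):
        with pytest.raises(InsufficientDataError):
            cumulative_rrp(np.ones(9), 1.0)

    def test_nonstandard_length_warns(self):
        with pytest.warns(UserWarning):
            cumulative_rrp(np.ones(25), 1.0)
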