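"""Simulator: release-probability curve, amplitude moments, trains, rendering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal, stats

import nmjquant as nq
from nmjquant.errors import ValidationError
from nmjquant.simulate import lowpass_ba, unit_waveform


class TestPRelease:
    def test_half_maximum_by_construction(self):
        truth = nq.GroundTruth(p_max=0.6, ca_half=1.5)
        assert nq.p_release(1.5, truth) == pytest.approx(0.30)

    def test_zero_calcium_limit(self, truth):
        assert nq.p_release(0.0, truth) == 0.0

    def test_saturates_at_p_max(self):
        truth = nq.GroundTruth(p_max=0.6, ca_half=1.5, hill=3.0)
        assert nq.p_release(150.0, truth) == pytest.approx(0.6, abs=1e-5)
        assert nq.p_release(150.0, truth) < 0.6

    def test_negative_calcium_rejected(self, truth):
        with pytest.raises(ValidationError):
            nq.p_release(-0.1, truth)

    @given(st.floats(0.01, 10.0), st.floats(0.02, 10.0))
    @settings(derandomize=True, max_examples=50)
    def test_monotone_in_calcium(self, ca1, ca2):
        truth = nq.GroundTruth()
        lo, hi = sorted([ca1, ca2])
        assert nq.p_release(lo, truth) <= nq.p_release(hi, truth)

    def test_calibrate_ca_half_pins_probability(self, truth):
        tuned = nq.calibrate_ca_half(truth, 0.25, 0.006)
        assert nq.p_release(0.25, tuned) == pytest.approx(0.006, rel=1e-12)


class TestGroundTruthValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_rrp=0),
            dict(q_mean=-1.0),
            dict(q_cv=1.5),
            dict(p_max=0.0),
            dict(p_max=1.2),
            dict(replenish_frac=1.5),
            dict(noise_sd=float("nan")),
            dict(ca_half=float("inf")),
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            nq.GroundTruth(**kwargs)


class TestSimulateCohort:
    def test_seed_determinism(self, truth):
        protos = [nq.Protocol.spontaneous(10.0), nq.Protocol.low_freq_evoked()]
        a = nq.simulate_cohort(truth, protos, 3, seed=99)
        b = nq.simulate_cohort(truth, protos, 3, seed=99)
        assert a.events.equals(b.events)
        assert a.nmj_meta.equals(b.nmj_meta)
        c = nq.simulate_cohort(truth, protos, 3, seed=100)
        assert not a.events["amplitude_na"].equals(c.events["amplitude_na"])

    def test_binomial_mean_recovered(self, clean_truth):
        # with no quantal/noise/NMJ variability the mean amplitude is N*p*q
        proto = nq.Protocol.low_freq_evoked(ca_mm=1.5, n_stim=10_000)
        ds = nq.simulate_cohort(clean_truth, proto, 1, seed=5)
        p = nq.p_release(1.5, clean_truth)
        expected = clean_truth.n_rrp * p * clean_truth.q_mean
        observed = ds.events["amplitude_na"].mean()
        assert observed == pytest.approx(expected, rel=0.02)

    def test_binomial_variance_recovered(self, clean_truth):
        proto = nq.Protocol.low_freq_evoked(ca_mm=1.5, n_stim=10_000)
        ds = nq.simulate_cohort(clean_truth, proto, 1, seed=5)
        p = nq.p_release(1.5, clean_truth)
        n, q = clean_truth.n_rrp, clean_truth.q_mean
        expected_var = n * p * (1 - p) * q**2
        # 3 standard errors of a sample variance: se ~ var * sqrt(2/(m-1))
        se = expected_var * np.sqrt(2 / 9999)
        assert abs(ds.events["amplitude_na"].var(ddof=1) - expected_var) < 3 * se

    def test_mini_count_matches_poisson_rate(self):
        truth = nq.GroundTruth(mini_rate=2.0)
        ds = nq.simulate_cohort(truth, nq.Protocol.spontaneous(100.0), 1, seed=7)
        n = len(ds.events)
        assert abs(n - 200) < 3 * np.sqrt(200)

    def test_oracle_counts_bounded_by_pool(self, truth):
        ds = nq.simulate_cohort(truth, nq.Protocol.failure(), 5, seed=3)
        merged = ds.oracle_counts.merge(ds.nmj_meta, on="nmj_id")
        assert (merged["n_released"] <= merged["true_n_rrp"]).all()

    def test_poisson_limit_of_binomial_release(self):
        # N >= 500, p <= 0.01: release counts follow Poisson(N*p)
        truth = nq.GroundTruth(n_rrp=500, q_cv=0.0, noise_sd=0.0, nmj_cv=0.0)
        truth = nq.calibrate_ca_half(truth, 0.25, 0.01)
        proto = nq.Protocol(kind="failure", ca_mm=0.25, stim_freq_hz=1.0, n_stim=10_000)
        ds = nq.simulate_cohort(truth, proto, 1, seed=17)
        counts = ds.oracle_counts["n_released"].to_numpy()
        mu = 5.0
        kmax = 14
        observed = np.bincount(np.minimum(counts, kmax), minlength=kmax + 1)
        pk = stats.poisson.pmf(np.arange(kmax + 1), mu)
        pk[kmax] = 1 - pk[:kmax].sum()
        res = stats.chisquare(observed, pk * counts.size)
        assert res.pvalue > 0.01


class TestSimulateTrain:
    def test_full_depletion_first_stimulus(self):
        truth = nq.GroundTruth(n_rrp=100, q_cv=0, noise_sd=0, replenish_frac=0.0, nmj_cv=0)
        sim = nq.simulate_train(truth, nq.Protocol.train(), mode="expectation", p=1.0)
        assert sim.release_counts[0] == 100
        assert np.all(sim.release_counts[1:] == 0)

    def test_expectation_mode_geometric_series(self):
        truth = nq.GroundTruth(n_rrp=100, q_mean=1.0, q_cv=0, noise_sd=0, replenish_frac=0.0, nmj_cv=0)
        sim = nq.simulate_train(truth, nq.Protocol.train(), mode="expectation", p=0.5)
        assert sim.amplitudes_na.sum() == pytest.approx(100 * (1 - 0.5**30), abs=1e-6)

    def test_stochastic_conservation_bound(self, truth):
        sim = nq.simulate_train(truth, nq.Protocol.train(), mode="stochastic", seed=11)
        bound = truth.n_rrp + 29 * truth.replenish_frac * truth.n_rrp
        assert sim.release_counts.sum() <= bound

    @given(st.integers(0, 2**31 - 1))
    @settings(derandomize=True, max_examples=25)
    def test_pool_stays_within_bounds(self, seed):
        truth = nq.GroundTruth(n_rrp=50, replenish_frac=0.3, nmj_cv=0)
        sim = nq.simulate_train(truth, nq.Protocol.train(), mode="stochastic", seed=seed)
        assert np.all(sim.pool_before >= 0)
        assert np.all(sim.pool_before <= truth.n_rrp)
        assert sim.release_counts.sum() <= truth.n_rrp + sim.replenished.sum() + 1e-9

    def test_requires_train_protocol(self, truth):
        with pytest.raises(ValidationError):
            nq.simulate_train(truth, nq.Protocol.low_freq_evoked(), seed=1)


class TestRenderSweep:
    def test_empty_render_is_flat_zero(self, kernel):
        sw = nq.render_sweep(kernel, 10_000, 1.0, seed=1, noise_sd_na=0.0)
        assert np.allclose(sw.current_na, 0.0)

    def test_filtered_peak_calibration(self, kernel):
        sw = nq.render_sweep(
            kernel, 10_000, 1.0, seed=1, mini_times_s=[0.3], mini_amplitudes_na=[1.0]
        )
        assert np.abs(sw.current_na).max() == pytest.approx(1.0, rel=0.02)
        assert sw.current_na.min() < 0  # inward current, negative-going

    def test_noise_sd_matches_direct_filter_simulation(self, kernel):
        noise_sd = 0.2
        sw = nq.render_sweep(kernel, 10_000, 5.0, seed=2, noise_sd_na=noise_sd)
        # oracle: filter white noise of the same sd directly
        rng = np.random.default_rng(999)
        b, a = lowpass_ba(10_000)
        ref = signal.lfilter(b, a, rng.normal(0, noise_sd, 50_000))
        assert sw.current_na.std() == pytest.approx(ref.std(), rel=0.10)

    def test_event_outside_duration_rejected(self, kernel):
        with pytest.raises(ValidationError):
            nq.render_sweep(
                kernel, 10_000, 1.0, seed=1, mini_times_s=[2.0], mini_amplitudes_na=[1.0]
            )

    def test_low_sample_rate_rejected(self, kernel):
        with pytest.raises(ValidationError):
            nq.render_sweep(kernel, 2_000, 1.0, seed=1)

    def test_unit_waveform_shape(self, kernel):
        u = unit_waveform(kernel, 10_000)
        assert u[0] == pytest.approx(0.0)
        assert u.max() > 0
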