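"""Unit and property tests for ACF, delay selection, tolerance and ApEn."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kinentropy import (
    ApEnConfig,
    analyze_series,
    compute_acf,
    compute_apen,
    estimate_tau,
    tolerance_from_series,
)
from kinentropy.entropy import AcfProfile
from kinentropy.errors import (
    ConstantSeriesError,
    InsufficientEmbeddingError,
    TauNotFoundError,
)
from kinentropy.reference import apen_reference
from kinentropy.simulate import SignalParams, simulate_joint_series

from _oracles import acf_oracle


class TestAcf:
    def test_zero_shift_is_unity_and_bounded(self, rng):
        x = rng.normal(size=200)
        prof = compute_acf(x, 50)
        assert prof.acf[0] == 1.0
        assert np.all(np.abs(prof.acf) <= 1.0 + 1e-12)

    def test_alternating_closed_form(self):
        # mean-zero alternating series: acf(1) = -(n-1)/n
        prof = compute_acf([1.0, -1.0, 1.0, -1.0])
        assert prof.acf[1] == pytest.approx(-0.75, abs=1e-12)

    def test_matches_direct_summation_oracle(self, rng):
        x = rng.normal(size=80) + np.sin(np.arange(80) / 5.0)
        prof = compute_acf(x, 20)
        np.testing.assert_allclose(prof.acf, acf_oracle(x, 20), atol=1e-10)

    def test_iid_gaussian_near_zero(self):
        x = np.random.default_rng(1234).normal(size=10_000)
        prof = compute_acf(x, 10)
        assert np.all(np.abs(prof.acf[1:]) < 0.05)

    def test_constant_series_rejected(self):
        with pytest.raises(ConstantSeriesError):
            compute_acf(np.ones(50))

    @pytest.mark.parametrize("max_shift", [0, 60])
    def test_max_shift_out_of_range(self, max_shift, rng):
        with pytest.raises(ValueError):
            compute_acf(rng.normal(size=50), max_shift)


def _profile(vals):
    acf = np.concatenate([[1.0], vals])
    return AcfProfile(shifts=np.arange(acf.size), acf=acf, n_source=100)


class TestEstimateTau:
    def test_first_shift_below_threshold(self):
        est = estimate_tau(_profile([0.5, 0.09, -0.3, 0.01]), 0.1)
        assert est.found and est.tau == 2
        assert est.acf_at_tau == pytest.approx(0.09)

    def test_absence_reported_via_flag(self):
        est = estimate_tau(_profile([0.9, 0.5, 0.2]), 0.1)
        assert not est.found and est.tau is None

    def test_strongly_negative_acf_does_not_qualify(self):
        # "closest to 0" is a magnitude criterion by default
        est = estimate_tau(_profile([-0.8, 0.05]), 0.1)
        assert est.tau == 2

    def test_signed_mode_accepts_negative(self):
        est = estimate_tau(_profile([-0.8, 0.05]), 0.1, signed=True)
        assert est.tau == 1

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_threshold_monotone(self, seed):
        # a smaller threshold never yields a smaller tau on the same profile
        vals = np.random.default_rng(seed).uniform(-1, 1, size=30)
        prof = _profile(vals)
        taus = []
        for thr in (0.05, 0.1, 0.3, 0.6):
            est = estimate_tau(prof, thr)
            taus.append(est.tau if est.found else np.inf)
        assert all(a >= b for a, b in zip(taus, taus[1:]))


class TestTolerance:
    def test_scales_sample_sd(self):
        x = np.array([0.0, 10.0])  # sample SD (n-1) is sqrt(50); scale to SD 5
        x = x / np.std(x, ddof=1) * 5.0
        assert tolerance_from_series(x, 0.2) == pytest.approx(1.0)

    def test_constant_gives_zero(self):
        assert tolerance_from_series(np.full(10, 3.3)) == 0.0

    @given(st.floats(-50, 50).filter(lambda a: abs(a) > 1e-6))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_homogeneity(self, a):
        x = np.random.default_rng(5).normal(size=40)
        assert tolerance_from_series(a * x) == pytest.approx(
            abs(a) * tolerance_from_series(x), rel=1e-9
        )


class TestApEn:
    def test_constant_series_is_zero(self):
        res = compute_apen(np.full(100, 7.0), m=2, r=0.5, tau=1)
        assert res.apen == 0.0

    def test_affine_invariance_with_rescaled_tolerance(self, rng):
        x = rng.normal(size=300)
        y = 3.0 * x + 7.0
        a1 = compute_apen(x, 2, 0.2 * np.std(x, ddof=1), 1).apen
        a2 = compute_apen(y, 2, 0.2 * np.std(y, ddof=1), 1).apen
        assert a1 == pytest.approx(a2, abs=1e-10)

    @pytest.mark.parametrize("m,tau", [(1, 1), (2, 1), (2, 5), (3, 2)])
    def test_matches_naive_reference(self, m, tau, rng):
        x = rng.normal(size=250)
        r = 0.2 * np.std(x, ddof=1)
        assert compute_apen(x, m, r, tau).apen == pytest.approx(
            apen_reference(x, m, r, tau), abs=1e-12
        )

    def test_non_increasing_in_r(self):
        s = simulate_joint_series(SignalParams(), 10.0, 100.0, 11)
        x = s.values
        sd = np.std(x, ddof=1)
        apens = [
            compute_apen(x, 2, f * sd, 1).apen
            for f in np.linspace(0.2, 2.0, 10)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(apens, apens[1:]))

    def test_insufficient_embedding_rejected(self):
        with pytest.raises(InsufficientEmbeddingError):
            compute_apen(np.arange(30.0), m=2, r=0.5, tau=12)

    def test_vector_counts_recorded(self, rng):
        x = rng.normal(size=120)
        res = compute_apen(x, 2, 0.3, 4)
        assert res.m_vectors == 120 - 4
        assert res.m1_vectors == 120 - 8
        assert (res.m, res.tau, res.n) == (2, 4, 120)

    def test_r_zero_non_constant_is_flagged(self, rng):
        res = compute_apen(rng.normal(size=60), 2, 0.0, 1)
        assert res.notes


class TestAnalyzeSeries:
    def test_constant_series_fails_recording(self):
        with pytest.raises(ConstantSeriesError):
            analyze_series(np.full(500, 1.0))

    def test_deterministic_on_same_input(self):
        s = simulate_joint_series(SignalParams(), 30.0, 100.0, 3)
        a = analyze_series(s.values)
        b = analyze_series(s.values)
        assert a.apen.apen == b.apen.apen
        assert a.tau == b.tau and a.mean_angle == b.mean_angle

    def test_tau_not_found_raises(self):
        # slow ramp: ACF stays near 1 over a restricted shift range
        x = np.linspace(0.0, 10.0, 2000)
        x += np.random.default_rng(0).normal(0, 0.001, 2000)
        with pytest.raises(TauNotFoundError):
            analyze_series(x, ApEnConfig(max_shift_fraction=0.05))

    def test_noisier_signal_has_higher_apen(self):
        # median over 20 replicates at sigma 2.0 vs 0.2
        meds = {}
        for sd in (0.2, 2.0):
            vals = []
            for seed in range(20):
                s = simulate_joint_series(
                    SignalParams(noise_sd=sd), 30.0, 100.0, seed
                )
                vals.append(analyze_series(s.values).apen.apen)
            meds[sd] = np.median(vals)
        assert meds[2.0] > meds[0.2]
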