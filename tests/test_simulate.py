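"""Synthetic signal and cohort generator: determinism, structure, ordering."""

import numpy as np
import pandas as pd
import pytest

from kinentropy import (
    CohortSpec,
    SignalParams,
    analyze_series,
    make_fixture,
    run_pipeline,
    simulate_cohort,
    simulate_joint_series,
)
from kinentropy.io import load_cohort


class TestJointSeries:
    def test_same_seed_reproduces(self):
        a = simulate_joint_series(SignalParams(), 10.0, 100.0, 5)
        b = simulate_joint_series(SignalParams(), 10.0, 100.0, 5)
        np.testing.assert_array_equal(a.values, b.values)
        c = simulate_joint_series(SignalParams(), 10.0, 100.0, 6)
        assert not np.array_equal(a.values, c.values)

    def test_noise_free_signal_is_periodic_with_tiny_apen(self):
        p = SignalParams(noise_sd=0.0, phase_jitter_sd=0.0)
        s = simulate_joint_series(p, 30.0, 100.0, 1)
        # 9 cycles at 0.9 Hz span 10 s = 1000 samples exactly
        k = 1000
        np.testing.assert_allclose(s.values[k:], s.values[:-k], atol=1e-9)
        assert analyze_series(s.values).apen.apen < 0.05

    def test_noise_component_sd_converges(self):
        # pure AR(1): empirical SD within 5% of noise_sd at 1e4 samples
        p = SignalParams(harmonics=(), noise_sd=2.0, mean_angle=0.0)
        sds = [
            np.std(simulate_joint_series(p, 100.0, 100.0, seed).values)
            for seed in range(20)
        ]
        assert abs(np.mean(sds) - 2.0) / 2.0 < 0.05

    def test_apen_nondecreasing_in_noise(self):
        meds = []
        for sd in (0.2, 0.5, 1.0, 2.0):
            vals = [
                analyze_series(
                    simulate_joint_series(
                        SignalParams(noise_sd=sd), 30.0, 100.0, seed
                    ).values
                ).apen.apen
                for seed in range(20)
            ]
            meds.append(np.median(vals))
        assert all(a <= b for a, b in zip(meds, meds[1:]))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SignalParams(ar_coeff=1.0)
        with pytest.raises(ValueError):
            SignalParams(noise_sd=-1.0)


class TestCohort:
    def test_manifest_counts_match_spec(self, tmp_path):
        spec = CohortSpec(
            n_pd=3, n_oa=2, dances=("tango", "waltz"), recordings_per_dance=2,
            duration_min_range=(0.2, 0.3), channels=(("knee", "flexion"),),
            seed=1,
        )
        manifest = simulate_cohort(spec, tmp_path)
        df = pd.read_csv(manifest)
        assert (df["group"] == "PD").sum() == 3 * 2 * 2
        assert (df["group"] == "OA").sum() == 2 * 2 * 2
        assert df["recording_id"].is_unique

    def test_total_recordings_mode(self, tmp_path):
        spec = CohortSpec(
            n_pd=7, n_oa=0, dances=("tango",), n_recordings_total=10,
            duration_min_range=(0.2, 0.2), channels=(("knee", "flexion"),),
            seed=2,
        )
        df = pd.read_csv(simulate_cohort(spec, tmp_path))
        assert len(df) == 10
        # round-robin: every participant contributes at least one recording
        assert df["participant_id"].nunique() == 7

    def test_symmetric_gamma_means_identical_parameters(self, tmp_path):
        # with gamma = 1 and no noise the two sides are literally identical
        spec = CohortSpec(
            n_pd=1, n_oa=0, dances=("tango",), duration_min_range=(0.2, 0.2),
            channels=(("knee", "flexion"),), noise_sd=0.0, asymmetry_gamma=1.0,
            seed=3,
        )
        rec = load_cohort(simulate_cohort(spec, tmp_path)).recordings[0]
        np.testing.assert_array_equal(
            rec.channels["left_knee_flexion"].values,
            rec.channels["right_knee_flexion"].values,
        )

    def test_asymmetric_cohort_left_more_regular(self, tmp_path):
        spec = CohortSpec(
            n_pd=3, n_oa=0, dances=("tango",), n_recordings_total=6,
            duration_min_range=(0.5, 0.5), channels=(("knee", "flexion"),),
            asymmetry_gamma=0.25, seed=4,
        )
        report = run_pipeline(simulate_cohort(spec, tmp_path))
        agg = report.aggregates
        left = agg[agg["side"] == "left"]["mean_apen"].mean()
        right = agg[agg["side"] == "right"]["mean_apen"].mean()
        assert left < right

    def test_generated_files_pass_io_validation(self, small_cohort_manifest):
        result = load_cohort(small_cohort_manifest)
        assert not result.exclusions
        assert all(r.fs == pytest.approx(100.0) for r in result.recordings)

    def test_master_seed_reproducibility(self, tmp_path):
        spec = CohortSpec(
            n_pd=1, n_oa=1, dances=("tango",), duration_min_range=(0.2, 0.2),
            channels=(("knee", "flexion"),), seed=9,
        )
        m1 = simulate_cohort(spec, tmp_path / "a")
        m2 = simulate_cohort(spec, tmp_path / "b")
        for f in sorted(p.name for p in (tmp_path / "a").iterdir()):
            assert (tmp_path / "a" / f).read_bytes() == (tmp_path / "b" / f).read_bytes()
        assert m1.name == m2.name

    def test_invalid_gamma_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(asymmetry_gamma=0.0)


class TestFixtures:
    def test_fixtures_are_byte_identical(self, tmp_path):
        for name in ("minimal_symmetric", "tau_not_found"):
            make_fixture(name, tmp_path / "a" / name)
            make_fixture(name, tmp_path / "b" / name)
            files_a = sorted((tmp_path / "a" / name).iterdir())
            for fa in files_a:
                fb = tmp_path / "b" / name / fa.name
                assert fa.read_bytes() == fb.read_bytes()

    def test_minimal_symmetric_runs_pipeline(self, minimal_symmetric_manifest):
        report = run_pipeline(minimal_symmetric_manifest)
        assert (report.qc["status"] == "ok").all()

    def test_unknown_fixture_lists_available(self, tmp_path):
        with pytest.raises(ValueError, match="minimal_symmetric"):
            make_fixture("nope", tmp_path)
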