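"""Synthetic quasi-periodic joint-angle recordings and whole dance cohorts.

The generator emulates the statistical structure the entropy pipeline
assumes: 100 Hz joint-angle channels dominated by a stepping rhythm
(fundamental ~0.9 Hz plus harmonics), corrupted by AR(1) "irregularity"
noise and optional cumulative phase jitter.  It is not a biomechanical
model — it exists so every pipeline stage can be exercised and calibrated
without any real recordings.

Asymmetric regularity (the Parkinson's-like condition) is modelled by
multiplying the noise SD of the affected side's channels by
``asymmetry_gamma`` in (0, 1]: a smaller gamma means a more regular (lower
ApEn) affected side, the direction of the loss-of-complexity hypothesis.
Amplitudes and mean angles stay side-equal, so mean-angle contrasts are null
unless configured otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .io import (
    LOWER_LIMB,
    JointSeries,
    ManifestEntry,
    Recording,
    channel_name,
    write_recording_csv,
)

__all__ = [
    "SignalParams",
    "CohortSpec",
    "default_signal_params",
    "simulate_joint_series",
    "simulate_cohort",
    "make_fixture",
    "FIXTURES",
]

#: per-channel harmonic content (multiple of base frequency, amplitude in
#: degrees, phase in radians) and resting mean angle, loosely shaped on
#: lower-limb range of motion during partnered dance
_HARMONICS = {
    ("knee", "flexion"): ((1, 30.0, 0.0), (2, 8.0, 0.6)),
    ("hip", "flexion"): ((1, 20.0, 0.0), (2, 5.0, 0.4)),
    ("hip", "abduction"): ((1, 8.0, 0.0),),
    ("hip", "rotation"): ((1, 8.0, 0.0),),
    ("elbow", "flexion"): ((1, 15.0, 0.0),),
}
_MEAN_ANGLE = {
    ("knee", "flexion"): 30.0,
    ("hip", "flexion"): 15.0,
    ("hip", "abduction"): 5.0,
    ("hip", "rotation"): 0.0,
    ("elbow", "flexion"): 70.0,
}

#: default stroke-to-stroke irregularity, degrees.  A couple of degrees of
#: cycle-to-cycle joint-angle variability is typical of older adults moving
#: to music; it sits inside the spec'd irregularity range exercised in tests.
DEFAULT_NOISE_SD = 2.0


@dataclass(frozen=True)
class SignalParams:
    """Generator parameters for one joint-angle channel.

    base_freq: stepping rate in Hz.
    harmonics: (multiple, amplitude_deg, phase_rad) components of the
        periodic part.
    mean_angle: offset in degrees.
    noise_sd: stationary SD of the AR(1) irregularity component, degrees.
    ar_coeff: AR(1) coefficient in [0, 1); gives the noise a short memory so
        the ACF is not a pure delta.
    phase_jitter_sd: SD (radians) of the per-cycle random-walk phase drift;
        0 keeps the rhythm metronomic.
    """

    base_freq: float = 0.9
    harmonics: tuple[tuple[float, float, float], ...] = ((1, 30.0, 0.0),)
    mean_angle: float = 0.0
    noise_sd: float = DEFAULT_NOISE_SD
    ar_coeff: float = 0.3
    phase_jitter_sd: float = 0.0

    def __post_init__(self):
        if self.base_freq <= 0:
            raise ValueError("base_freq must be > 0")
        if any(a < 0 for _, a, _ in self.harmonics):
            raise ValueError("harmonic amplitudes must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.ar_coeff < 1:
            raise ValueError("ar_coeff must be in [0, 1)")
        if self.phase_jitter_sd < 0:
            raise ValueError("phase_jitter_sd must be >= 0")


def default_signal_params(
    joint: str, measure: str, *, noise_sd: float = DEFAULT_NOISE_SD,
    phase_offset: float = 0.0, **overrides,
) -> SignalParams:
    """Standard parameters for a named channel, with optional overrides."""
    key = (joint, measure)
    if key not in _HARMONICS:
        raise ValueError(f"no default parameters for channel {joint}/{measure}")
    harmonics = tuple(
        (mult, amp, ph + mult * phase_offset) for mult, amp, ph in _HARMONICS[key]
    )
    kwargs = dict(
        harmonics=harmonics, mean_angle=_MEAN_ANGLE[key], noise_sd=noise_sd
    )
    kwargs.update(overrides)
    return SignalParams(**kwargs)


def _ar1(rng: np.random.Generator, n: int, coeff: float, sd: float) -> np.ndarray:
    if sd == 0.0:
        return np.zeros(n)
    innov_sd = sd * math.sqrt(1.0 - coeff * coeff)
    innov = rng.normal(0.0, innov_sd, size=n)
    innov[0] = rng.normal(0.0, sd)  # start at the stationary distribution
    return lfilter([1.0], [1.0, -coeff], innov)


def simulate_joint_series(
    params: SignalParams,
    duration_s: float,
    fs: float = 100.0,
    seed: int | np.random.SeedSequence = 0,
    *,
    joint: str = "knee",
    measure: str = "flexion",
    side: str = "right",
    recording_id: str = "sim",
) -> JointSeries:
    """One channel: harmonic stack + cumulative phase jitter + AR(1) noise.

    theta(t) = mean + sum_h A_h sin(2*pi*h*f*t + phi_h + h*J(t)) + eps(t),
    deterministic given the seed.
    """
    n = int(round(duration_s * fs))
    if n < 100:
        raise ValueError("duration too short for downstream analysis")
    rng = np.random.default_rng(seed)
    t = np.arange(n) / fs
    if params.phase_jitter_sd > 0:
        cycle = np.floor(params.base_freq * t).astype(np.int64)
        steps = rng.normal(0.0, params.phase_jitter_sd, size=int(cycle[-1]) + 1)
        steps[0] = 0.0
        jitter = np.cumsum(steps)[cycle]
    else:
        jitter = 0.0
    theta = np.full(n, params.mean_angle, dtype=np.float64)
    for mult, amp, phase in params.harmonics:
        theta += amp * np.sin(
            2.0 * np.pi * mult * params.base_freq * t + phase + mult * jitter
        )
    theta += _ar1(rng, n, params.ar_coeff, params.noise_sd)
    return JointSeries(
        values=theta, fs=fs, joint=joint, measure=measure, side=side,
        recording_id=recording_id,
    )


@dataclass(frozen=True)
class CohortSpec:
    """Shape and conditions of a simulated dance cohort.

    ``n_recordings_total`` (per group), when set, distributes that many
    recordings round-robin over the group's participant x dance grid —
    matching the unbalanced recording counts of a real community class;
    otherwise every participant contributes ``recordings_per_dance``
    recordings of every dance.  PD-like participants get the affected side's
    noise SD multiplied by ``asymmetry_gamma`` on all simulated channels.
    """

    n_pd: int = 7
    n_oa: int = 5
    dances: tuple[str, ...] = ("tango", "waltz", "foxtrot", "line")
    recordings_per_dance: int = 1
    n_recordings_total: int | None = None
    duration_min_range: tuple[float, float] = (1.0, 4.0)
    fs: float = 100.0
    asymmetry_gamma: float = 1.0
    affected_side: str = "left"
    channels: tuple[tuple[str, str], ...] = LOWER_LIMB
    noise_sd: float = DEFAULT_NOISE_SD
    phase_jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_pd < 0 or self.n_oa < 0 or self.n_pd + self.n_oa < 1:
            raise ValueError("need at least one participant")
        if not 0 < self.asymmetry_gamma <= 1:
            raise ValueError("asymmetry_gamma must be in (0, 1]")
        if self.recordings_per_dance < 1:
            raise ValueError("recordings_per_dance must be >= 1")
        lo, hi = self.duration_min_range
        if not 0 < lo <= hi:
            raise ValueError("invalid duration range")


def _group_assignments(spec: CohortSpec, group: str) -> list[tuple[str, str]]:
    """(participant_id, dance) for each recording of one group."""
    n = spec.n_pd if group == "PD" else spec.n_oa
    prefix = "P" if group == "PD" else "O"
    participants = [f"{prefix}{i + 1:02d}" for i in range(n)]
    if n == 0:
        return []
    grid = [(p, d) for d in spec.dances for p in participants]
    if spec.n_recordings_total is None:
        return grid * spec.recordings_per_dance
    return [grid[i % len(grid)] for i in range(spec.n_recordings_total)]


def simulate_cohort(spec: CohortSpec, out_dir) -> Path:
    """Write recording CSVs and a manifest; return the manifest path.

    Sub-seeds are derived deterministically from ``spec.seed`` keyed on
    (group, recording index, channel index) so the dataset is reproducible
    and independent of file-system ordering.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for g_idx, group in enumerate(("PD", "OA")):
        for r_idx, (pid, dance) in enumerate(_group_assignments(spec, group)):
            rec_id = f"{group.lower()}_r{r_idx + 1:03d}"
            dur_rng = np.random.default_rng(
                np.random.SeedSequence([spec.seed, g_idx, r_idx, 997])
            )
            lo, hi = spec.duration_min_range
            duration_s = 60.0 * float(dur_rng.uniform(lo, hi))
            channels: dict[str, JointSeries] = {}
            for c_idx, (joint, measure) in enumerate(spec.channels):
                for s_idx, side in enumerate(("left", "right")):
                    noise = spec.noise_sd
                    if group == "PD" and side == spec.affected_side:
                        noise *= spec.asymmetry_gamma
                    # sides share identical deterministic parameters; every
                    # downstream statistic is phase-invariant, so contralateral
                    # phase relationships are not modelled
                    params = default_signal_params(
                        joint, measure, noise_sd=noise,
                        phase_jitter_sd=spec.phase_jitter_sd,
                    )
                    ss = np.random.SeedSequence(
                        [spec.seed, g_idx, r_idx, c_idx, s_idx]
                    )
                    series = simulate_joint_series(
                        params, duration_s, spec.fs, ss,
                        joint=joint, measure=measure, side=side,
                        recording_id=rec_id,
                    )
                    channels[series.name] = series
            rec = Recording(
                recording_id=rec_id, participant_id=pid, group=group,
                dance=dance, channels=channels, fs=spec.fs,
            )
            fname = f"{rec_id}.csv"
            write_recording_csv(rec, out_dir / fname)
            rows.append(
                {
                    "file": fname,
                    "participant_id": pid,
                    "group": group,
                    "dance": dance,
                    "recording_id": rec_id,
                }
            )
    manifest_path = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest_path, index=False, lineterminator="\n")
    return manifest_path


def _fixture_minimal_symmetric(out_dir: Path) -> Path:
    spec = CohortSpec(
        n_pd=1, n_oa=1, dances=("tango",), recordings_per_dance=1,
        duration_min_range=(0.5, 0.5), channels=(("knee", "flexion"), ("hip", "flexion")),
        asymmetry_gamma=1.0, seed=20220655,
    )
    return simulate_cohort(spec, out_dir)


def _fixture_tau_not_found(out_dir: Path) -> Path:
    """A trend-dominated channel whose ACF stays far from zero at short lags.

    Designed for configurations that bound the delay search (e.g.
    max_shift_fraction <= 0.1): over the first tenth of the lags the ACF of a
    near-constant ramp stays well above 0.1, so no delay qualifies and the
    recording fails the tau search.
    """
    out_dir.mkdir(parents=True, exist_ok=True)
    fs = 100.0
    n = 3000
    rng = np.random.default_rng(20220656)
    ramp = np.linspace(0.0, 10.0, n) + rng.normal(0.0, 0.01, n)
    series = JointSeries(
        values=ramp, fs=fs, joint="knee", measure="flexion", side="left",
        recording_id="trend_r001",
    )
    rec = Recording(
        recording_id="trend_r001", participant_id="T01", group="PD",
        dance="tango", channels={series.name: series}, fs=fs,
    )
    write_recording_csv(rec, out_dir / "trend_r001.csv")
    pd.DataFrame(
        [
            {
                "file": "trend_r001.csv",
                "participant_id": "T01",
                "group": "PD",
                "dance": "tango",
                "recording_id": "trend_r001",
            }
        ]
    ).to_csv(out_dir / "manifest.csv", index=False, lineterminator="\n")
    return out_dir / "manifest.csv"


FIXTURES = {
    "minimal_symmetric": _fixture_minimal_symmetric,
    "tau_not_found": _fixture_tau_not_found,
}


def make_fixture(name: str, out_dir) -> Path:
    """Emit a small pinned dataset by name; returns the manifest path."""
    if name not in FIXTURES:
        raise ValueError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}"
        )
    return FIXTURES[name](Path(out_dir))
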