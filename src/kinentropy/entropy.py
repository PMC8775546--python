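"""Approximate entropy of a time series with autocorrelation-based delay selection.

Approximate entropy (ApEn) quantifies the regularity of a time series: a
perfectly repetitive signal scores near zero, an unpredictable one scores
higher.  Given a series u(1..N), an embedding dimension ``m`` (pattern
length), a tolerance ``r`` and a delay ``tau``, ApEn is

    ApEn(m, r, tau) = Phi^m - Phi^{m+1}

where, at dimension d, the M_d = N - (d-1)*tau embedding vectors are
x_d(i) = (u(i), u(i+tau), ..., u(i+(d-1)tau)),

    C_i^d = #{ j : max_k |x_d(i)_k - x_d(j)_k| <= r } / M_d
    Phi^d = (1/M_d) * sum_i ln C_i^d .

The Chebyshev (max-norm) distance is used, the comparison is non-strict, and
the self-match j = i is counted, so every C_i^d >= 1/M_d and the logarithm is
always defined.  The tolerance is conventionally r = 0.2 * SD(u), which makes
ApEn invariant under affine rescaling of the signal.

The delay ``tau`` is chosen from the autocorrelation function (ACF): the
smallest positive lag at which the ACF is closest to zero, operationalized as
the first lag with |acf| below a threshold (0.1 by default).  At that lag the
series is essentially decorrelated from its shifted copy, so successive
embedding coordinates carry non-redundant information.

Shift indexing is 0-based throughout: shift 0 is the unshifted series
(acf = 1).  Some motion-capture reports count the unshifted series as
"lag 1"; that 1-based display lag equals shift + 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from statsmodels.tsa.stattools import acf as _sm_acf

from .errors import ConstantSeriesError, InsufficientEmbeddingError, TauNotFoundError

__all__ = [
    "AcfProfile",
    "TauEstimate",
    "ApEnConfig",
    "ApEnResult",
    "SeriesAnalysis",
    "compute_acf",
    "estimate_tau",
    "tolerance_from_series",
    "compute_apen",
    "analyze_series",
]


def _as_series(x) -> np.ndarray:
    arr = np.asarray(x, dtype=np.float64)
    if arr.ndim != 1:
        raise ValueError(f"expected a 1-d series, got shape {arr.shape}")
    if arr.size < 2:
        raise ValueError(f"series needs at least 2 samples, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("series contains non-finite values")
    return arr


@dataclass(frozen=True)
class AcfProfile:
    """Sample autocorrelation by shift, 0-based (shift 0 = no shift, acf = 1)."""

    shifts: np.ndarray
    acf: np.ndarray
    n_source: int

    def __post_init__(self):
        if self.shifts.shape != self.acf.shape:
            raise ValueError("shifts and acf must have equal length")

    @property
    def max_shift(self) -> int:
        return int(self.shifts[-1])


@dataclass(frozen=True)
class TauEstimate:
    """Selected embedding delay: first shift >= 1 with |acf| under ``threshold``."""

    tau: int | None
    acf_at_tau: float | None
    threshold: float
    found: bool


@dataclass(frozen=True)
class ApEnConfig:
    """Parameters of the single-series analysis chain.

    m: pattern length (embedding dimension of the first pass).
    r_factor: tolerance as a multiple of the series' sample SD.
    acf_threshold: |acf| bound defining a usable delay.
    max_shift_fraction: fraction of (n - 1) searched for the delay; 1.0
        searches every possible shift, smaller values bound the search.
    signed_threshold: if True the delay criterion is acf < threshold
        (signed) instead of |acf| < threshold.
    """

    m: int = 2
    r_factor: float = 0.2
    acf_threshold: float = 0.1
    max_shift_fraction: float = 1.0
    signed_threshold: bool = False

    def __post_init__(self):
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.r_factor <= 0:
            raise ValueError("r_factor must be > 0")
        if not 0 < self.acf_threshold < 1:
            raise ValueError("acf_threshold must be in (0, 1)")
        if not 0 < self.max_shift_fraction <= 1:
            raise ValueError("max_shift_fraction must be in (0, 1]")


@dataclass(frozen=True)
class ApEnResult:
    """An ApEn value together with the exact parameters that produced it."""

    apen: float
    m: int
    r: float
    tau: int
    n: int
    m_vectors: int  # embedding vectors at dimension m
    m1_vectors: int  # embedding vectors at dimension m + 1
    notes: tuple[str, ...] = field(default=())


def compute_acf(x, max_shift: int | None = None) -> AcfProfile:
    """Sample autocorrelation with the shared-denominator estimator.

    acf(k) = sum_{t=1..n-k} (x_t - xbar)(x_{t+k} - xbar)
             / sum_{t=1..n} (x_t - xbar)^2

    which guarantees acf(0) = 1 and |acf(k)| <= 1.  ``max_shift`` defaults to
    n - 1 (every possible shift).
    """
    arr = _as_series(x)
    n = arr.size
    if np.var(arr) == 0.0:
        raise ConstantSeriesError("constant series: autocorrelation undefined")
    if max_shift is None:
        max_shift = n - 1
    if not 1 <= max_shift <= n - 1:
        raise ValueError(f"max_shift must be in [1, {n - 1}], got {max_shift}")
    acf = _sm_acf(arr, nlags=max_shift, fft=True, adjusted=False)
    acf[0] = 1.0  # exact by construction; guard fft rounding
    return AcfProfile(shifts=np.arange(max_shift + 1), acf=acf, n_source=n)


def estimate_tau(
    profile: AcfProfile, threshold: float = 0.1, *, signed: bool = False
) -> TauEstimate:
    """First shift k >= 1 with |acf(k)| < threshold (acf(k) < threshold if signed).

    Absence of a qualifying shift is reported via ``found=False`` rather than
    an exception; the cohort pipeline turns it into a per-recording failure.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    vals = profile.acf[1:]
    hit = (vals < threshold) if signed else (np.abs(vals) < threshold)
    idx = np.flatnonzero(hit)
    if idx.size == 0:
        return TauEstimate(tau=None, acf_at_tau=None, threshold=threshold, found=False)
    tau = int(idx[0] + 1)
    return TauEstimate(
        tau=tau, acf_at_tau=float(profile.acf[tau]), threshold=threshold, found=True
    )


def tolerance_from_series(x, r_factor: float = 0.2) -> float:
    """Match tolerance r = r_factor * sample SD (n - 1 denominator).

    A constant series yields 0.0 (the SD is zero); callers decide whether a
    zero tolerance is meaningful for their data.
    """
    arr = _as_series(x)
    if r_factor <= 0:
        raise ValueError("r_factor must be > 0")
    return float(r_factor * np.std(arr, ddof=1))


@njit(cache=True)
def _match_counts(x, m, r, tau):  # pragma: no cover - exercised via compute_apen
    """Per-vector match counts at dimensions m and m+1 (self-match included)."""
    n = x.shape[0]
    mm = n - (m - 1) * tau
    mm1 = n - m * tau
    cm = np.ones(mm)
    cm1 = np.ones(mm1)
    for i in range(mm):
        for j in range(i + 1, mm):
            ok = True
            for k in range(m):
                d = abs(x[i + k * tau] - x[j + k * tau])
                if d > r:
                    ok = False
                    break
            if ok:
                cm[i] += 1.0
                cm[j] += 1.0
                if j < mm1 and abs(x[i + m * tau] - x[j + m * tau]) <= r:
                    cm1[i] += 1.0
                    cm1[j] += 1.0
    return cm, cm1


def compute_apen(x, m: int = 2, r: float | None = None, tau: int = 1) -> ApEnResult:
    """Approximate entropy of one series for fixed (m, r, tau).

    ``r`` defaults to 0.2 * sample SD.  Requires at least 10 embedding
    vectors at dimension m + 1 (n - m*tau >= 10): the logarithm of an
    empirical match frequency needs a minimal sample to mean anything.
    """
    arr = _as_series(x)
    n = arr.size
    if m < 1:
        raise ValueError("m must be >= 1")
    if tau < 1:
        raise ValueError("tau must be >= 1")
    if r is None:
        r = tolerance_from_series(arr)
    if r < 0:
        raise ValueError("r must be >= 0")
    if n - m * tau < 10:
        raise InsufficientEmbeddingError(
            f"need n - m*tau >= 10 embedding vectors at dimension m+1; "
            f"n={n}, m={m}, tau={tau} gives {n - m * tau}"
        )
    notes: tuple[str, ...] = ()
    if r == 0.0 and np.var(arr) > 0:
        notes = ("r=0 on a non-constant series: matches are exact equality",)
    cm, cm1 = _match_counts(arr, m, float(r), tau)
    mm = cm.size
    mm1 = cm1.size
    phi_m = float(np.mean(np.log(cm / mm)))
    phi_m1 = float(np.mean(np.log(cm1 / mm1)))
    apen = phi_m - phi_m1
    return ApEnResult(
        apen=apen, m=m, r=float(r), tau=tau, n=n, m_vectors=mm, m1_vectors=mm1,
        notes=notes,
    )


@dataclass(frozen=True)
class SeriesAnalysis:
    """Output of the full single-series chain: delay, entropy, mean angle."""

    tau: TauEstimate
    apen: ApEnResult
    mean_angle: float


def analyze_series(x, config: ApEnConfig = ApEnConfig()) -> SeriesAnalysis:
    """ACF -> delay -> tolerance -> ApEn for one series; plus its mean.

    Raises ConstantSeriesError, TauNotFoundError or InsufficientEmbeddingError
    for series the chain cannot handle; the pipeline treats these as
    per-recording failures, not run failures.
    """
    arr = _as_series(x)
    n = arr.size
    max_shift = max(1, int(math.floor(config.max_shift_fraction * (n - 1))))
    profile = compute_acf(arr, max_shift)
    tau_est = estimate_tau(
        profile, config.acf_threshold, signed=config.signed_threshold
    )
    if not tau_est.found:
        raise TauNotFoundError(
            f"no shift in 1..{max_shift} with |acf| < {config.acf_threshold}"
        )
    r = tolerance_from_series(arr, config.r_factor)
    result = compute_apen(arr, m=config.m, r=r, tau=tau_est.tau)
    return SeriesAnalysis(tau=tau_est, apen=result, mean_angle=float(np.mean(arr)))
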