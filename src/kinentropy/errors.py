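"""Exception types shared across the package.

Per-recording failures (constant channel, no usable delay, series too short
for the requested embedding) are distinct classes so the cohort pipeline can
catch them, log the recording as excluded, and keep going — mirroring how a
study drops an invalid recording without aborting the whole analysis.
"""


class KinentropyError(Exception):
    """Base class for all package errors."""


class ConstantSeriesError(KinentropyError, ValueError):
    """The series has zero variance; autocorrelation and tolerance are undefined."""


class TauNotFoundError(KinentropyError, RuntimeError):
    """No lag within the searched range brings |ACF| under the threshold."""


class InsufficientEmbeddingError(KinentropyError, ValueError):
    """Too few delay-embedding vectors for the requested (m, tau)."""


class FormatError(KinentropyError, ValueError):
    """A recording CSV or manifest violates the documented dialect."""


class CohortError(KinentropyError, RuntimeError):
    """Cohort-level failure, e.g. zero loadable recordings."""
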