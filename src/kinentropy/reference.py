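"""Naive O(M^2) approximate-entropy reference.

A deliberately plain implementation of the same definition as
:func:`kinentropy.entropy.compute_apen`, written directly from the formula:
build the delay-embedding matrix at each dimension, count Chebyshev matches
row by row (self-match included, non-strict ``<=``), average the log match
frequencies.  It shares no code with the optimized kernel and exists so the
two can be checked against each other.
"""

from __future__ import annotations

import numpy as np


def _phi(x: np.ndarray, d: int, r: float, tau: int) -> float:
    n = x.size
    m_vec = n - (d - 1) * tau
    emb = np.empty((m_vec, d))
    for k in range(d):
        emb[:, k] = x[k * tau : k * tau + m_vec]
    log_c = np.empty(m_vec)
    for i in range(m_vec):
        dist = np.max(np.abs(emb - emb[i]), axis=1)
        log_c[i] = np.log(np.count_nonzero(dist <= r) / m_vec)
    return float(np.mean(log_c))


def apen_reference(x, m: int = 2, r: float | None = None, tau: int = 1) -> float:
    """ApEn(m, r, tau) by direct double-loop evaluation of Phi^m - Phi^{m+1}."""
    arr = np.asarray(x, dtype=np.float64)
    if r is None:
        r = 0.2 * float(np.std(arr, ddof=1))
    if arr.size - m * tau < 1:
        raise ValueError("series too short for the requested (m, tau)")
    return _phi(arr, m, r, tau) - _phi(arr, m + 1, r, tau)
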