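"""Independent closed-form / brute-force oracles used only by the tests.

Each function implements its statistic directly from the textbook formula
(or by exhaustive enumeration), sharing no code with the package paths it
checks.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
from scipy.stats import distributions


def welch_oracle(a, b):
    """Welch t statistic, Welch-Satterthwaite df, two-sided p (a vs b)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = a.size, b.size
    va = a.var(ddof=1) / na
    vb = b.var(ddof=1) / nb
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (na - 1) + vb**2 / (nb - 1))
    p = 2.0 * distributions.t.sf(abs(t), df)
    return t, df, p


def pooled_t_oracle(a, b):
    """Classic equal-variance two-sample t statistic."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    return (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))


def anova_oracle(groups):
    """One-way fixed-effects ANOVA by explicit sums of squares."""
    groups = [np.asarray(g, float) for g in groups]
    k = len(groups)
    n = sum(g.size for g in groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1, df2 = k - 1, n - k
    f = (ss_between / df1) / (ss_within / df2)
    p = distributions.f.sf(f, df1, df2)
    return f, (df1, df2), p


def levene_median_oracle(a, b):
    """Brown-Forsythe Levene: one-way ANOVA on |x - group median|."""
    za = np.abs(np.asarray(a, float) - np.median(a))
    zb = np.abs(np.asarray(b, float) - np.median(b))
    f, _, p = anova_oracle([za, zb])
    return f, p


def mannwhitney_u(a, b):
    """U statistic of sample a from the rank-sum definition (midranks)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    combined = np.concatenate([a, b])
    order = np.argsort(combined, kind="mergesort")
    ranks = np.empty(combined.size)
    sorted_vals = combined[order]
    i = 0
    while i < sorted_vals.size:
        j = i
        while j + 1 < sorted_vals.size and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    r_a = ranks[: a.size].sum()
    return r_a - a.size * (a.size + 1) / 2.0


def mannwhitney_exact_oracle(a, b):
    """Two-sided exact Mann-Whitney p by enumerating all group assignments."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    u_obs = mannwhitney_u(a, b)
    na = a.size
    pooled = np.concatenate([a, b])
    n = pooled.size
    mean_u = na * (n - na) / 2.0
    dev_obs = abs(u_obs - mean_u)
    total = 0
    hits = 0
    for idx in combinations(range(n), na):
        mask = np.zeros(n, bool)
        mask[list(idx)] = True
        u = mannwhitney_u(pooled[mask], pooled[~mask])
        total += 1
        if abs(u - mean_u) >= dev_obs - 1e-12:
            hits += 1
    return u_obs, hits / total


def mannwhitney_asymptotic_oracle(a, b):
    """Tie-corrected normal approximation with continuity correction."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = a.size, b.size
    u = mannwhitney_u(a, b)
    mean_u = na * nb / 2.0
    combined = np.concatenate([a, b])
    _, counts = np.unique(combined, return_counts=True)
    n = na + nb
    tie_term = (counts**3 - counts).sum() / (n * (n - 1))
    var_u = na * nb / 12.0 * (n + 1 - tie_term)
    z = (abs(u - mean_u) - 0.5) / math.sqrt(var_u)
    return u, 2.0 * distributions.norm.sf(z)


def acf_oracle(x, max_shift):
    """Shared-denominator sample autocorrelation by direct summation."""
    x = np.asarray(x, float)
    xc = x - x.mean()
    denom = (xc**2).sum()
    return np.array(
        [(xc[: x.size - k] * xc[k:]).sum() / denom for k in range(max_shift + 1)]
    )
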