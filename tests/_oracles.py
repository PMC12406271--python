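"""Independent reference implementations used only to check the package."""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq


def bateman_occupancies(rates, times):
    """Closed-form occupancies of an irreversible chain with distinct rates.

    States 0..n-1 with forward rates ``rates`` (length n-1); the last state is
    absorbing. Classic partial-fraction (Bateman) solution; valid only for
    pairwise-distinct rates.
    """
    rates = np.asarray(rates, dtype=float)
    times = np.asarray(times, dtype=float)
    n = rates.size + 1
    occ = np.zeros((n, times.size))
    for i in range(n - 1):
        prefac = np.prod(rates[:i])
        acc = np.zeros(times.size)
        for j in range(i + 1):
            denom = np.prod([rates[l] - rates[j] for l in range(i + 1) if l != j])
            acc += np.exp(-rates[j] * times) / denom
        occ[i] = prefac * acc
    occ[n - 1] = 1.0 - occ[: n - 1].sum(axis=0)
    return occ


def fraction_bound_numeric(chaperone_total, client_total, kd):
    """Mass-balance root-finding solution of single-site binding."""
    K, L = chaperone_total, client_total
    if L == 0 or K == 0:
        return 0.0

    def g(c):
        return (K - c) * (L - c) - kd * c

    hi = min(K, L)
    if g(hi) > 0:  # numerically exhausted limit
        return hi / K
    c = brentq(g, 0.0, hi, xtol=1e-16, rtol=1e-15)
    return c / K
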