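"""Random-walk Metropolis kernel on log rates for a single feature.

The hot loop is JIT-compiled with numba when available; the pure-Python
fallback is identical. All randomness is pre-drawn with numpy so chains are
bit-identical regardless of the JIT backend.
"""

from __future__ import annotations

import numpy as np


def _rw_chain(g0, xnz, Lnz, sl, topics, deltas, logu, out):
    """Simulate the chain in place.

    g0     : (K,) initial log rates
    xnz    : (nnz,) counts at rows with x > 0 (pseudocount rows included)
    Lnz    : (nnz, K) membership rows for those counts
    sl     : (K,) sum_i s_i l_ik over ALL rows (sparse linear term)
    topics : (ns,) coordinate picked per step
    deltas : (ns,) Gaussian proposal increments
    logu   : (ns,) log of uniform accept draws
    out    : (ns, K) sampled g states, written in place

    Acceptance: log A = sum_nz x log(theta*/theta) - sl_k (p*_k - p_k) + delta,
    the final delta being the log-transform Jacobian log(p*_k / p_k).
    """
    ns = topics.shape[0]
    nnz = xnz.shape[0]
    K = g0.shape[0]
    g = g0.copy()
    p = np.exp(g)
    theta = np.zeros(nnz)
    for i in range(nnz):
        acc = 0.0
        for k in range(K):
            acc += Lnz[i, k] * p[k]
        theta[i] = acc
    for t in range(ns):
        k = topics[t]
        d = deltas[t]
        p_new = np.exp(g[k] + d)
        dp = p_new - p[k]
        loga = d - sl[k] * dp
        ok = True
        for i in range(nnz):
            lik = Lnz[i, k]
            if lik != 0.0:
                tn = theta[i] + lik * dp
                if tn <= 0.0:
                    ok = False
                    break
                loga += xnz[i] * np.log(tn / theta[i])
        if ok and logu[t] <= min(0.0, loga):
            for i in range(nnz):
                lik = Lnz[i, k]
                if lik != 0.0:
                    theta[i] += lik * dp
            p[k] = p_new
            g[k] = g[k] + d
        for k2 in range(K):
            out[t, k2] = g[k2]


try:  # pragma: no cover - exercised implicitly
    from numba import njit

    rw_chain = njit(cache=True)(_rw_chain)
except Exception:  # pragma: no cover
    rw_chain = _rw_chain
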