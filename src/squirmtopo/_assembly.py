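"""Numba-accelerated kernel aggregation for the free-space Stokeslet.

The mobility assembly spends nearly all its time forming

    Kagg[n', n] = sum_q S^eps(x[n'], x_q) nu[q, n] dA[q],

a (N, 3, N, 3) array.  The jitted routine accumulates fine-node
contributions directly into the aggregated blocks, avoiding the
(N, Q, 3, 3) intermediate; a pure-numpy fallback keeps the package
importable without numba.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly by which path runs
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f

        return deco if not (args and callable(args[0])) else args[0]


@njit(cache=True, fastmath=False)
def _stokeslet_aggregate_nb(Xc, Yf, w, nn, eps, out):  # pragma: no cover
    N = Xc.shape[0]
    Q = Yf.shape[0]
    e2 = eps * eps
    for a in range(N):
        xa0 = Xc[a, 0]
        xa1 = Xc[a, 1]
        xa2 = Xc[a, 2]
        for q in range(Q):
            r0 = xa0 - Yf[q, 0]
            r1 = xa1 - Yf[q, 1]
            r2v = xa2 - Yf[q, 2]
            r2 = r0 * r0 + r1 * r1 + r2v * r2v
            inv = 1.0 / (r2 + e2)
            s3 = w[q] * inv * np.sqrt(inv)
            diag = (r2 + 2.0 * e2) * s3
            n = nn[q]
            out[a, 0, n, 0] += diag + r0 * r0 * s3
            out[a, 1, n, 1] += diag + r1 * r1 * s3
            out[a, 2, n, 2] += diag + r2v * r2v * s3
            v01 = r0 * r1 * s3
            v02 = r0 * r2v * s3
            v12 = r1 * r2v * s3
            out[a, 0, n, 1] += v01
            out[a, 1, n, 0] += v01
            out[a, 0, n, 2] += v02
            out[a, 2, n, 0] += v02
            out[a, 1, n, 2] += v12
            out[a, 2, n, 1] += v12


def stokeslet_aggregate(Xc, Yf, weights, nn, eps: float) -> np.ndarray:
    """Aggregated quadrature blocks, shape (N, 3, N, 3)."""
    N = Xc.shape[0]
    out = np.zeros((N, 3, N, 3))
    _stokeslet_aggregate_nb(
        np.ascontiguousarray(Xc),
        np.ascontiguousarray(Yf),
        np.ascontiguousarray(weights),
        np.ascontiguousarray(nn),
        float(eps),
        out,
    )
    return out


if not HAVE_NUMBA:  # numpy fallback: chunked to bound memory

    def stokeslet_aggregate(Xc, Yf, weights, nn, eps):  # noqa: F811
        from .kernels import stokeslet_matrix

        N = Xc.shape[0]
        out = np.zeros((N, 3, N, 3))
        order = np.argsort(nn, kind="stable")
        bounds = np.searchsorted(nn[order], np.arange(N))
        K = stokeslet_matrix(Xc, Yf[order], eps, weights=np.asarray(weights)[order])
        agg = np.add.reduceat(K, bounds, axis=1)  # (N, N, 3, 3)
        return agg.transpose(0, 2, 1, 3)
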