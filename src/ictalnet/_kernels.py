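"""im2col / col2im inner loops.

The JIT-compiled versions copy contiguous ``kernel * channels`` runs per
output position and are memory-bandwidth bound; the NumPy fallback uses
strided slice assignment and is several times slower but always available.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    @njit(cache=True)
    def _im2col_jit(xp, cols, s):  # (B, Lp, C) -> (B, l_out, k, C)
        B, l_out, k, C = cols.shape
        for b in range(B):
            for t in range(l_out):
                base = t * s
                for j in range(k):
                    for c in range(C):
                        cols[b, t, j, c] = xp[b, base + j, c]

    @njit(cache=True)
    def _col2im_jit(dcols, dxp, s):  # scatter-add transpose of _im2col_jit
        B, l_out, k, C = dcols.shape
        for b in range(B):
            for t in range(l_out):
                base = t * s
                for j in range(k):
                    for c in range(C):
                        dxp[b, base + j, c] += dcols[b, t, j, c]

    @njit(cache=True)
    def _bn_stats_jit(x2):  # (N, C) -> per-channel (sum, sum of squares)
        N, C = x2.shape
        acc = np.zeros(C, dtype=np.float64)
        acc2 = np.zeros(C, dtype=np.float64)
        for i in range(N):
            for c in range(C):
                v = x2[i, c]
                acc[c] += v
                acc2[c] += v * v
        return acc, acc2

    @njit(cache=True)
    def _bn_fwd_jit(x2, mu, inv_std, gamma, beta, xhat2, y2):
        N, C = x2.shape
        for i in range(N):
            for c in range(C):
                h = (x2[i, c] - mu[c]) * inv_std[c]
                xhat2[i, c] = h
                y2[i, c] = gamma[c] * h + beta[c]

    @njit(cache=True)
    def _bn_bwd_reduce_jit(dy2, xhat2):  # -> (dbeta, dgamma) float64
        N, C = dy2.shape
        dbeta = np.zeros(C, dtype=np.float64)
        dgamma = np.zeros(C, dtype=np.float64)
        for i in range(N):
            for c in range(C):
                d = dy2[i, c]
                dbeta[c] += d
                dgamma[c] += d * xhat2[i, c]
        return dbeta, dgamma

    @njit(cache=True)
    def _bn_bwd_dx_jit(dy2, xhat2, gamma, inv_std, m1, m2, dx2):
        N, C = dy2.shape
        for i in range(N):
            for c in range(C):
                dxhat = dy2[i, c] * gamma[c]
                dx2[i, c] = inv_std[c] * (dxhat - m1[c] - xhat2[i, c] * m2[c])

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False


def im2col(xp: np.ndarray, cols: np.ndarray, stride: int) -> None:
    if HAVE_NUMBA:
        _im2col_jit(xp, cols, stride)
        return
    _, l_out, k, _ = cols.shape
    span = stride * (l_out - 1) + 1
    for j in range(k):
        cols[:, :, j, :] = xp[:, j : j + span : stride, :]


def col2im(dcols: np.ndarray, dxp: np.ndarray, stride: int) -> None:
    if HAVE_NUMBA:
        _col2im_jit(dcols, dxp, stride)
        return
    _, l_out, k, _ = dcols.shape
    span = stride * (l_out - 1) + 1
    for j in range(k):
        dxp[:, j : j + span : stride, :] += dcols[:, :, j, :]


def bn_stats(x2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel sum and sum-of-squares of a (N, C) view, float64."""
    if HAVE_NUMBA:
        return _bn_stats_jit(x2)
    xd = x2.astype(np.float64)
    return xd.sum(axis=0), (xd * xd).sum(axis=0)


def bn_forward(x2, mu, inv_std, gamma, beta, xhat2, y2) -> None:
    if HAVE_NUMBA:
        _bn_fwd_jit(x2, mu, inv_std, gamma, beta, xhat2, y2)
        return
    np.multiply(x2 - mu, inv_std, out=xhat2)
    np.multiply(xhat2, gamma, out=y2)
    y2 += beta


def bn_backward_reduce(dy2, xhat2) -> tuple[np.ndarray, np.ndarray]:
    if HAVE_NUMBA:
        return _bn_bwd_reduce_jit(dy2, xhat2)
    dyd = dy2.astype(np.float64)
    return dyd.sum(axis=0), (dyd * xhat2).sum(axis=0)


def bn_backward_dx(dy2, xhat2, gamma, inv_std, m1, m2, dx2) -> None:
    if HAVE_NUMBA:
        _bn_bwd_dx_jit(dy2, xhat2, gamma, inv_std, m1, m2, dx2)
        return
    dxhat = dy2 * gamma
    np.multiply(inv_std, dxhat - m1 - xhat2 * m2, out=dx2)
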