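"""Fused single-pass kernels for the training hot path.

The training loop is memory-bandwidth bound on large activations, so
the elementwise pieces (Leaky ReLU forward/backward, the SGD-momentum
update, max pooling) are implemented as fused numba loops; each does a
single pass over its operands.  Pure-NumPy fallbacks keep the package
importable without a JIT; numerical behavior is identical either way
and the public operations in :mod:`gsfan.layers` / :mod:`gsfan.model`
remain the reference implementations the tests exercise.
"""

from __future__ import annotations

import numpy as np

try:
    import numba as _nb

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    _HAVE_NUMBA = False


if _HAVE_NUMBA:

    @_nb.njit(cache=True)
    def _leaky_fwd(flat, slope):
        out = np.empty_like(flat)
        for i in range(flat.size):
            v = flat[i]
            out[i] = v if v > 0 else slope * v
        return out

    @_nb.njit(cache=True)
    def _leaky_bwd_inplace(dflat, xflat, slope):
        for i in range(xflat.size):
            if xflat[i] <= 0:
                dflat[i] *= slope

    @_nb.njit(cache=True)
    def _sgd_inplace(p, v, g, lr, mom):
        for i in range(p.size):
            v[i] = mom * v[i] - lr * g[i]
            p[i] += v[i]

    @_nb.njit(cache=True)
    def _maxpool(P):
        B, N, T = P.shape
        z = np.empty((B, T), dtype=P.dtype)
        idx = np.empty((B, T), dtype=np.int64)
        for b in range(B):
            for t in range(T):
                z[b, t] = P[b, 0, t]
                idx[b, t] = 0
            for n in range(1, N):
                for t in range(T):
                    v = P[b, n, t]
                    if v > z[b, t]:
                        z[b, t] = v
                        idx[b, t] = n
        return z, idx


def leaky(x: np.ndarray, slope: float) -> np.ndarray:
    """Leaky ReLU preserving dtype and shape."""
    if _HAVE_NUMBA and x.dtype.kind == "f":
        flat = np.ascontiguousarray(x).ravel()
        return _leaky_fwd(flat, x.dtype.type(slope)).reshape(x.shape)
    return np.maximum(x, x * slope)


def leaky_bwd(dout: np.ndarray, x: np.ndarray, slope: float) -> np.ndarray:
    """In-place dout *= leaky'(x); dout must be a contiguous owned buffer."""
    if _HAVE_NUMBA and dout.flags.c_contiguous and x.flags.c_contiguous:
        _leaky_bwd_inplace(dout.ravel(), x.ravel(), dout.dtype.type(slope))
        return dout
    np.multiply(dout, dout.dtype.type(slope), where=(x <= 0), out=dout)
    return dout


def sgd_update(params: dict, velocity: dict, grads: dict, lr: float, momentum: float):
    """In-place momentum update over dicts of parameter arrays."""
    for key, p in params.items():
        v, g = velocity[key], grads[key]
        if _HAVE_NUMBA and p.flags.c_contiguous:
            _sgd_inplace(p.ravel(), v.ravel(),
                         np.ascontiguousarray(g, dtype=p.dtype).ravel(),
                         p.dtype.type(lr), p.dtype.type(momentum))
        else:
            v *= momentum
            v -= lr * g.astype(p.dtype, copy=False)
            p += v


def maxpool(P: np.ndarray):
    """Max over axis 1 of (B, N, T); returns (values, argmax indices)."""
    if _HAVE_NUMBA and P.flags.c_contiguous:
        return _maxpool(P)
    idx = P.argmax(axis=1)
    z = np.take_along_axis(P, idx[:, None, :], axis=1)[:, 0, :]
    return z, idx
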