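"""Dimension abstraction: shared-MLP lifting plus a gated nonlinear transform.

Per-point features are lifted to a target embedding dimension by fully
connected layers whose weights are shared across points (so every
operation here is row-permutation equivariant), followed by a gated
transform

    z_tilde = V . ( sigma(z) (*) tanh(W2 . z + beta) ) + gamma

where ``(*)`` is the elementwise product: the activated signal path
sigma(z) is modulated by a tanh gate, then linearly mixed and offset by
learnable gamma.  Because tanh(0) = 0, a zero input with zero beta and
gamma maps exactly to zero, and the output is bounded by
||V|| * max|sigma(z)| + ||gamma|| for bounded inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import DEFAULT_LEAKY_SLOPE, leaky_relu

__all__ = [
    "MLPLayerParams",
    "GatedParams",
    "mlp_layer",
    "gated_transform",
    "ladder_widths",
    "init_ladder_params",
    "dimension_ladder",
    "he_uniform",
]


def he_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int,
               dtype=np.float64) -> np.ndarray:
    """Scaled uniform fan-in initialization: U(+/- sqrt(6 / fan_in))."""
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


@dataclass
class MLPLayerParams:
    """One shared fully connected layer: W (D_out, D_in) and bias (D_out,)."""

    W: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W)
        self.b = np.asarray(self.b)
        if self.W.ndim != 2 or self.b.ndim != 1 or self.W.shape[0] != self.b.shape[0]:
            raise ValueError("W must be (D_out, D_in) and b (D_out,)")
        if not (np.all(np.isfinite(self.W)) and np.all(np.isfinite(self.b))):
            raise ValueError("parameters must be finite")


@dataclass
class GatedParams:
    """Parameters of the gated transform: V, W2 (square), beta, gamma."""

    V: np.ndarray
    W2: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray

    def __post_init__(self) -> None:
        self.V = np.asarray(self.V)
        self.W2 = np.asarray(self.W2)
        self.beta = np.asarray(self.beta)
        self.gamma = np.asarray(self.gamma)
        if self.W2.shape[0] != self.beta.shape[0]:
            raise ValueError("W2 row dim must equal beta dim")
        if self.V.shape[1] != self.W2.shape[0]:
            raise ValueError("V column dim must equal W2 row dim")
        if self.V.shape[0] != self.gamma.shape[0]:
            raise ValueError("V row dim must equal gamma dim")


def mlp_layer(H_prev: np.ndarray, params: MLPLayerParams, act=leaky_relu) -> np.ndarray:
    """Shared fully connected layer: row i -> act(W @ row_i + b)."""
    H_prev = np.asarray(H_prev)
    single = H_prev.ndim == 1
    H = H_prev[None, :] if single else H_prev
    if H.shape[1] != params.W.shape[1]:
        raise ValueError(
            f"layer expects D_in={params.W.shape[1]}, features have D={H.shape[1]}"
        )
    out = act(H @ params.W.T + params.b)
    return out[0] if single else out


def gated_transform(z: np.ndarray, params: GatedParams, act=leaky_relu) -> np.ndarray:
    """Gated nonlinear transform applied to a vector or to each matrix row."""
    z = np.asarray(z)
    single = z.ndim == 1
    Z = z[None, :] if single else z
    if Z.shape[1] != params.W2.shape[1]:
        raise ValueError(
            f"gated transform expects dim {params.W2.shape[1]}, got {Z.shape[1]}"
        )
    gate = np.tanh(Z @ params.W2.T + params.beta)
    out = (act(Z) * gate) @ params.V.T + params.gamma
    return out[0] if single else out


def ladder_widths(d_in: int, target_dim: int, hidden_dim: int = 64) -> list[int]:
    """Stage widths of the dimension ladder: one shared hidden stage, then
    a projection to the target embedding dimension."""
    if target_dim < 1:
        raise ValueError("target_dim must be >= 1")
    if target_dim == hidden_dim:
        return [hidden_dim]
    return [hidden_dim, target_dim]


def init_ladder_params(d_in: int, target_dim: int, rng: np.random.Generator,
                       hidden_dim: int = 64, dtype=np.float64):
    """Initialize MLP stages plus the top gated transform."""
    widths = ladder_widths(d_in, target_dim, hidden_dim)
    stages = []
    prev = d_in
    for w in widths:
        stages.append(
            MLPLayerParams(
                W=he_uniform(rng, (w, prev), prev, dtype),
                b=np.zeros(w, dtype=dtype),
            )
        )
        prev = w
    gate = GatedParams(
        V=he_uniform(rng, (target_dim, target_dim), target_dim, dtype),
        W2=he_uniform(rng, (target_dim, target_dim), target_dim, dtype),
        beta=np.zeros(target_dim, dtype=dtype),
        gamma=np.zeros(target_dim, dtype=dtype),
    )
    return stages, gate


def dimension_ladder(
    features: np.ndarray,
    target_dim: int,
    stages: list[MLPLayerParams] | None = None,
    gate: GatedParams | None = None,
    act=leaky_relu,
    rng: np.random.Generator | None = None,
    hidden_dim: int = 64,
) -> np.ndarray:
    """Lift (N, D_in) per-point features to (N, target_dim).

    Composes shared-MLP stages ending at ``target_dim`` and applies the
    gated transform once at the top, per point.  If parameters are not
    supplied they are initialized from ``rng``.
    """
    features = np.asarray(features)
    if features.ndim != 2:
        raise ValueError("features must be (N, D_in)")
    if stages is None or gate is None:
        rng = rng if rng is not None else np.random.default_rng(0)
        stages, gate = init_ladder_params(features.shape[1], target_dim, rng, hidden_dim)
    H = features
    for stage in stages:
        H = mlp_layer(H, stage, act)
    if H.shape[1] != target_dim:
        raise ValueError("ladder stages do not end at target_dim")
    return gated_transform(H, gate, act)
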