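"""The gesture surface feature analysis network (GSFAN) classifier.

Architecture, per cloud of N points:

1. normalize the cloud (centroid to origin, max norm 1),
2. a stack of edge-convolution layers over the spatial kNN graph
   (mean aggregation with an explicit self-loop, shared linear mix,
   Leaky ReLU),
3. per-point dimension abstraction: shared-MLP stages lifting the final
   edge-conv features (optionally the concatenation of all layers) to
   the target embedding dimension,
4. symmetric global pooling over points (max by default), which makes
   the model invariant to any permutation of the input points,
5. the gated nonlinear transform on the pooled descriptor (a per-point
   placement before pooling is available via ``gate_location``),
6. dropout (training only) and a linear classifier head.

Training is plain minibatch SGD with momentum and cross-entropy loss.
Everything is NumPy with hand-written backpropagation; all gradients are
checked against scalar-loop/numerical oracles in the test suite.  All
randomness (init, shuffling, dropout) flows from one seeded Generator,
so runs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .abstraction import he_uniform, ladder_widths
from .io import normalize_cloud
from . import _kernels as _k
from .layers import aggregation_matrix
from .hand import LabeledCloud

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "GSFANClassifier",
    "init_params",
    "forward",
    "backward",
    "cross_entropy_loss",
    "sgd_momentum_step",
    "train",
    "predict",
    "save_model",
    "load_model",
]


@dataclass
class ModelConfig:
    """Architecture hyperparameters."""

    n_edgeconv_layers: int = 3
    k: int = 8
    edgeconv_dims: tuple[int, ...] | None = None
    target_dim: int = 128
    hidden_dim: int = 64
    dropout_rate: float = 0.5
    leaky_slope: float = 0.2
    n_classes: int = 32
    dynamic_graph: bool = False
    concat_layers: bool = True
    pool: str = "max"
    gate_location: str = "global"

    def __post_init__(self) -> None:
        if self.n_edgeconv_layers < 1:
            raise ValueError("need at least one edge-convolution layer")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.pool not in ("max", "mean"):
            raise ValueError("pool must be 'max' or 'mean'")
        if self.gate_location not in ("global", "per_point"):
            raise ValueError("gate_location must be 'global' or 'per_point'")
        if self.edgeconv_dims is None:
            self.edgeconv_dims = tuple([64] * self.n_edgeconv_layers)
        else:
            self.edgeconv_dims = tuple(int(d) for d in self.edgeconv_dims)
            if len(self.edgeconv_dims) != self.n_edgeconv_layers:
                raise ValueError("edgeconv_dims length must equal n_edgeconv_layers")

    @property
    def concat_dim(self) -> int:
        return sum(self.edgeconv_dims) if self.concat_layers else self.edgeconv_dims[-1]


@dataclass
class TrainConfig:
    """Optimization hyperparameters (SGD with momentum, cross-entropy)."""

    learning_rate: float = 1e-3
    batch_size: int = 32
    momentum: float = 0.9
    epochs: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError("momentum must lie in [0, 1)")


_DTYPE = np.float32


def init_params(config: ModelConfig, rng: np.random.Generator,
                d_in: int = 3) -> dict[str, np.ndarray]:
    """Scaled-uniform fan-in initialization of all learnable tensors."""
    params: dict[str, np.ndarray] = {}
    prev = d_in
    for l, d_out in enumerate(config.edgeconv_dims):
        params[f"ec_W_{l}"] = he_uniform(rng, (d_out, prev), prev, _DTYPE)
        prev = d_out
    widths = ladder_widths(config.concat_dim, config.target_dim, config.hidden_dim)
    prev = config.concat_dim
    for s, w in enumerate(widths):
        params[f"mlp_{s}_W"] = he_uniform(rng, (w, prev), prev, _DTYPE)
        params[f"mlp_{s}_b"] = np.zeros(w, dtype=_DTYPE)
        prev = w
    t = config.target_dim
    params["g_V"] = he_uniform(rng, (t, t), t, _DTYPE)
    params["g_W2"] = he_uniform(rng, (t, t), t, _DTYPE)
    params["g_beta"] = np.zeros(t, dtype=_DTYPE)
    params["g_gamma"] = np.zeros(t, dtype=_DTYPE)
    params["head_W"] = he_uniform(rng, (config.n_classes, t), t, _DTYPE)
    params["head_b"] = np.zeros(config.n_classes, dtype=_DTYPE)
    return params


def _n_ladder_stages(params: dict) -> int:
    s = 0
    while f"mlp_{s}_W" in params:
        s += 1
    return s


def _gate_forward(Z, params, slope):
    G = _k.leaky(Z, slope)
    T = np.tanh(Z @ params["g_W2"].T + params["g_beta"])
    U = (G * T).astype(_DTYPE, copy=False)
    out = U @ params["g_V"].T + params["g_gamma"]
    return out, (Z, G, T, U)


def _gate_backward(dout, cache, params, slope, grads):
    Z, G, T, U = cache
    dU = dout @ params["g_V"]
    grads["g_V"] = dout.T @ U
    grads["g_gamma"] = dout.sum(axis=0)
    dG = dU * T
    dT = dU * G
    dpre = dT * (1.0 - T * T)
    grads["g_W2"] = dpre.T @ Z
    grads["g_beta"] = dpre.sum(axis=0)
    dZ = _k.leaky_bwd(dG, Z, slope) + dpre @ params["g_W2"]
    return dZ.astype(_DTYPE, copy=False)


def forward(coords, agg_mats, params, config: ModelConfig,
            train_mode: bool = False, rng: np.random.Generator | None = None):
    """Forward pass on a batch of equal-size clouds.

    ``coords`` is (B, N, 3) already normalized; ``agg_mats`` is a list of
    B sparse row-stochastic aggregation matrices (self-loop mean).
    Returns (scores (B, n_classes), cache for :func:`backward`).
    """
    X = np.ascontiguousarray(coords, dtype=_DTYPE)
    B, N, _ = X.shape
    slope = config.leaky_slope
    layer_in = X
    ec_cache = []
    outputs = []
    # (B, N, N) stack of dense row-stochastic aggregation matrices
    graphs_used = np.stack([np.asarray(m.todense() if hasattr(m, "todense") else m,
                                       dtype=_DTYPE) for m in agg_mats])
    for l in range(config.n_edgeconv_layers):
        if config.dynamic_graph and l > 0:
            graphs_used = np.stack(
                [_feature_agg(outputs[-1][b], config.k) for b in range(B)]
            )
        Agg = graphs_used @ layer_in
        W = params[f"ec_W_{l}"]
        Z = Agg.reshape(B * N, -1) @ W.T
        out = _k.leaky(Z, slope)
        ec_cache.append((layer_in, Agg, Z, graphs_used))
        layer_in = out.reshape(B, N, -1)
        outputs.append(layer_in)
    F = np.concatenate(outputs, axis=2) if config.concat_layers else outputs[-1]
    H = F.reshape(B * N, -1)
    mlp_cache = []
    for s in range(_n_ladder_stages(params)):
        A = H @ params[f"mlp_{s}_W"].T + params[f"mlp_{s}_b"]
        mlp_cache.append((H, A))
        H = _k.leaky(A, slope)
    gate_cache = None
    if config.gate_location == "per_point":
        H, gate_cache = _gate_forward(H, params, slope)
    P = H.reshape(B, N, -1)
    if config.pool == "max":
        z, amax = _k.maxpool(np.ascontiguousarray(P))
    else:
        amax = None
        z = P.mean(axis=1)
    if config.gate_location == "global":
        zt, gate_cache = _gate_forward(z, params, slope)
    else:
        zt = z
    if train_mode and config.dropout_rate > 0:
        if rng is None:
            raise ValueError("training-mode forward needs an rng for dropout")
        keep = 1.0 - config.dropout_rate
        mask = (rng.random(zt.shape) < keep).astype(_DTYPE) / keep
    else:
        mask = None
    zd = zt * mask if mask is not None else zt
    scores = zd @ params["head_W"].T + params["head_b"]
    cache = dict(
        B=B, N=N, ec=ec_cache, F_shape=F.shape, mlp=mlp_cache,
        gate=gate_cache, amax=amax, z=z, zt=zt, mask=mask, zd=zd,
        outputs_dims=[o.shape[2] for o in outputs],
    )
    return scores.astype(_DTYPE, copy=False), cache


def _feature_agg(features, k):
    """Dense aggregation matrix of a feature-space kNN graph (dynamic mode)."""
    from .layers import _feature_knn

    M = aggregation_matrix(_feature_knn(np.asarray(features, float), k), dtype=_DTYPE)
    return np.asarray(M.todense(), dtype=_DTYPE)


def backward(dscores, cache, params, config: ModelConfig) -> dict[str, np.ndarray]:
    """Gradients of the batch loss with respect to every parameter."""
    grads: dict[str, np.ndarray] = {}
    slope = config.leaky_slope
    B, N = cache["B"], cache["N"]
    dzd = dscores.astype(_DTYPE, copy=False)
    grads["head_W"] = dzd.T @ cache["zd"]
    grads["head_b"] = dzd.sum(axis=0)
    dzt = dzd @ params["head_W"]
    if cache["mask"] is not None:
        dzt = dzt * cache["mask"]
    if config.gate_location == "global":
        dz = _gate_backward(dzt, cache["gate"], params, slope, grads)
    else:
        dz = dzt
    t = dz.shape[1]
    if config.pool == "max":
        dP = np.zeros((B, N, t), dtype=_DTYPE)
        np.put_along_axis(dP, cache["amax"][:, None, :], dz[:, None, :], axis=1)
    else:
        dP = np.broadcast_to(dz[:, None, :] / N, (B, N, t)).astype(_DTYPE)
    dH = dP.reshape(B * N, t)
    if config.gate_location == "per_point":
        dH = _gate_backward(dH, cache["gate"], params, slope, grads)
    for s in range(len(cache["mlp"]) - 1, -1, -1):
        H_in, A = cache["mlp"][s]
        dA = _k.leaky_bwd(np.ascontiguousarray(dH), A, slope)
        grads[f"mlp_{s}_W"] = dA.T @ H_in
        grads[f"mlp_{s}_b"] = dA.sum(axis=0)
        dH = dA @ params[f"mlp_{s}_W"]
    dF = dH.reshape(cache["F_shape"])
    dims = cache["outputs_dims"]
    if config.concat_layers:
        splits = np.cumsum(dims)[:-1]
        dlayer_outputs = np.split(dF, splits, axis=2)
    else:
        dlayer_outputs = [None] * (len(dims) - 1) + [dF]
    dnext_in = None
    for l in range(config.n_edgeconv_layers - 1, -1, -1):
        layer_in, Agg, Z, graphs_used = cache["ec"][l]
        dout = dlayer_outputs[l]
        if dout is None:
            dout = np.zeros((B, N, dims[l]), dtype=_DTYPE)
        dout = np.ascontiguousarray(dout)
        if dnext_in is not None:
            dout = dout + dnext_in
        dZ = _k.leaky_bwd(np.ascontiguousarray(dout.reshape(B * N, -1)), Z, slope)
        W = params[f"ec_W_{l}"]
        grads[f"ec_W_{l}"] = dZ.T @ Agg.reshape(B * N, -1)
        dAgg = (dZ @ W).reshape(B, N, -1)
        dnext_in = graphs_used.transpose(0, 2, 1) @ dAgg
    return grads


def cross_entropy_loss(scores, labels):
    """Mean negative log softmax probability of the true class.

    Returns ``(loss, dscores)`` where ``dscores`` is the gradient of the
    mean loss with respect to the scores.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        scores = scores[None, :]
    labels = np.atleast_1d(np.asarray(labels, dtype=int))
    n, c = scores.shape
    if labels.shape[0] != n:
        raise ValueError("labels length must match scores rows")
    if labels.min() < 0 or labels.max() >= c:
        raise ValueError(f"labels must lie in [0, {c})")
    shifted = scores - scores.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(shifted).sum(axis=1))
    logp = shifted[np.arange(n), labels] - logsumexp
    loss = float(-logp.mean())
    probs = np.exp(shifted - logsumexp[:, None])
    dscores = probs
    dscores[np.arange(n), labels] -= 1.0
    dscores /= n
    return loss, dscores


def sgd_momentum_step(params, grads, velocity, lr: float, momentum: float):
    """One SGD-with-momentum update: v' = m v - lr g;  p' = p + v'.

    Accepts single arrays or dicts of arrays; returns (params', velocity').
    """
    if isinstance(params, dict):
        new_p, new_v = {}, {}
        for key in params:
            new_p[key], new_v[key] = sgd_momentum_step(
                params[key], grads[key], velocity[key], lr, momentum
            )
        return new_p, new_v
    params = np.asarray(params)
    grads = np.asarray(grads)
    velocity = np.asarray(velocity)
    if params.shape != grads.shape or params.shape != velocity.shape:
        raise ValueError("params, grads and velocity must share a shape")
    v_new = momentum * velocity - lr * grads
    return params + v_new, v_new


# ---------------------------------------------------------------------------
# estimator


class GSFANClassifier(BaseEstimator, ClassifierMixin):
    """Point-cloud gesture classifier with a scikit-learn interface.

    ``X`` is a sequence of (N, 3) arrays (or one (n_clouds, N, 3) array) of
    raw coordinates; each cloud is normalized internally.  ``y`` holds the
    gesture class ids.  In evaluation mode predictions are invariant to
    permutations of each cloud's points.

    Parameters mirror :class:`ModelConfig` and :class:`TrainConfig`; fitted
    state lives in ``params_`` (all learnable tensors), ``history_`` (per-
    epoch loss/accuracy) and ``classes_``.
    """

    def __init__(
        self,
        n_edgeconv_layers: int = 3,
        k: int = 8,
        edgeconv_dims=None,
        target_dim: int = 128,
        hidden_dim: int = 64,
        dropout_rate: float = 0.5,
        leaky_slope: float = 0.2,
        dynamic_graph: bool = False,
        concat_layers: bool = True,
        pool: str = "max",
        gate_location: str = "global",
        learning_rate: float = 1e-3,
        batch_size: int = 32,
        momentum: float = 0.9,
        epochs: int = 100,
        random_state: int = 0,
    ):
        self.n_edgeconv_layers = n_edgeconv_layers
        self.k = k
        self.edgeconv_dims = edgeconv_dims
        self.target_dim = target_dim
        self.hidden_dim = hidden_dim
        self.dropout_rate = dropout_rate
        self.leaky_slope = leaky_slope
        self.dynamic_graph = dynamic_graph
        self.concat_layers = concat_layers
        self.pool = pool
        self.gate_location = gate_location
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.momentum = momentum
        self.epochs = epochs
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _model_config(self, n_classes: int) -> ModelConfig:
        return ModelConfig(
            n_edgeconv_layers=self.n_edgeconv_layers,
            k=self.k,
            edgeconv_dims=self.edgeconv_dims,
            target_dim=self.target_dim,
            hidden_dim=self.hidden_dim,
            dropout_rate=self.dropout_rate,
            leaky_slope=self.leaky_slope,
            n_classes=n_classes,
            dynamic_graph=self.dynamic_graph,
            concat_layers=self.concat_layers,
            pool=self.pool,
            gate_location=self.gate_location,
        )

    @staticmethod
    def _as_cloud_list(X):
        if isinstance(X, np.ndarray) and X.ndim == 3:
            return [X[i] for i in range(X.shape[0])]
        clouds = []
        for item in X:
            c = item.coords if isinstance(item, LabeledCloud) else np.asarray(item)
            if c.ndim != 2 or c.shape[1] != 3:
                raise ValueError("each cloud must be an (N, 3) array")
            clouds.append(c)
        return clouds

    def _preprocess(self, X):
        """Normalize clouds and build per-cloud aggregation matrices."""
        from scipy.spatial.distance import cdist

        clouds = self._as_cloud_list(X)
        k = self.k
        prepped = []
        for c in clouds:
            n = c.shape[0]
            if n <= k:
                raise ValueError(
                    f"cloud with {n} points: need more than k={self.k} points"
                )
            norm = normalize_cloud(c).astype(_DTYPE)
            # fast inline kNN aggregation matrix (same (distance, index)
            # tie-break as graph.knn_neighbors, validated against it in tests)
            D = cdist(norm, norm)
            np.fill_diagonal(D, np.inf)
            order = np.argsort(D, axis=1, kind="stable")[:, :k]
            M = np.zeros((n, n), dtype=_DTYPE)
            M[np.arange(n)[:, None], np.column_stack([np.arange(n), order])] = (
                1.0 / (k + 1)
            )
            prepped.append((norm, M))
        return prepped

    def _forward_indices(self, prepped, indices, params, config,
                         train_mode=False, rng=None, collect_cache=False):
        """Forward over an index list, grouped by cloud size; returns scores
        in the order of ``indices`` (plus per-group caches if requested)."""
        sizes = {}
        for pos, i in enumerate(indices):
            sizes.setdefault(prepped[i][0].shape[0], []).append(pos)
        scores = np.empty((len(indices), config.n_classes), dtype=_DTYPE)
        caches = []
        for n, positions in sizes.items():
            coords = np.stack([prepped[indices[p]][0] for p in positions])
            mats = [prepped[indices[p]][1] for p in positions]
            s, cache = forward(coords, mats, params, config, train_mode, rng)
            scores[positions] = s
            if collect_cache:
                caches.append((positions, cache))
        return (scores, caches) if collect_cache else scores

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y):
        y = np.asarray(y, dtype=int)
        prepped = self._preprocess(X)
        if len(prepped) == 0:
            raise ValueError("training set is empty")
        if len(prepped) != len(y):
            raise ValueError("X and y length mismatch")
        self.classes_ = np.unique(y)
        class_index = {c: i for i, c in enumerate(self.classes_)}
        y_idx = np.array([class_index[v] for v in y])
        config = self._model_config(len(self.classes_))
        rng = np.random.default_rng(self.random_state)
        params = init_params(config, rng)
        velocity = {k_: np.zeros_like(v) for k_, v in params.items()}
        n = len(prepped)
        history = []
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            epoch_correct = 0
            for start in range(0, n, self.batch_size):
                batch = order[start:start + self.batch_size]
                scores, caches = self._forward_indices(
                    prepped, batch, params, config,
                    train_mode=True, rng=rng, collect_cache=True,
                )
                loss, dscores = cross_entropy_loss(scores, y_idx[batch])
                epoch_loss += loss * len(batch)
                epoch_correct += int((scores.argmax(axis=1) == y_idx[batch]).sum())
                grads = None
                for positions, cache in caches:
                    g = backward(dscores[positions], cache, params, config)
                    if grads is None:
                        grads = g
                    else:
                        for key in grads:
                            grads[key] += g[key]
                _k.sgd_update(params, velocity, grads,
                              self.learning_rate, self.momentum)
            history.append(
                {"epoch": epoch, "loss": epoch_loss / n, "accuracy": epoch_correct / n}
            )
        self.params_ = params
        self.config_ = config
        self.history_ = pd.DataFrame(history)
        return self

    def decision_function(self, X):
        self._check_fitted()
        prepped = self._preprocess(X)
        idx = list(range(len(prepped)))
        out = np.empty((len(idx), self.config_.n_classes), dtype=_DTYPE)
        for start in range(0, len(idx), max(self.batch_size, 1)):
            chunk = idx[start:start + self.batch_size]
            out[chunk] = self._forward_indices(prepped, chunk, self.params_, self.config_)
        return out

    def predict_proba(self, X):
        scores = np.asarray(self.decision_function(X), dtype=float)
        shifted = scores - scores.max(axis=1, keepdims=True)
        e = np.exp(shifted)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, X):
        scores = self.decision_function(X)
        return self.classes_[np.argmax(scores, axis=1)]

    def _check_fitted(self):
        if not hasattr(self, "params_"):
            raise RuntimeError("classifier is not fitted")


# ---------------------------------------------------------------------------
# functional wrappers and persistence


def train(split, model_config: ModelConfig | None = None,
          train_config: TrainConfig | None = None):
    """Fit a :class:`GSFANClassifier` on a :class:`~gsfan.io.DatasetSplit`.

    Returns ``(classifier, history)``; the history is the per-epoch loss and
    training accuracy DataFrame.
    """
    model_config = model_config or ModelConfig()
    train_config = train_config or TrainConfig()
    if not split.train:
        raise ValueError("training set is empty")
    clf = GSFANClassifier(
        n_edgeconv_layers=model_config.n_edgeconv_layers,
        k=model_config.k,
        edgeconv_dims=model_config.edgeconv_dims,
        target_dim=model_config.target_dim,
        hidden_dim=model_config.hidden_dim,
        dropout_rate=model_config.dropout_rate,
        leaky_slope=model_config.leaky_slope,
        dynamic_graph=model_config.dynamic_graph,
        concat_layers=model_config.concat_layers,
        pool=model_config.pool,
        gate_location=model_config.gate_location,
        learning_rate=train_config.learning_rate,
        batch_size=train_config.batch_size,
        momentum=train_config.momentum,
        epochs=train_config.epochs,
        random_state=train_config.seed,
    )
    clf.fit([c.coords for c in split.train], [c.label for c in split.train])
    return clf, clf.history_


def predict(clouds, clf: GSFANClassifier):
    """Predict gesture classes for LabeledClouds or raw coordinate arrays."""
    return clf.predict(clouds)


def save_model(clf: GSFANClassifier, path):
    """Save fitted parameters to an .npz archive with a JSON config sidecar."""
    import json
    from pathlib import Path

    clf._check_fitted()
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    np.savez(path, classes=clf.classes_, **clf.params_)
    sidecar = path.with_suffix(path.suffix + ".json")
    cfg = asdict(clf.config_)
    cfg["estimator"] = clf.get_params()
    with open(sidecar, "w") as fh:
        json.dump(cfg, fh, indent=2, default=lambda o: list(o) if isinstance(o, tuple) else o)


def load_model(path) -> GSFANClassifier:
    import json
    from pathlib import Path

    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    with open(sidecar) as fh:
        cfg = json.load(fh)
    est_params = cfg.pop("estimator")
    if est_params.get("edgeconv_dims") is not None:
        est_params["edgeconv_dims"] = tuple(est_params["edgeconv_dims"])
    clf = GSFANClassifier(**est_params)
    with np.load(path) as archive:
        data = {k_: archive[k_] for k_ in archive.files}
    clf.classes_ = data.pop("classes")
    clf.params_ = data
    clf.config_ = clf._model_config(len(clf.classes_))
    return clf
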