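"""Deep & Cross Network for sparse tabular risk prediction, in NumPy.

The network combines an explicit feature-crossing tower with a standard
feed-forward (deep) tower and a sigmoid head:

* cross layer ``l``:  ``x_{l+1} = x0 * (x_l . w_l) + b_l + x_l``  — each layer
  adds one degree of multiplicative feature interaction at O(d) parameters;
* deep tower: affine + ReLU stack on the raw input;
* head: single affine on the concatenated tower outputs, then a sigmoid.

Selected features enter as a dense numeric d-vector (post-selection they are
binary indicators, so no embedding layer is used).  Parameters live in an
ordered, named, flat-aggregatable collection so federated averaging and
DP-SGD can treat the model as one vector.  The backward pass returns
**per-example** gradients, which per-example clipping in DP-SGD requires.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.special

__all__ = ["DCNConfig", "ModelParams", "init_params", "cross_layer", "forward",
           "forward_proba", "bce_loss", "per_example_gradients"]

_CLAMP = 1e-7


@dataclass(frozen=True)
class DCNConfig:
    """Architecture hyperparameters.

    ``input_dim`` is the number of selected features; two cross layers and a
    [16, 8] deep stack keep the parameter count small.  Under per-example
    gradient clipping (DP-SGD) a small parameter vector matters beyond CPU
    cost: the clip norm C bounds each example's *total* gradient, so fewer
    coordinates mean more signal per coordinate per step.
    """

    input_dim: int
    n_cross_layers: int = 2
    deep_widths: tuple[int, ...] = (16, 8)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_dim < 1:
            raise ValueError("input_dim must be >= 1")
        if self.n_cross_layers < 0:
            raise ValueError("n_cross_layers must be >= 0")
        if any(w <= 0 for w in self.deep_widths):
            raise ValueError("deep widths must be positive")

    def param_shapes(self) -> list[tuple[str, tuple[int, ...]]]:
        d = self.input_dim
        shapes: list[tuple[str, tuple[int, ...]]] = []
        for l in range(self.n_cross_layers):
            shapes.append((f"cross_w{l}", (d,)))
            shapes.append((f"cross_b{l}", (d,)))
        prev = d
        for k, w in enumerate(self.deep_widths):
            shapes.append((f"deep_W{k}", (prev, w)))
            shapes.append((f"deep_b{k}", (w,)))
            prev = w
        head_in = d + (self.deep_widths[-1] if self.deep_widths else d)
        shapes.append(("head_w", (head_in,)))
        shapes.append(("head_b", (1,)))
        return shapes


class ModelParams(dict):
    """Named arrays in the fixed order given by ``DCNConfig.param_shapes``.

    ``flatten``/``unflatten`` form a bijection with R^P, the representation
    exchanged and averaged in federated training.
    """

    def __init__(self, config: DCNConfig, arrays: dict[str, np.ndarray]):
        super().__init__()
        self.config = config
        for name, shape in config.param_shapes():
            a = np.asarray(arrays[name], dtype=np.float64)
            if a.shape != shape:
                raise ValueError(f"{name}: expected shape {shape}, got {a.shape}")
            self[name] = a

    def flatten(self) -> np.ndarray:
        return np.concatenate([self[name].ravel() for name, _ in self.config.param_shapes()])

    @classmethod
    def unflatten(cls, config: DCNConfig, vec: np.ndarray) -> "ModelParams":
        vec = np.asarray(vec, dtype=np.float64)
        arrays = {}
        i = 0
        for name, shape in config.param_shapes():
            size = int(np.prod(shape))
            arrays[name] = vec[i : i + size].reshape(shape)
            i += size
        if i != vec.size:
            raise ValueError(f"vector size {vec.size} != parameter count {i}")
        return cls(config, arrays)

    @property
    def n_params(self) -> int:
        return sum(int(np.prod(s)) for _, s in self.config.param_shapes())

    def copy(self) -> "ModelParams":
        return ModelParams(self.config, {k: v.copy() for k, v in self.items()})


def init_params(config: DCNConfig) -> ModelParams:
    """Glorot-style initialization, deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    arrays: dict[str, np.ndarray] = {}
    for name, shape in config.param_shapes():
        if name.startswith(("cross_b", "deep_b")) or name == "head_b":
            arrays[name] = np.zeros(shape)
        elif name.startswith("cross_w"):
            arrays[name] = rng.normal(0.0, 1.0 / np.sqrt(shape[0]), size=shape)
        elif name.startswith("deep_W"):
            fan_in, fan_out = shape
            lim = np.sqrt(6.0 / (fan_in + fan_out))
            arrays[name] = rng.uniform(-lim, lim, size=shape)
        elif name == "head_w":
            # zero head: the untrained model predicts a constant, so training
            # under clipped (DP) gradients never has to unlearn random signal
            arrays[name] = np.zeros(shape)
        else:  # bias fallthrough
            arrays[name] = np.zeros(shape)
    return ModelParams(config, arrays)


def cross_layer(x0: np.ndarray, x_l: np.ndarray, w_l: np.ndarray, b_l: np.ndarray) -> np.ndarray:
    """One explicit-crossing step: ``x0 * (x_l . w_l) + b_l + x_l``.

    Accepts a single d-vector or a batch of shape (n, d).
    """
    x0 = np.asarray(x0, dtype=float)
    x_l = np.asarray(x_l, dtype=float)
    if x0.shape != x_l.shape or x0.shape[-1] != w_l.shape[0] or w_l.shape != b_l.shape:
        raise ValueError("cross_layer: dimension mismatch")
    s = x_l @ w_l  # scalar per example
    if x0.ndim == 1:
        return x0 * s + b_l + x_l
    return x0 * s[:, None] + b_l + x_l


def _forward_cached(params: ModelParams, X: np.ndarray):
    cfg = params.config
    X = np.atleast_2d(np.asarray(X, dtype=float))
    cache: dict[str, object] = {"X": X}
    # cross tower
    xs = [X]
    ss = []
    for l in range(cfg.n_cross_layers):
        w, b = params[f"cross_w{l}"], params[f"cross_b{l}"]
        s = xs[-1] @ w
        ss.append(s)
        xs.append(X * s[:, None] + b + xs[-1])
    cache["cross_xs"], cache["cross_ss"] = xs, ss
    # deep tower
    hs = [X]
    pres = []
    for k in range(len(cfg.deep_widths)):
        a = hs[-1] @ params[f"deep_W{k}"] + params[f"deep_b{k}"]
        pres.append(a)
        hs.append(np.maximum(a, 0.0))
    cache["deep_hs"], cache["deep_pres"] = hs, pres
    concat = np.concatenate([xs[-1], hs[-1]], axis=1)
    cache["concat"] = concat
    z = concat @ params["head_w"] + params["head_b"][0]
    if not np.all(np.isfinite(z)):
        raise FloatingPointError("non-finite intermediate in forward pass")
    p = scipy.special.expit(z)
    cache["z"], cache["p"] = z, p
    return p, cache


def forward(params: ModelParams, x: np.ndarray) -> np.ndarray:
    """Predicted probability p in (0,1); accepts a d-vector or (n, d) batch."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    p, _ = _forward_cached(params, x)
    return float(p[0]) if single else p


def forward_proba(params: ModelParams, X) -> np.ndarray:
    """Batch probabilities from a dense array or scipy sparse matrix."""
    if hasattr(X, "toarray"):
        X = X.toarray()
    return forward(params, np.asarray(X, dtype=float))


def bce_loss(p: np.ndarray, y: np.ndarray) -> float:
    """Mean binary cross-entropy; probabilities clamped to [1e-7, 1-1e-7]."""
    p = np.clip(np.asarray(p, dtype=float), _CLAMP, 1.0 - _CLAMP)
    y = np.asarray(y, dtype=float)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def per_example_gradients(params: ModelParams, X, y: np.ndarray) -> dict[str, np.ndarray]:
    """Gradient of per-example BCE w.r.t. every parameter.

    Returns arrays with a leading batch axis: shape ``(n,) + param_shape``.
    The per-example loss is the single-example BCE (not divided by n), so
    averaging these gradients over the batch gives the minibatch gradient.
    """
    cfg = params.config
    if hasattr(X, "toarray"):
        X = X.toarray()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    p, cache = _forward_cached(params, X)
    g = p - y  # dBCE/dz per example
    grads: dict[str, np.ndarray] = {}

    concat = cache["concat"]
    grads["head_w"] = g[:, None] * concat
    grads["head_b"] = g[:, None]
    dcat = g[:, None] * params["head_w"][None, :]
    d = cfg.input_dim
    dcross = dcat[:, :d]
    ddeep = dcat[:, d:]

    # deep tower backward
    hs, pres = cache["deep_hs"], cache["deep_pres"]
    delta = ddeep
    for k in reversed(range(len(cfg.deep_widths))):
        delta = delta * (pres[k] > 0)
        grads[f"deep_W{k}"] = np.einsum("ni,nj->nij", hs[k], delta)
        grads[f"deep_b{k}"] = delta
        delta = delta @ params[f"deep_W{k}"].T

    # cross tower backward: x_{l+1} = X * s_l + b_l + x_l, s_l = x_l . w_l
    xs = cache["cross_xs"]
    u = dcross
    for l in reversed(range(cfg.n_cross_layers)):
        w = params[f"cross_w{l}"]
        t = np.einsum("ni,ni->n", u, X)  # dL/ds_l per example
        grads[f"cross_w{l}"] = t[:, None] * xs[l]
        grads[f"cross_b{l}"] = u
        u = u + t[:, None] * w[None, :]
    return grads


def flat_per_example_gradients(params: ModelParams, X, y: np.ndarray) -> np.ndarray:
    """Per-example gradients stacked as an (n, P) matrix in canonical order."""
    grads = per_example_gradients(params, X, y)
    n = next(iter(grads.values())).shape[0]
    return np.concatenate(
        [grads[name].reshape(n, -1) for name, _ in params.config.param_shapes()],
        axis=1,
    )
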