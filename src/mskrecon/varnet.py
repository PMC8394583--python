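"""Unrolled variational-network reconstruction.

The reconstruction is a fixed chain of cascades operating on a complex image
estimate, built from the SENSE operator A (coil sensitivities + centered
unitary FFT + sampling mask):

* **pre-cascades** — data consistency only, with trainable extrapolation:
  ``z = x_k + mu_k (x_k - x_{k-1})`` (Nesterov-style momentum with learned
  scalar ``mu_k``), then a gradient step ``z - t_k A^H (A z - y)`` with
  learned step size ``t_k``.  These stages do the parallel-imaging part of
  the work (recovering missing lines near the k-space center) before any
  learned prior is applied.
* **main cascades** — the same extrapolated data-consistency step followed by
  a residual CNN regularizer on the 2-channel real/imaginary image.
* **post-cascades** — non-trainable unit-step gradient descent on the data
  term.  Because RSS-normalized sensitivities give ``||A|| <= 1``, the
  acquired-line residual is never increased by these steps; they re-anchor
  the output to the measured data regardless of what the CNN did.

The clinical-scale configuration is 6 pre / 12 main / 1 post cascades; the
desk-scale default used throughout this package is 2 / 4 / 1 with a small
two-level regularizer, which trains in minutes on a CPU.

Training minimizes ``alpha * L1 + beta * (1 - MS-SSIM)`` between the
bias-corrected magnitude of the prediction and the ground-truth magnitude,
per item (batch size 1) with Adam.  All gradients are analytic; complex
gradients use the real-pair convention (``dL/dRe + i dL/dIm``), under which
every complex-linear Hermitian operator is its own adjoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import KSpaceData
from .msssim import msssim, msssim_and_grad
from .nn import Adam, ConvRegularizer
from .sampling import SamplingPattern, extract_acs
from .sense import (
    BiasField,
    CoilSensitivities,
    adjoint,
    bias_correct,
    estimate_sensitivities,
    forward,
)

__all__ = [
    "CascadeConfig",
    "UnrolledNetworkParams",
    "ReconResult",
    "dc_gradient",
    "pre_cascade_step",
    "main_cascade_step",
    "post_cascade_step",
    "reconstruct",
    "loss",
    "train",
    "save_params",
    "load_params",
]

#: cascade counts of the clinical-scale network
CLINICAL_SCALE = (6, 12, 1)


@dataclass(frozen=True)
class CascadeConfig:
    """Cascade counts and regularizer size.

    Defaults are the desk-scale configuration (2 pre / 4 main / 1 post,
    two-level regularizer with 8 base channels); the clinical-scale network
    uses ``n_pre=6, n_main=12, n_post=1``.
    """

    n_pre: int = 2
    n_main: int = 4
    n_post: int = 1
    n_levels: int = 2
    base_channels: int = 8
    share_weights: bool = False

    def __post_init__(self):
        if min(self.n_pre, self.n_main, self.n_post) < 0:
            raise ValueError("cascade counts must be >= 0")


@dataclass
class UnrolledNetworkParams:
    """All trainable quantities: per-cascade step sizes ``t`` and momentum
    coefficients ``mu`` for pre and main cascades, and the CNN regularizer
    weights (one per main cascade, or one shared).  Post-cascades have no
    parameters.  ``alpha``/``beta`` are the loss weights used at training."""

    config: CascadeConfig
    t_pre: np.ndarray
    mu_pre: np.ndarray
    t_main: np.ndarray
    mu_main: np.ndarray
    regularizers: list[ConvRegularizer]
    alpha: float = 1.0
    beta: float = 1.0
    g_t_pre: np.ndarray = field(default=None, repr=False)
    g_mu_pre: np.ndarray = field(default=None, repr=False)
    g_t_main: np.ndarray = field(default=None, repr=False)
    g_mu_main: np.ndarray = field(default=None, repr=False)

    @classmethod
    def init(cls, config: CascadeConfig, seed: int = 0,
             alpha: float = 1.0, beta: float = 1.0,
             dtype=np.float64) -> "UnrolledNetworkParams":
        """Initialize with t = 0.5, mu = 0 and zero-output regularizers (the
        output convolutions start at zero, so the fresh chain is exactly a
        linear data-consistency reconstruction).  ``dtype`` sets the CNN
        weight precision (training uses single precision by default)."""
        rng = np.random.default_rng(seed)
        n_reg = 1 if config.share_weights else config.n_main
        regs = [
            ConvRegularizer(config.n_levels, config.base_channels, rng, dtype=dtype)
            for _ in range(n_reg)
        ]
        p = cls(
            config=config,
            t_pre=np.full(config.n_pre, 0.5),
            mu_pre=np.zeros(config.n_pre),
            t_main=np.full(config.n_main, 0.5),
            mu_main=np.zeros(config.n_main),
            regularizers=regs,
            alpha=alpha,
            beta=beta,
        )
        p._alloc_grads()
        return p

    def _alloc_grads(self):
        self.g_t_pre = np.zeros_like(self.t_pre)
        self.g_mu_pre = np.zeros_like(self.mu_pre)
        self.g_t_main = np.zeros_like(self.t_main)
        self.g_mu_main = np.zeros_like(self.mu_main)

    def regularizer(self, k: int) -> ConvRegularizer:
        return self.regularizers[0 if self.config.share_weights else k]

    def zero_regularizers(self) -> "UnrolledNetworkParams":
        """Zero every CNN weight, making the whole chain linear in y."""
        for reg in self.regularizers:
            for layer in reg.layers():
                layer.W[...] = 0.0
                layer.b[...] = 0.0
        return self

    def trainable(self):
        pairs = [
            (self.t_pre, self.g_t_pre),
            (self.mu_pre, self.g_mu_pre),
            (self.t_main, self.g_t_main),
            (self.mu_main, self.g_mu_main),
        ]
        for reg in self.regularizers:
            pairs.extend(reg.params())
        return pairs


@dataclass
class ReconResult:
    """Reconstruction output: complex image, bias-corrected magnitude, and
    the acquired-line data-consistency residual after each cascade."""

    image: np.ndarray
    magnitude: np.ndarray
    residuals: np.ndarray

    @property
    def final_residual(self) -> float:
        return float(self.residuals[-1])


# ---------------------------------------------------------------------------
# cascade steps


def dc_gradient(
    x: np.ndarray,
    y: np.ndarray,
    sens: CoilSensitivities,
    pattern: SamplingPattern,
) -> np.ndarray:
    """Gradient of the data term 0.5 ||mask (F x - y)||^2 : A^H (A x - y).

    ``y`` is the (already masked) measured multi-coil k-space.
    """
    return adjoint(forward(x, sens, pattern) - y, sens, pattern)


def pre_cascade_step(
    x: np.ndarray,
    x_prev: np.ndarray,
    y: np.ndarray,
    sens: CoilSensitivities,
    pattern: SamplingPattern,
    t: float,
    mu: float,
) -> np.ndarray:
    """Extrapolated data-consistency step, no regularization."""
    z = x + mu * (x - x_prev)
    return z - t * dc_gradient(z, y, sens, pattern)


def main_cascade_step(
    x: np.ndarray,
    x_prev: np.ndarray,
    y: np.ndarray,
    sens: CoilSensitivities,
    pattern: SamplingPattern,
    t: float,
    mu: float,
    regularizer: ConvRegularizer,
) -> np.ndarray:
    """Data-consistency step followed by the residual CNN update."""
    x_dc = pre_cascade_step(x, x_prev, y, sens, pattern, t, mu)
    r, _ = regularizer.forward(_c2r(x_dc))
    return x_dc + _r2c(r)


def post_cascade_step(
    x: np.ndarray,
    y: np.ndarray,
    sens: CoilSensitivities,
    pattern: SamplingPattern,
) -> np.ndarray:
    """Fixed unit-step gradient step on the data term (non-trainable).

    With ||A|| <= 1 the residual map is r -> (I - A A^H) r, a contraction, so
    the acquired-line residual never increases.
    """
    return x - dc_gradient(x, y, sens, pattern)


def _c2r(x: np.ndarray) -> np.ndarray:
    return np.stack([x.real, x.imag])


def _r2c(x2: np.ndarray) -> np.ndarray:
    return x2[0] + 1j * x2[1]


def _residual(x, y, sens, pattern) -> float:
    return float(np.linalg.norm(forward(x, sens, pattern) - y))


# ---------------------------------------------------------------------------
# full chain


def _prepare(y: KSpaceData, sens, bias, pattern):
    pattern = pattern or y.pattern
    if sens is None:
        sens = y.sens
    if sens is None:
        sens = estimate_sensitivities(
            extract_acs(y.kspace, pattern), y.shape
        )
    if bias is None:
        bias = y.bias if y.bias is not None else BiasField(np.ones(y.shape))
    return sens, bias, pattern


def _forward_chain(yn, sens, pattern, params, record=None):
    """Run the cascade chain on normalized k-space; optionally cache for
    backprop (``record`` list) and return the iterate list."""
    cfg = params.config
    x = adjoint(yn, sens, pattern)
    iterates = [x]
    x_prev = x
    for k in range(cfg.n_pre):
        t, mu = float(params.t_pre[k]), float(params.mu_pre[k])
        z = x + mu * (x - x_prev)
        g = dc_gradient(z, yn, sens, pattern)
        x_new = z - t * g
        if record is not None:
            record.append(("pre", k, z, g, x, x_prev, None))
        x_prev, x = x, x_new
        iterates.append(x)
    for k in range(cfg.n_main):
        t, mu = float(params.t_main[k]), float(params.mu_main[k])
        z = x + mu * (x - x_prev)
        g = dc_gradient(z, yn, sens, pattern)
        x_dc = z - t * g
        r, cache = params.regularizer(k).forward(_c2r(x_dc))
        x_new = x_dc + _r2c(r)
        if record is not None:
            record.append(("main", k, z, g, x, x_prev, cache))
        x_prev, x = x, x_new
        iterates.append(x)
    for _ in range(cfg.n_post):
        x_new = post_cascade_step(x, yn, sens, pattern)
        if record is not None:
            record.append(("post", 0, x, None, x, x_prev, None))
        x_prev, x = x, x_new
        iterates.append(x)
    return iterates


def _backward_chain(grad_out, record, iterates, yn, sens, pattern, params):
    """Adjoint sweep of :func:`_forward_chain`, accumulating parameter grads.

    ``grad_out`` is dL/dx_final in the real-pair convention.  The two-term
    momentum recursion means each step distributes gradient onto both x_k and
    x_{k-1}; ``grads[i]`` collects dL/d(iterates[i]).
    """

    def AHA(v):
        return adjoint(forward(v, sens, pattern), sens, pattern)

    n = len(iterates)
    grads = [None] * n
    grads[n - 1] = grad_out
    for step_idx in reversed(range(len(record))):
        kind, k, z, g, x, x_prev, cache = record[step_idx]
        out_idx = step_idx + 1
        d_out = grads[out_idx]
        if d_out is None:
            continue
        if kind == "post":
            dx = d_out - AHA(d_out)
            _acc(grads, out_idx - 1, dx)
            continue
        if kind == "main":
            reg = params.regularizer(k)
            d_in2 = reg.backward(cache, _c2r(d_out))
            d_dc = d_out + _r2c(d_in2)
        else:
            d_dc = d_out
        t = float(params.t_pre[k] if kind == "pre" else params.t_main[k])
        mu = float(params.mu_pre[k] if kind == "pre" else params.mu_main[k])
        # x_dc = z - t g(z);  dt = -<d_dc, g(z)>,  dz = (I - t A^H A) d_dc
        dt = -float(np.real(np.vdot(d_dc, g)))
        dz = d_dc - t * AHA(d_dc)
        dmu = float(np.real(np.vdot(dz, x - x_prev)))
        if kind == "pre":
            params.g_t_pre[k] += dt
            params.g_mu_pre[k] += dmu
        else:
            params.g_t_main[k] += dt
            params.g_mu_main[k] += dmu
        _acc(grads, out_idx - 1, (1.0 + mu) * dz)
        if out_idx - 2 >= 0:
            _acc(grads, out_idx - 2, -mu * dz)
        else:
            # x_prev of the first cascade is x_0 itself
            _acc(grads, 0, -mu * dz)
    return grads


def _acc(grads, i, v):
    grads[i] = v if grads[i] is None else grads[i] + v


def reconstruct(
    y: KSpaceData,
    params: UnrolledNetworkParams,
    sens: CoilSensitivities | None = None,
    bias: BiasField | None = None,
    pattern: SamplingPattern | None = None,
) -> ReconResult:
    """Reconstruct one acquisition with the unrolled chain.

    The input is normalized by the 99th percentile of the zero-filled adjoint
    magnitude (undone on output); sensitivities default to the ones stored
    with the data or, failing that, an ACS estimate; the bias field is
    divided out of the output magnitude as the final correction step.
    Deterministic given ``params``.
    """
    sens, bias, pattern = _prepare(y, sens, bias, pattern)
    x0 = adjoint(y.kspace, sens, pattern)
    scale = float(np.percentile(np.abs(x0), 99))
    scale = scale if scale > 0 else 1.0
    yn = y.kspace / scale
    iterates = _forward_chain(yn, sens, pattern, params)
    residuals = scale * np.array(
        [_residual(x, yn, sens, pattern) for x in iterates[1:]]
    )
    image = iterates[-1] * scale
    magnitude = bias_correct(np.abs(image), bias)
    return ReconResult(image=image, magnitude=magnitude, residuals=residuals)


# ---------------------------------------------------------------------------
# loss and training


def loss(
    prediction: np.ndarray,
    target: np.ndarray,
    alpha: float = 1.0,
    beta: float = 1.0,
) -> float:
    """Combined content loss ``alpha * mean|p - t| + beta * (1 - MS-SSIM)``."""
    prediction = np.asarray(prediction, float)
    target = np.asarray(target, float)
    if prediction.shape != target.shape:
        raise ValueError("prediction/target shape mismatch")
    if alpha < 0 or beta < 0:
        raise ValueError("loss weights must be >= 0")
    value = alpha * float(np.mean(np.abs(prediction - target)))
    if beta > 0:
        data_range = float(target.max()) or 1.0
        value += beta * (1.0 - msssim(prediction, target, data_range))
    return value


def _loss_and_grad(pred, target, alpha, beta):
    diff = pred - target
    value = alpha * float(np.mean(np.abs(diff)))
    grad = alpha * np.sign(diff) / diff.size
    if beta > 0:
        data_range = float(target.max()) or 1.0
        ms, dms = msssim_and_grad(pred, target, data_range)
        value += beta * (1.0 - ms)
        grad -= beta * dms
    return value, grad


@dataclass
class _PreparedItem:
    yn: np.ndarray
    scale: float
    sens: CoilSensitivities
    bias_guarded: np.ndarray
    target: np.ndarray
    pattern: SamplingPattern


def _prepare_item(item, sens_mode: str, single_precision: bool = False):
    y = item.acquire()
    if sens_mode == "true":
        sens = item.sens
    else:
        sens = estimate_sensitivities(
            extract_acs(y.kspace, y.pattern), y.shape
        )
    x0 = adjoint(y.kspace, sens, y.pattern)
    scale = float(np.percentile(np.abs(x0), 99)) or 1.0
    yn = y.kspace / scale
    bias_guarded = np.maximum(item.bias.field, item.bias.floor)
    target = np.abs(item.image)
    if single_precision:
        yn = yn.astype(np.complex64)
        sens = CoilSensitivities(
            maps=sens.maps.astype(np.complex64), support=sens.support
        )
        bias_guarded = bias_guarded.astype(np.float32)
        target = target.astype(np.float32)
    return _PreparedItem(
        yn=yn,
        scale=scale,
        sens=sens,
        bias_guarded=bias_guarded,
        target=target,
        pattern=y.pattern,
    )


def _item_loss(prep, params, with_grad: bool):
    record = [] if with_grad else None
    iterates = _forward_chain(prep.yn, prep.sens, prep.pattern, params, record)
    x_final = iterates[-1]
    pred = np.abs(x_final) * prep.scale / prep.bias_guarded
    value, dpred = (
        _loss_and_grad(pred, prep.target, params.alpha, params.beta)
        if with_grad
        else (loss(pred, prep.target, params.alpha, params.beta), None)
    )
    if not with_grad:
        return value
    # back through bias division, scaling and |.|
    mag = np.abs(x_final)
    phase = np.where(mag > 0, x_final / np.maximum(mag, 1e-30), 0.0)
    grad_x = (dpred * prep.scale / prep.bias_guarded) * phase
    _backward_chain(
        grad_x, record, iterates, prep.yn, prep.sens, prep.pattern, params
    )
    return value


def train(
    training_set,
    config: CascadeConfig | None = None,
    epochs: int = 20,
    learning_rate: float = 2e-3,
    seed: int = 0,
    alpha: float = 1.0,
    beta: float = 1.0,
    sens_mode: str = "estimate",
    precision: str = "single",
) -> tuple[UnrolledNetworkParams, dict]:
    """Train the unrolled network on a phantom corpus.

    Per-item (batch size 1) Adam on all trainable parameters; ``sens_mode``
    chooses between ACS-estimated (``"estimate"``, realistic) and
    ground-truth (``"true"``) sensitivity maps.  Training runs in single
    precision by default (``precision="double"`` to override); the chain's
    structural properties are asserted in double in the test suite.
    Reproducible under ``seed``; raises on divergence (non-finite loss).
    Returns the trained parameters and a history dict with per-epoch mean
    training and validation losses.
    """
    config = config or CascadeConfig()
    single = precision == "single"
    train_items = training_set.train
    if not train_items:
        raise ValueError("training split is empty")
    val_items = training_set.val
    prep_train = [_prepare_item(it, sens_mode, single) for it in train_items]
    prep_val = [_prepare_item(it, sens_mode, single) for it in val_items]

    params = UnrolledNetworkParams.init(
        config, seed=seed, alpha=alpha, beta=beta,
        dtype=np.float32 if single else np.float64,
    )
    opt = Adam(params.trainable(), lr=learning_rate)
    rng = np.random.default_rng(seed + 1)

    def val_loss():
        if not prep_val:
            return float("nan")
        return float(np.mean([_item_loss(p, params, False) for p in prep_val]))

    history = {"train_loss": [], "val_loss": [], "initial_val_loss": val_loss()}
    for epoch in range(epochs):
        order = rng.permutation(len(prep_train))
        epoch_losses = []
        for i in order:
            opt.zero_grad()
            value = _item_loss(prep_train[i], params, True)
            if not np.isfinite(value):
                raise RuntimeError(
                    f"training diverged: non-finite loss {value} at epoch "
                    f"{epoch}, item {i}; reduce the learning rate"
                )
            opt.step()
            epoch_losses.append(value)
        history["train_loss"].append(float(np.mean(epoch_losses)))
        history["val_loss"].append(val_loss())
    return params, history


# ---------------------------------------------------------------------------
# checkpoints


def save_params(
    path, params: UnrolledNetworkParams, history: dict | None = None
) -> None:
    """Save parameters to ``<path>.npz`` with a JSON sidecar ``<path>.json``
    (config, loss weights, loss history)."""
    import json
    from pathlib import Path

    path = Path(path)
    arrays = {
        "t_pre": params.t_pre,
        "mu_pre": params.mu_pre,
        "t_main": params.t_main,
        "mu_main": params.mu_main,
    }
    for i, reg in enumerate(params.regularizers):
        for j, layer in enumerate(reg.layers()):
            arrays[f"reg{i}_l{j}_W"] = layer.W
            arrays[f"reg{i}_l{j}_b"] = layer.b
    np.savez(path.with_suffix(".npz"), **arrays)
    cfg = params.config
    sidecar = {
        "config": {
            "n_pre": cfg.n_pre,
            "n_main": cfg.n_main,
            "n_post": cfg.n_post,
            "n_levels": cfg.n_levels,
            "base_channels": cfg.base_channels,
            "share_weights": cfg.share_weights,
        },
        "alpha": params.alpha,
        "beta": params.beta,
        "history": history or {},
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_params(path) -> UnrolledNetworkParams:
    """Load parameters saved by :func:`save_params`."""
    import json
    from pathlib import Path

    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    config = CascadeConfig(**sidecar["config"])
    params = UnrolledNetworkParams.init(
        config, alpha=sidecar["alpha"], beta=sidecar["beta"]
    )
    with np.load(path.with_suffix(".npz")) as data:
        params.t_pre[...] = data["t_pre"]
        params.mu_pre[...] = data["mu_pre"]
        params.t_main[...] = data["t_main"]
        params.mu_main[...] = data["mu_main"]
        for i, reg in enumerate(params.regularizers):
            for j, layer in enumerate(reg.layers()):
                layer.W = data[f"reg{i}_l{j}_W"].copy()
                layer.b = data[f"reg{i}_l{j}_b"].copy()
                layer.gW = np.zeros_like(layer.W)
                layer.gb = np.zeros_like(layer.b)
    return params
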