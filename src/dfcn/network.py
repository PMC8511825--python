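"""NumPy execution engine for the architecture specs.

Implements forward and backward passes for every layer kind so the networks
are trainable on a CPU without a deep-learning framework: dilated convolution
via im2col + BLAS matmul, 2-element max pooling (strided or dilated), and
learnable transposed-convolution upsampling initialised to bilinear
interpolation.  All arithmetic is float32.

Convolutions use symmetric "same" zero padding of ``dilation * (kernel - 1)``
total, so spatial resolution is controlled by strides alone.  Stride-1 pools
pad their lower/right edge with -inf (the window must never prefer padding).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .arch import ArchitectureSpec
from .windowing import window_transform

__all__ = [
    "NetworkInstance",
    "init_network",
    "bilinear_kernel",
    "forward",
    "predict_labels",
    "softmax_cross_entropy",
    "backward",
    "copy_matching_parameters",
]

_F32 = np.float32


# ---------------------------------------------------------------------------
# low-level ops
# ---------------------------------------------------------------------------

def _same_pad(kernel: int, dilation: int) -> tuple[int, int]:
    total = dilation * (kernel - 1)
    return total // 2, total - total // 2


def _im2col(xp: np.ndarray, k: int, d: int, ho: int, wo: int) -> np.ndarray:
    """(N, C, Hp, Wp) -> (N, C*k*k, ho*wo) patch matrix for stride-1 conv."""
    n, c = xp.shape[:2]
    col = np.empty((n, c, k, k, ho, wo), dtype=_F32)
    for i in range(k):
        for j in range(k):
            col[:, :, i, j] = xp[:, :, i * d:i * d + ho, j * d:j * d + wo]
    return col.reshape(n, c * k * k, ho * wo)


def conv2d_forward(x, w, b, dilation=1):
    """Stride-1 'same' dilated convolution.  w: (O, C, k, k)."""
    k = w.shape[2]
    pl, pr = _same_pad(k, dilation)
    xp = np.pad(x, ((0, 0), (0, 0), (pl, pr), (pl, pr))) if k > 1 else x
    ho, wo = x.shape[2], x.shape[3]
    col = _im2col(xp, k, dilation, ho, wo) if k > 1 else x.reshape(x.shape[0], x.shape[1], -1)
    out = np.matmul(w.reshape(w.shape[0], -1), col)
    out += b[:, None]
    return out.reshape(x.shape[0], w.shape[0], ho, wo), col


def conv2d_backward(grad, col, w, x_shape, dilation=1):
    n, _, ho, wo = grad.shape
    o = w.shape[0]
    k = w.shape[2]
    g2 = grad.reshape(n, o, ho * wo)
    # weight/bias grads over the whole batch in one GEMM
    dw = np.matmul(
        g2.transpose(1, 0, 2).reshape(o, -1),
        col.transpose(0, 2, 1).reshape(n * ho * wo, -1),
    ).reshape(w.shape)
    db = g2.sum(axis=(0, 2))
    dcol = np.matmul(w.reshape(o, -1).T, g2)  # (N, C*k*k, L)
    if k == 1:
        return dcol.reshape(x_shape), dw, db
    pl, pr = _same_pad(k, dilation)
    c = x_shape[1]
    dxp = np.zeros((n, c, x_shape[2] + pl + pr, x_shape[3] + pl + pr), dtype=_F32)
    dcol = dcol.reshape(n, c, k, k, ho, wo)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i * dilation:i * dilation + ho,
                j * dilation:j * dilation + wo] += dcol[:, :, i, j]
    if pl or pr:
        dxp = dxp[:, :, pl:pl + x_shape[2], pl:pl + x_shape[3]]
    return dxp, dw, db


def maxpool_forward(x, stride: int, dilation: int = 1):
    """2x2 max pool.  stride 2 halves resolution; stride 1 (converted pool)
    keeps it, reading elements ``dilation`` apart and padding lower/right."""
    n, c, h, w = x.shape
    if stride == 2:
        if h % 2 or w % 2:
            raise ValueError(f"stride-2 pool needs even spatial dims, got {h}x{w}")
        ho, wo = h // 2, w // 2
        xp = x
    else:
        ho, wo = h, w
        xp = np.pad(x, ((0, 0), (0, 0), (0, dilation), (0, dilation)),
                    constant_values=-np.inf)
    cand = np.empty((4, n, c, ho, wo), dtype=_F32)
    for s, (i, j) in enumerate(((0, 0), (0, 1), (1, 0), (1, 1))):
        if stride == 2:
            cand[s] = xp[:, :, i::2, j::2]
        else:
            cand[s] = xp[:, :, i * dilation:i * dilation + ho,
                         j * dilation:j * dilation + wo]
    idx = cand.argmax(axis=0)
    out = np.take_along_axis(cand, idx[None], axis=0)[0]
    return out, idx


def maxpool_backward(grad, idx, x_shape, stride: int, dilation: int = 1):
    n, c, h, w = x_shape
    if stride == 2:
        dx = np.zeros(x_shape, dtype=_F32)
        for s, (i, j) in enumerate(((0, 0), (0, 1), (1, 0), (1, 1))):
            dx[:, :, i::2, j::2] += grad * (idx == s)
        return dx
    dxp = np.zeros((n, c, h + dilation, w + dilation), dtype=_F32)
    ho, wo = h, w
    for s, (i, j) in enumerate(((0, 0), (0, 1), (1, 0), (1, 1))):
        dxp[:, :, i * dilation:i * dilation + ho,
            j * dilation:j * dilation + wo] += grad * (idx == s)
    return dxp[:, :, :h, :w]


def bilinear_kernel(factor: int, dtype=np.float64) -> np.ndarray:
    """Separable 2-D bilinear interpolation kernel of size 2f x 2f (f even)
    or 2f-1 (f odd) for a transposed conv of stride ``factor``."""
    k = 2 * factor - factor % 2
    center = factor - 1 if k % 2 else factor - 0.5
    og = np.arange(k, dtype=dtype)
    f1 = 1.0 - np.abs(og - center) / factor
    return np.outer(f1, f1)


def convT_forward(x, w, factor: int):
    """Transposed conv, stride ``factor``, kernel 2f, pad f/2 -> exact fx
    upsampling.  w: (Ci, Co, k, k)."""
    n, ci, h, wd = x.shape
    co, k = w.shape[1], w.shape[2]
    p = (k - factor) // 2
    hp, wp = (h - 1) * factor + k, (wd - 1) * factor + k
    t = np.matmul(w.reshape(ci, -1).T, x.reshape(n, ci, h * wd))  # (N, Co*k*k, L)
    t = t.reshape(n, co, k, k, h, wd)
    out = np.zeros((n, co, hp, wp), dtype=_F32)
    for i in range(k):
        for j in range(k):
            out[:, :, i:i + (h - 1) * factor + 1:factor,
                j:j + (wd - 1) * factor + 1:factor] += t[:, :, i, j]
    return out[:, :, p:p + h * factor, p:p + wd * factor]


def convT_backward(grad, x, w, factor: int):
    n, ci, h, wd = x.shape
    co, k = w.shape[1], w.shape[2]
    p = (k - factor) // 2
    hp, wp = (h - 1) * factor + k, (wd - 1) * factor + k
    gp = np.zeros((n, co, hp, wp), dtype=_F32)
    gp[:, :, p:p + h * factor, p:p + wd * factor] = grad
    dt = np.empty((n, co, k, k, h, wd), dtype=_F32)
    for i in range(k):
        for j in range(k):
            dt[:, :, i, j] = gp[:, :, i:i + (h - 1) * factor + 1:factor,
                                j:j + (wd - 1) * factor + 1:factor]
    dt = dt.reshape(n, co * k * k, h * wd)
    dx = np.matmul(w.reshape(ci, -1), dt).reshape(x.shape)
    x2 = x.reshape(n, ci, h * wd)
    dw = np.einsum("ncl,nkl->ck", x2, dt, optimize=True).reshape(w.shape)
    return dx, dw


# ---------------------------------------------------------------------------
# network instance
# ---------------------------------------------------------------------------

@dataclass
class NetworkInstance:
    """An architecture bound to concrete parameter values."""

    arch: ArchitectureSpec
    params: dict[str, np.ndarray]
    init_seed: int = 0

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_params(self, params: dict[str, np.ndarray]) -> None:
        for k, v in params.items():
            if k not in self.params:
                raise KeyError(f"unknown parameter {k!r}")
            if self.params[k].shape != v.shape:
                raise ValueError(f"shape mismatch for {k!r}: "
                                 f"{self.params[k].shape} vs {v.shape}")
            self.params[k] = np.asarray(v, dtype=_F32).copy()


def init_network(arch: ArchitectureSpec, seed: int = 0) -> NetworkInstance:
    """Deterministic initialisation: He fan-in normals for convs, zeros for
    score layers, identity-bilinear kernels for upsampling."""
    rng = np.random.default_rng(seed)
    params: dict[str, np.ndarray] = {}
    for l in arch.layers:
        if l.kind == "conv":
            fan_in = l.in_channels * l.kernel * l.kernel
            std = np.sqrt(2.0 / fan_in)
            params[f"{l.name}.w"] = rng.normal(
                0.0, std, (l.out_channels, l.in_channels, l.kernel, l.kernel)
            ).astype(_F32)
            params[f"{l.name}.b"] = np.zeros(l.out_channels, dtype=_F32)
        elif l.kind == "score":
            params[f"{l.name}.w"] = np.zeros(
                (l.out_channels, l.in_channels, l.kernel, l.kernel), dtype=_F32)
            params[f"{l.name}.b"] = np.zeros(l.out_channels, dtype=_F32)
        elif l.kind == "upsample":
            k = l.kernel
            filt = bilinear_kernel(l.stride)
            w = np.zeros((l.in_channels, l.out_channels, k, k), dtype=_F32)
            for c in range(min(l.in_channels, l.out_channels)):
                w[c, c] = filt
            params[f"{l.name}.w"] = w
    return NetworkInstance(arch=arch, params=params, init_seed=seed)


def copy_matching_parameters(src: NetworkInstance, dst: NetworkInstance) -> list[str]:
    """Copy every parameter whose name and shape match; returns copied names."""
    copied = []
    for k, v in src.params.items():
        if k in dst.params and dst.params[k].shape == v.shape:
            dst.params[k] = v.copy()
            copied.append(k)
    return copied


def _as_batch(x) -> np.ndarray:
    x = np.asarray(x, dtype=_F32)
    if x.ndim == 2:
        x = x[None, None]
    elif x.ndim == 3:
        x = x[:, None]
    if x.ndim != 4:
        raise ValueError(f"expected (H,W), (N,H,W) or (N,C,H,W) input, got {x.shape}")
    return x


@dataclass
class _ForwardState:
    outputs: dict[str, np.ndarray] = field(default_factory=dict)
    caches: dict[str, object] = field(default_factory=dict)
    order: list[str] = field(default_factory=list)


def _forward_pass(net: NetworkInstance, x: np.ndarray, upto: str | None = None,
                  need_cache: bool = False) -> _ForwardState:
    st = _ForwardState()
    prev = None
    p = net.params
    for l in net.arch.layers:
        if l.kind == "window":
            # (Cw, N, H, W) -> (N, Cw, H, W)
            out = window_transform(x[:, 0], net.arch.window).transpose(1, 0, 2, 3).copy()
        elif l.kind in ("conv", "score"):
            inp = st.outputs[l.source] if l.source is not None else prev
            out, col = conv2d_forward(inp, p[f"{l.name}.w"], p[f"{l.name}.b"], l.dilation)
            if l.activation == "relu":
                np.maximum(out, 0.0, out=out)
            if need_cache:
                st.caches[l.name] = (col, inp.shape, out if l.activation == "relu" else None)
            del col
        elif l.kind == "pool":
            out, idx = maxpool_forward(prev, l.stride, l.dilation)
            if need_cache:
                st.caches[l.name] = (idx, prev.shape)
        elif l.kind == "upsample":
            out = convT_forward(prev, p[f"{l.name}.w"], l.stride)
            if need_cache:
                st.caches[l.name] = prev
        elif l.kind == "fuse":
            out = prev + st.outputs[l.source]
        else:  # pragma: no cover
            raise AssertionError(l.kind)
        st.outputs[l.name] = out
        st.order.append(l.name)
        prev = out
        if upto is not None and l.name == upto:
            break
    return st


def forward(net: NetworkInstance, x, upto: str | None = None) -> np.ndarray:
    """Run the network on raw-HU input.

    ``x`` may be (H, W), (N, H, W) or (N, 1, H, W); spatial dims must be
    divisible by the backbone stride product (32 for the FCN family).  Output
    is (N, n_classes, H, W) score maps, or the named layer's output if
    ``upto`` is given.
    """
    x = _as_batch(x)
    _check_divisible(net.arch, x)
    st = _forward_pass(net, x, upto=upto)
    return st.outputs[st.order[-1]]


def _backbone_stride(arch: ArchitectureSpec) -> int:
    s = 1
    for l in arch.layers:
        if l.kind in ("conv", "pool", "window"):
            s *= l.stride
    return s


def _check_divisible(arch: ArchitectureSpec, x: np.ndarray) -> None:
    s = _backbone_stride(arch)
    if x.shape[2] % s or x.shape[3] % s:
        raise ValueError(
            f"input spatial dims {x.shape[2]}x{x.shape[3]} must be divisible by {s}; "
            f"pad the input first")


def predict_labels(scores: np.ndarray) -> np.ndarray:
    """Argmax decoding; ties resolve to the lowest class index."""
    scores = np.asarray(scores)
    axis = 1 if scores.ndim == 4 else 0
    return scores.argmax(axis=axis).astype(np.int32)


# ---------------------------------------------------------------------------
# loss and gradients
# ---------------------------------------------------------------------------

def softmax_cross_entropy(scores, labels, class_weights=None):
    """Mean per-pixel multinomial cross-entropy and its gradient wrt scores.

    Returns ``(loss, grad)``; ``class_weights`` (length n_classes) rescales
    each pixel's contribution by its reference class weight, normalised by the
    total pixel weight.
    """
    n, k = scores.shape[:2]
    s = scores.reshape(n, k, -1)
    lab = np.asarray(labels).reshape(n, -1)
    m = s.max(axis=1, keepdims=True)
    e = np.exp(s - m)
    z = e.sum(axis=1, keepdims=True)
    logp = s - m - np.log(z)
    gather = np.take_along_axis(logp, lab[:, None].astype(np.intp), axis=1)[:, 0]
    if class_weights is not None:
        cw = np.asarray(class_weights, dtype=np.float64)
        pw = cw[lab]
    else:
        pw = np.ones_like(gather, dtype=np.float64)
    total = pw.sum()
    loss = float(-(gather * pw).sum() / total)
    grad = (e / z).astype(_F32)
    onehot_idx = lab[:, None].astype(np.intp)
    np.put_along_axis(grad, onehot_idx,
                      np.take_along_axis(grad, onehot_idx, axis=1) - 1.0, axis=1)
    grad *= (pw[:, None] / total).astype(_F32)
    return loss, grad.reshape(scores.shape)


def backward(net: NetworkInstance, x, grad_scores) -> dict[str, np.ndarray]:
    """Parameter gradients for a caller-supplied upstream score gradient."""
    grads, _, _ = forward_backward(net, x, labels=None, grad_scores=grad_scores)
    return grads


def forward_backward(net: NetworkInstance, x, labels, class_weights=None,
                     grad_scores=None):
    """One training step's worth of computation: forward pass, loss, and
    gradients for every parameter.  Returns ``(grads, loss, scores)``."""
    x = _as_batch(x)
    _check_divisible(net.arch, x)
    st = _forward_pass(net, x, need_cache=True)
    scores = st.outputs[st.order[-1]]
    if grad_scores is None:
        loss, gout = softmax_cross_entropy(scores, labels, class_weights)
    else:
        loss, gout = float("nan"), np.asarray(grad_scores, dtype=_F32)

    p = net.params
    grads: dict[str, np.ndarray] = {}
    pending: dict[str, np.ndarray] = {st.order[-1]: gout}
    layers = {l.name: l for l in net.arch.layers}
    for i in range(len(st.order) - 1, -1, -1):
        name = st.order[i]
        l = layers[name]
        g = pending.pop(name, None)
        if g is None:
            continue
        prev_name = st.order[i - 1] if i > 0 else None

        def _send(target: str | None, gg: np.ndarray) -> None:
            if target is None:
                return
            if target in pending:
                pending[target] = pending[target] + gg
            else:
                pending[target] = gg

        if l.kind == "window":
            continue  # input layer: nothing upstream
        if l.kind in ("conv", "score"):
            col, in_shape, relu_out = st.caches[name]
            if relu_out is not None:
                g = g * (relu_out > 0)
            dx, dw, db = conv2d_backward(g, col, p[f"{name}.w"], in_shape, l.dilation)
            grads[f"{name}.w"] = grads.get(f"{name}.w", 0) + dw
            grads[f"{name}.b"] = grads.get(f"{name}.b", 0) + db
            _send(l.source if l.source is not None else prev_name, dx)
        elif l.kind == "pool":
            idx, in_shape = st.caches[name]
            _send(prev_name, maxpool_backward(g, idx, in_shape, l.stride, l.dilation))
        elif l.kind == "upsample":
            xin = st.caches[name]
            dx, dw = convT_backward(g, xin, p[f"{name}.w"], l.stride)
            grads[f"{name}.w"] = grads.get(f"{name}.w", 0) + dw
            _send(prev_name, dx)
        elif l.kind == "fuse":
            _send(prev_name, g)
            _send(l.source, g)
    return grads, loss, scores
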