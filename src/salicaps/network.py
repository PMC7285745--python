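"""Multilane 1D capsule network, implemented in NumPy.

Architecture, per lane: a 1D convolution (10 filters, lane-specific kernel
size, stride 1, 'same' zero padding, ReLU, dropout at training time) over the
``input_len x 20`` profile, a PrimaryCaps layer (size-1 convolution grouping
the filters into ``primary_channels`` capsules of ``capsule_dim`` units,
squashed per capsule), and a HiddenCaps layer reached by dynamic routing with
position-shared transformation matrices.  Hidden capsules from all lanes are
concatenated and fed through a dense ReLU layer and a 2-class softmax.

The squash nonlinearity rescales a capsule vector s to length ||s||^2/(1+||s||^2)
(``sabour`` variant) or ||s||/(1+||s||^2) (``as_printed`` variant) while
preserving its direction.  The ``sabour`` form is the default: it is monotone
in ||s|| and maps lengths onto [0, 1); the ``as_printed`` form peaks at 1/2
and is kept selectable.

Dynamic routing iteratively assigns each primary capsule's prediction vectors
u_hat(j|i) to hidden capsules via coupling coefficients c(i,j) = softmax_j of
agreement logits b(i,j), with b updated by the dot product between u_hat and
the squashed output capsule.

Everything needed for training — forward caches, analytic backprop through
every layer including the unrolled routing loop, and parameter
initialization — lives here; optimization and ensembling live in
:mod:`salicaps.training`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np

from salicaps.encoding import EncodedInput

#: Lane kernel sizes of the full-size network.
DEFAULT_KERNEL_SIZES = (1, 3, 5, 9, 15, 21, 27, 33)

SQUASH_EPS = 1e-8


class ConfigurationError(ValueError):
    """Raised when weights and configuration disagree."""


@dataclass(frozen=True)
class LaneConfig:
    """Configuration of one convolution/capsule lane."""

    kernel_size: int
    n_conv_filters: int = 10
    primary_channels: int = 8
    capsule_dim: int = 16
    primary_stride: int = 1
    hidden_capsules: int = 8
    routing_iterations: int = 5
    dropout_rate: float = 0.5

    def __post_init__(self) -> None:
        if self.kernel_size < 1 or self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be a positive odd integer")
        for name in (
            "n_conv_filters",
            "primary_channels",
            "capsule_dim",
            "primary_stride",
            "hidden_capsules",
            "routing_iterations",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")


@dataclass(frozen=True)
class NetworkConfig:
    """Configuration of the whole multilane network."""

    lanes: tuple[LaneConfig, ...] = field(
        default_factory=lambda: tuple(
            LaneConfig(kernel_size=k) for k in DEFAULT_KERNEL_SIZES
        )
    )
    input_len: int = 1000
    input_channels: int = 20
    dense_units: int = 128
    n_classes: int = 2
    squash_variant: str = "sabour"
    l2_coefficient: float = 1e-4

    def __post_init__(self) -> None:
        if not self.lanes:
            raise ValueError("at least one lane is required")
        if self.n_classes != 2:
            raise ValueError("binary classification only: n_classes must be 2")
        if self.squash_variant not in ("sabour", "as_printed"):
            raise ValueError(f"unknown squash variant {self.squash_variant!r}")
        object.__setattr__(self, "lanes", tuple(self.lanes))

    @property
    def concat_dim(self) -> int:
        return sum(l.hidden_capsules * l.capsule_dim for l in self.lanes)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "NetworkConfig":
        d = dict(d)
        d["lanes"] = tuple(LaneConfig(**lane) for lane in d["lanes"])
        return cls(**d)


# ---------------------------------------------------------------------------
# squash
# ---------------------------------------------------------------------------

def squash(
    s: np.ndarray, variant: str = "sabour", axis: int = -1, eps: float = SQUASH_EPS
) -> np.ndarray:
    """Squash capsule vectors along ``axis``, preserving direction.

    sabour:      v = (||s||^2 / (1 + ||s||^2)) * s/||s||
    as_printed:  v = (||s||   / (1 + ||s||^2)) * s/||s||

    The zero vector maps to the zero vector (epsilon-guarded norm).
    """
    s = _as_float(s)
    nsq = np.sum(s * s, axis=axis, keepdims=True)
    n = np.sqrt(nsq + eps * eps)
    if variant == "sabour":
        scale = n / (1.0 + nsq)
    elif variant == "as_printed":
        scale = 1.0 / (1.0 + nsq)
    else:
        raise ValueError(f"unknown squash variant {variant!r}")
    return scale * s


def squash_backward(
    grad_v: np.ndarray,
    s: np.ndarray,
    variant: str = "sabour",
    axis: int = -1,
    eps: float = SQUASH_EPS,
) -> np.ndarray:
    """Vector-Jacobian product of :func:`squash` at input ``s``.

    With v = a(n) s and n the (guarded) norm, dv/ds = a I + (a'(n)/n) s s^T.
    """
    s = _as_float(s)
    grad_v = _as_float(grad_v)
    nsq = np.sum(s * s, axis=axis, keepdims=True)
    n = np.sqrt(nsq + eps * eps)
    denom = (1.0 + nsq) ** 2
    if variant == "sabour":
        a = n / (1.0 + nsq)
        da_dn = (1.0 - nsq) / denom
    elif variant == "as_printed":
        a = 1.0 / (1.0 + nsq)
        da_dn = -2.0 * n / denom
    else:
        raise ValueError(f"unknown squash variant {variant!r}")
    s_dot_g = np.sum(s * grad_v, axis=axis, keepdims=True)
    return a * grad_v + (da_dn / n) * s_dot_g * s


def _as_float(a: np.ndarray) -> np.ndarray:
    """View as floating point, preserving float32/float64."""
    a = np.asarray(a)
    if not np.issubdtype(a.dtype, np.floating):
        return a.astype(np.float64)
    return a


# ---------------------------------------------------------------------------
# parameter initialization
# ---------------------------------------------------------------------------

def init_params(
    cfg: NetworkConfig, rng: np.random.Generator, dtype=np.float64
) -> dict[str, np.ndarray]:
    """He/Glorot-style initialization of all network weights.

    ``dtype`` selects the working precision; float32 roughly halves training
    cost at no measurable loss of classification quality.
    """
    params: dict[str, np.ndarray] = {}
    for li, lane in enumerate(cfg.lanes):
        fan_in = lane.kernel_size * cfg.input_channels
        params[f"lane{li}/conv_W"] = rng.normal(
            0.0, np.sqrt(2.0 / fan_in),
            size=(lane.kernel_size, cfg.input_channels, lane.n_conv_filters),
        )
        params[f"lane{li}/conv_b"] = np.zeros(lane.n_conv_filters)
        cd = lane.primary_channels * lane.capsule_dim
        params[f"lane{li}/prim_W"] = rng.normal(
            0.0, np.sqrt(2.0 / lane.n_conv_filters),
            size=(lane.n_conv_filters, cd),
        )
        params[f"lane{li}/prim_b"] = np.zeros(cd)
        params[f"lane{li}/hid_W"] = rng.normal(
            0.0, np.sqrt(1.0 / lane.capsule_dim),
            size=(
                lane.primary_channels,
                lane.hidden_capsules,
                lane.capsule_dim,  # output dim
                lane.capsule_dim,  # input dim
            ),
        )
    params["dense_W"] = rng.normal(
        0.0, np.sqrt(2.0 / cfg.concat_dim), size=(cfg.concat_dim, cfg.dense_units)
    )
    params["dense_b"] = np.zeros(cfg.dense_units)
    params["out_W"] = rng.normal(
        0.0, np.sqrt(2.0 / cfg.dense_units), size=(cfg.dense_units, cfg.n_classes)
    )
    params["out_b"] = np.zeros(cfg.n_classes)
    return {k: v.astype(dtype) for k, v in params.items()}


# ---------------------------------------------------------------------------
# layer forwards
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kernel_size: int) -> np.ndarray:
    """(B, L, C) -> (B, L, kernel_size*C) with 'same' zero padding."""
    batch, length, channels = x.shape
    half = kernel_size // 2
    padded = np.zeros((batch, length + 2 * half, channels), dtype=x.dtype)
    padded[:, half : half + length] = x
    cols = np.empty((batch, length, kernel_size, channels), dtype=x.dtype)
    for t in range(kernel_size):
        cols[:, :, t, :] = padded[:, t : t + length, :]
    return cols.reshape(batch, length, kernel_size * channels)


def conv_lane(
    x: np.ndarray,
    cfg: LaneConfig,
    conv_W: np.ndarray,
    conv_b: np.ndarray,
    dropout_mask: np.ndarray | None = None,
) -> np.ndarray:
    """First convolutional layer of a lane.

    1D cross-correlation with stride 1 and 'same' zero padding, ReLU, then
    (training only) inverted dropout via a precomputed ``dropout_mask``.
    ``x`` is (B, L, 20) or (L, 20); output is (B, L, n_conv_filters).
    """
    x = _as_float(x)
    single = x.ndim == 2
    if single:
        x = x[None]
    if cfg.kernel_size > x.shape[1]:
        raise ValueError("kernel_size exceeds input length")
    cols = _im2col(x, cfg.kernel_size)
    z = cols @ conv_W.reshape(-1, conv_W.shape[-1]) + conv_b
    a = np.maximum(z, 0.0)
    if dropout_mask is not None:
        a = a * dropout_mask / (1.0 - cfg.dropout_rate)
    return a[0] if single else a


def primary_caps(
    features: np.ndarray,
    cfg: LaneConfig,
    prim_W: np.ndarray,
    prim_b: np.ndarray,
    squash_variant: str = "sabour",
) -> np.ndarray:
    """PrimaryCaps layer: size-1 convolutional capsules, squashed per capsule.

    ``features`` is (B, L, F) from :func:`conv_lane`.  Positions are strided
    by ``primary_stride``; each retained position yields ``primary_channels``
    capsules of ``capsule_dim`` units.  Output is (B, P, channels, dim).
    """
    features = _as_float(features)
    single = features.ndim == 2
    if single:
        features = features[None]
    strided = features[:, :: cfg.primary_stride, :]
    z = strided @ prim_W + prim_b
    batch, positions, _ = z.shape
    s = z.reshape(batch, positions, cfg.primary_channels, cfg.capsule_dim)
    mu = squash(s, variant=squash_variant, axis=-1)
    return mu[0] if single else mu


def _routing_forward(
    u_hat: np.ndarray, iterations: int, variant: str
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Dynamic routing on prediction vectors u_hat of shape (B, I, J, E).

    Returns (V, couplings, cache) where V is (B, J, E) and couplings (B, I, J)
    are the final coupling coefficients.  The cache holds the per-iteration
    quantities needed by :func:`_routing_backward`.
    """
    batch, n_in, n_out, dim = u_hat.shape
    logits = np.zeros((batch, n_in, n_out), dtype=u_hat.dtype)
    cache: dict = {"c": [], "s": [], "v": [], "u_hat": u_hat}
    couplings = None
    v = None
    for it in range(iterations):
        # softmax over output capsules j; logits start at 0 so iteration 1
        # couples uniformly
        shifted = logits - logits.max(axis=2, keepdims=True)
        expl = np.exp(shifted)
        couplings = expl / expl.sum(axis=2, keepdims=True)
        s = np.einsum("bij,bije->bje", couplings, u_hat)
        v = squash(s, variant=variant, axis=-1)
        cache["c"].append(couplings)
        cache["s"].append(s)
        cache["v"].append(v)
        if it < iterations - 1:
            logits = logits + np.einsum("bije,bje->bij", u_hat, v)
    return v, couplings, cache


def dynamic_routing(
    u_hat: np.ndarray, iterations: int = 5, squash_variant: str = "sabour"
) -> tuple[np.ndarray, np.ndarray]:
    """Route prediction vectors u_hat(j|i) to output capsules.

    ``u_hat`` has shape (I, J, E) or (B, I, J, E).  Logits initialize at
    zero; each iteration computes couplings c(i,.) = softmax_j b(i,.), the
    weighted sum s_j, the squashed output V_j, and (except after the final
    iteration) the agreement update b(i,j) += u_hat(j|i) . V_j.

    Returns (V, couplings); for each i the couplings are nonnegative and sum
    to 1 over j.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    u_hat = _as_float(u_hat)
    single = u_hat.ndim == 3
    if single:
        u_hat = u_hat[None]
    v, couplings, _ = _routing_forward(u_hat, iterations, squash_variant)
    if single:
        return v[0], couplings[0]
    return v, couplings


def _routing_backward(grad_v: np.ndarray, cache: dict, variant: str) -> np.ndarray:
    """Backprop through the unrolled routing loop; returns grad wrt u_hat."""
    u_hat = cache["u_hat"]
    iterations = len(cache["c"])
    grad_logits = np.zeros(u_hat.shape[:3], dtype=u_hat.dtype)
    # grad_u is a sum of outer products A(b,i,j) x B(b,j,e); collect the
    # factors and contract them in one batched matmul at the end instead of
    # materializing a (B, I, J, E) temporary per term
    factors_ij: list[np.ndarray] = []
    factors_je: list[np.ndarray] = []
    gv = grad_v
    for it in range(iterations - 1, -1, -1):
        c_t, s_t, v_t = cache["c"][it], cache["s"][it], cache["v"][it]
        if it < iterations - 1:
            # b_{t+1} = b_t + sum_e u_hat * v_t : contribute to u_hat and v_t
            factors_ij.append(grad_logits)
            factors_je.append(v_t)
            gv = np.einsum("bij,bije->bje", grad_logits, u_hat)
        gs = squash_backward(gv, s_t, variant=variant, axis=-1)
        grad_c = np.einsum("bje,bije->bij", gs, u_hat)
        factors_ij.append(c_t)
        factors_je.append(gs)
        # b_t feeds both the softmax at step t and, additively, b_{t+1};
        # grad_logits already carries the identity path from later steps
        inner = np.sum(grad_c * c_t, axis=2, keepdims=True)
        grad_logits = grad_logits + c_t * (grad_c - inner)
    stacked_ij = np.stack(factors_ij, axis=3)  # (B, I, J, T)
    stacked_je = np.stack(factors_je, axis=2)  # (B, J, T, E)
    grad_u = np.matmul(stacked_ij.transpose(0, 2, 1, 3), stacked_je)
    return grad_u.transpose(0, 2, 1, 3)


def hidden_caps(
    mu: np.ndarray,
    cfg: LaneConfig,
    hid_W: np.ndarray,
    squash_variant: str = "sabour",
) -> tuple[np.ndarray, np.ndarray]:
    """HiddenCaps layer of one lane.

    ``mu`` is (B, P, channels, dim) or (P, channels, dim) from
    :func:`primary_caps`.  Prediction vectors u_hat(j|i) = W(channel(i), j) mu_i
    share their transformation matrix across the positional grid within each
    channel.  Returns (V, couplings) from :func:`dynamic_routing` with V of
    shape (B, hidden_capsules, capsule_dim).
    """
    mu = _as_float(mu)
    single = mu.ndim == 3
    if single:
        mu = mu[None]
    expected = (
        cfg.primary_channels,
        cfg.hidden_capsules,
        cfg.capsule_dim,
        cfg.capsule_dim,
    )
    if hid_W.shape != expected:
        raise ConfigurationError(
            f"hidden weight shape {hid_W.shape} != expected {expected}"
        )
    u_hat = np.einsum("bpcd,cjed->bpcje", mu, hid_W, optimize=True)
    batch, positions, channels, n_out, dim = u_hat.shape
    u_hat = u_hat.reshape(batch, positions * channels, n_out, dim)
    v, couplings = dynamic_routing(
        u_hat, iterations=cfg.routing_iterations, squash_variant=squash_variant
    )
    if single:
        return v[0], couplings[0]
    return v, couplings


# ---------------------------------------------------------------------------
# full forward (+cache) and backward
# ---------------------------------------------------------------------------

def _softmax(z: np.ndarray) -> np.ndarray:
    shifted = z - z.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def forward_with_cache(
    x: np.ndarray,
    cfg: NetworkConfig,
    params: Mapping[str, np.ndarray],
    train: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, dict]:
    """Full forward pass returning (softmax probabilities, cache).

    With ``train=True`` a fresh dropout mask is drawn per lane from ``rng``.
    """
    x = np.asarray(x, dtype=params["out_W"].dtype)
    if x.ndim == 2:
        x = x[None]
    batch = x.shape[0]
    cache: dict = {"x": x, "lanes": []}
    hidden_parts = []
    for li, lane in enumerate(cfg.lanes):
        lc: dict = {}
        cols = _im2col(x, lane.kernel_size)
        conv_W = params[f"lane{li}/conv_W"]
        z1 = cols @ conv_W.reshape(-1, conv_W.shape[-1]) + params[f"lane{li}/conv_b"]
        a1 = np.maximum(z1, 0.0)
        if train and lane.dropout_rate > 0.0:
            if rng is None:
                raise ValueError("training forward pass requires an rng for dropout")
            draw_dtype = a1.dtype if a1.dtype == np.float32 else np.float64
            mask = rng.random(a1.shape, dtype=draw_dtype) >= lane.dropout_rate
            a1d = a1 * mask / (1.0 - lane.dropout_rate)
        else:
            mask = None
            a1d = a1
        strided = a1d[:, :: lane.primary_stride, :]
        z2 = strided @ params[f"lane{li}/prim_W"] + params[f"lane{li}/prim_b"]
        positions = z2.shape[1]
        s_prim = z2.reshape(batch, positions, lane.primary_channels, lane.capsule_dim)
        mu = squash(s_prim, variant=cfg.squash_variant, axis=-1)
        u_hat = np.einsum(
            "bpcd,cjed->bpcje", mu, params[f"lane{li}/hid_W"], optimize=True
        )
        u_hat_flat = u_hat.reshape(
            batch, positions * lane.primary_channels, lane.hidden_capsules,
            lane.capsule_dim,
        )
        v, couplings, rcache = _routing_forward(
            u_hat_flat, lane.routing_iterations, cfg.squash_variant
        )
        hidden_parts.append(v.reshape(batch, -1))
        lc.update(
            cols=cols, z1=z1, a1=a1, mask=mask, a1d=a1d, strided=strided,
            s_prim=s_prim, mu=mu, rcache=rcache, positions=positions, v=v,
            couplings=couplings,
        )
        cache["lanes"].append(lc)
    h = np.concatenate(hidden_parts, axis=1)
    zd = h @ params["dense_W"] + params["dense_b"]
    ad = np.maximum(zd, 0.0)
    logits = ad @ params["out_W"] + params["out_b"]
    probs = _softmax(logits)
    if not np.all(np.isfinite(probs)):
        raise FloatingPointError("non-finite activations in output layer")
    cache.update(h=h, zd=zd, ad=ad, logits=logits, probs=probs)
    return probs, cache


def forward(
    x: EncodedInput | np.ndarray,
    cfg: NetworkConfig,
    params: Mapping[str, np.ndarray],
) -> np.ndarray:
    """Inference forward pass (dropout off).

    Accepts a single :class:`~salicaps.encoding.EncodedInput`, a single
    (L, 20) array, or a batch (B, L, 20).  Returns probabilities of shape
    (2,) or (B, 2); index 1 is the positive (saliva-secretory) class.
    """
    if isinstance(x, EncodedInput):
        x = x.values
    x = np.asarray(x, dtype=np.float64)
    single = x.ndim == 2
    probs, _ = forward_with_cache(x, cfg, params, train=False)
    return probs[0] if single else probs


def loss_and_grads(
    x: np.ndarray,
    y: np.ndarray,
    cfg: NetworkConfig,
    params: Mapping[str, np.ndarray],
    train: bool = True,
    rng: np.random.Generator | None = None,
) -> tuple[float, dict[str, np.ndarray], np.ndarray]:
    """Mean cross-entropy (+ L2 on weights) and analytic gradients.

    Returns (loss, grads, probs).  The L2 penalty 0.5*l2*sum(W^2) covers
    weight matrices only, not biases.
    """
    y = np.asarray(y, dtype=np.int64)
    probs, cache = forward_with_cache(x, cfg, params, train=train, rng=rng)
    batch = probs.shape[0]
    eps = 1e-12
    ce = -np.mean(np.log(probs[np.arange(batch), y] + eps))
    l2 = cfg.l2_coefficient
    reg = 0.0
    if l2 > 0.0:
        reg = 0.5 * l2 * sum(
            float(np.sum(w * w)) for k, w in params.items() if not k.endswith("_b")
        )
    loss = ce + reg

    grads: dict[str, np.ndarray] = {}
    # softmax + cross-entropy
    dlogits = probs.copy()
    dlogits[np.arange(batch), y] -= 1.0
    dlogits /= batch
    grads["out_W"] = cache["ad"].T @ dlogits
    grads["out_b"] = dlogits.sum(axis=0)
    dad = dlogits @ params["out_W"].T
    dzd = dad * (cache["zd"] > 0.0)
    grads["dense_W"] = cache["h"].T @ dzd
    grads["dense_b"] = dzd.sum(axis=0)
    dh = dzd @ params["dense_W"].T

    offset = 0
    for li, lane in enumerate(cfg.lanes):
        lc = cache["lanes"][li]
        width = lane.hidden_capsules * lane.capsule_dim
        dv = dh[:, offset : offset + width].reshape(
            batch, lane.hidden_capsules, lane.capsule_dim
        )
        offset += width
        du_flat = _routing_backward(dv, lc["rcache"], cfg.squash_variant)
        du = du_flat.reshape(
            batch, lc["positions"], lane.primary_channels,
            lane.hidden_capsules, lane.capsule_dim,
        )
        grads[f"lane{li}/hid_W"] = np.einsum("bpcje,bpcd->cjed", du, lc["mu"], optimize=True)
        dmu = np.einsum(
            "bpcje,cjed->bpcd", du, params[f"lane{li}/hid_W"], optimize=True
        )
        ds_prim = squash_backward(
            dmu, lc["s_prim"], variant=cfg.squash_variant, axis=-1
        )
        dz2 = ds_prim.reshape(batch, lc["positions"], -1)
        grads[f"lane{li}/prim_W"] = (
            lc["strided"].reshape(-1, lane.n_conv_filters).T
            @ dz2.reshape(-1, dz2.shape[-1])
        )
        grads[f"lane{li}/prim_b"] = dz2.sum(axis=(0, 1))
        dstrided = dz2 @ params[f"lane{li}/prim_W"].T
        da1d = np.zeros_like(lc["a1"])
        da1d[:, :: lane.primary_stride, :] = dstrided
        if lc["mask"] is not None:
            da1 = da1d * lc["mask"] / (1.0 - lane.dropout_rate)
        else:
            da1 = da1d
        dz1 = da1 * (lc["z1"] > 0.0)
        conv_W = params[f"lane{li}/conv_W"]
        grads[f"lane{li}/conv_W"] = (
            lc["cols"].reshape(-1, lc["cols"].shape[-1]).T
            @ dz1.reshape(-1, dz1.shape[-1])
        ).reshape(conv_W.shape)
        grads[f"lane{li}/conv_b"] = dz1.sum(axis=(0, 1))

    if l2 > 0.0:
        for k in grads:
            if not k.endswith("_b"):
                grads[k] = grads[k] + l2 * params[k]
    return float(loss), grads, probs
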