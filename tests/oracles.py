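"""Straight-line, loop-based reference implementations.

These are deliberately naive reimplementations of the network operations,
kept independent of the vectorized code paths they validate.
"""

import numpy as np


def squash_oracle(s, variant="sabour"):
    s = np.asarray(s, dtype=np.float64)
    n = np.linalg.norm(s)
    if n < 1e-12:
        return np.zeros_like(s)
    if variant == "sabour":
        return (n * n / (1.0 + n * n)) * (s / n)
    return (n / (1.0 + n * n)) * (s / n)


def conv1d_oracle(x, weights, bias):
    """'same'-padded stride-1 cross-correlation with ReLU; x is (L, C)."""
    length, channels = x.shape
    kernel_size, _, n_filters = weights.shape
    half = kernel_size // 2
    out = np.zeros((length, n_filters))
    for pos in range(length):
        for f in range(n_filters):
            acc = bias[f]
            for t in range(kernel_size):
                src = pos + t - half
                if 0 <= src < length:
                    for c in range(channels):
                        acc += x[src, c] * weights[t, c, f]
            out[pos, f] = max(acc, 0.0)
    return out


def primary_caps_oracle(features, prim_W, prim_b, channels, dim, stride,
                        variant="sabour"):
    """Size-1 convolutional capsules with per-capsule squash; (P, C, D)."""
    strided = features[::stride]
    positions = strided.shape[0]
    out = np.zeros((positions, channels, dim))
    for p in range(positions):
        z = strided[p] @ prim_W + prim_b
        for c in range(channels):
            out[p, c] = squash_oracle(z[c * dim : (c + 1) * dim], variant)
    return out


def routing_oracle(u_hat, iterations, variant="sabour"):
    """Reference dynamic routing on (I, J, E) prediction vectors."""
    n_in, n_out, dim = u_hat.shape
    logits = np.zeros((n_in, n_out))
    for it in range(iterations):
        couplings = np.zeros_like(logits)
        for i in range(n_in):
            e = np.exp(logits[i] - logits[i].max())
            couplings[i] = e / e.sum()
        v = np.zeros((n_out, dim))
        for j in range(n_out):
            s = np.zeros(dim)
            for i in range(n_in):
                s += couplings[i, j] * u_hat[i, j]
            v[j] = squash_oracle(s, variant)
        if it < iterations - 1:
            for i in range(n_in):
                for j in range(n_out):
                    logits[i, j] += float(u_hat[i, j] @ v[j])
    return v, couplings


def forward_oracle(x, cfg, params):
    """Composed straight-line forward pass for one (L, C) input."""
    hidden = []
    for li, lane in enumerate(cfg.lanes):
        feats = conv1d_oracle(
            x, params[f"lane{li}/conv_W"], params[f"lane{li}/conv_b"]
        )
        mu = primary_caps_oracle(
            feats, params[f"lane{li}/prim_W"], params[f"lane{li}/prim_b"],
            lane.primary_channels, lane.capsule_dim, lane.primary_stride,
            cfg.squash_variant,
        )
        positions = mu.shape[0]
        hid_W = params[f"lane{li}/hid_W"]
        u_hat = np.zeros(
            (positions * lane.primary_channels, lane.hidden_capsules,
             lane.capsule_dim)
        )
        for p in range(positions):
            for c in range(lane.primary_channels):
                for j in range(lane.hidden_capsules):
                    u_hat[p * lane.primary_channels + c, j] = (
                        hid_W[c, j] @ mu[p, c]
                    )
        v, _ = routing_oracle(u_hat, lane.routing_iterations, cfg.squash_variant)
        hidden.append(v.reshape(-1))
    h = np.concatenate(hidden)
    ad = np.maximum(h @ params["dense_W"] + params["dense_b"], 0.0)
    logits = ad @ params["out_W"] + params["out_b"]
    e = np.exp(logits - logits.max())
    return e / e.sum()
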