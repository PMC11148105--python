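"""Independent straight-loop reference implementations used by the tests.

Everything here is written as plain nested Python loops (or the most naive
vectorized equivalent) in float64, deliberately sharing no code with the
package, so agreement is evidence of correctness rather than tautology.
"""

from __future__ import annotations

import numpy as np


def conv2d_oracle(x: np.ndarray, w: np.ndarray, b: np.ndarray | None,
                  dilation: int = 1) -> np.ndarray:
    """Naive dilated "same"-padded cross-correlation, nested loops."""
    x = np.asarray(x, dtype=np.float64)
    w = np.asarray(w, dtype=np.float64)
    N, C, H, W = x.shape
    Cout, Cin, k, _ = w.shape
    d = dilation
    pad = ((k - 1) * d) // 2
    out = np.zeros((N, Cout, H, W))
    for n in range(N):
        for o in range(Cout):
            for y in range(H):
                for xx in range(W):
                    acc = 0.0
                    for c in range(C):
                        for i in range(k):
                            for j in range(k):
                                yy = y + i * d - pad
                                xj = xx + j * d - pad
                                if 0 <= yy < H and 0 <= xj < W:
                                    acc += x[n, c, yy, xj] * w[o, c, i, j]
                    out[n, o, y, xx] = acc
            if b is not None:
                out[n, o] += float(b[o])
    return out


def conv_transpose2d_oracle(x: np.ndarray, w: np.ndarray,
                            b: np.ndarray | None) -> np.ndarray:
    """Naive 2x2 stride-2 transposed convolution (spatial doubling)."""
    x = np.asarray(x, dtype=np.float64)
    w = np.asarray(w, dtype=np.float64)
    N, C, H, W = x.shape
    Cin, Cout, _, _ = w.shape
    out = np.zeros((N, Cout, 2 * H, 2 * W))
    for n in range(N):
        for c in range(C):
            for o in range(Cout):
                for y in range(H):
                    for xx in range(W):
                        for i in range(2):
                            for j in range(2):
                                out[n, o, 2 * y + i, 2 * xx + j] += (
                                    x[n, c, y, xx] * w[c, o, i, j]
                                )
    if b is not None:
        out += np.asarray(b, dtype=np.float64).reshape(1, -1, 1, 1)
    return out


def batchnorm_eval_oracle(x, mean, var, weight, bias, eps=1e-5):
    """Eval-mode batch normalization with running statistics."""
    x = np.asarray(x, dtype=np.float64)
    out = np.empty_like(x)
    for c in range(x.shape[1]):
        xhat = (x[:, c] - float(mean[c])) / np.sqrt(float(var[c]) + eps)
        out[:, c] = xhat * float(weight[c]) + float(bias[c])
    return out


def sigmoid_oracle(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=np.float64)))


def spatial_attention_oracle(x, w, b):
    """Per-pixel channel mean/max -> 2-channel 7x7 conv loop -> sigmoid."""
    x = np.asarray(x, dtype=np.float64)
    avg = x.mean(axis=1, keepdims=True)
    mx = x.max(axis=1, keepdims=True)
    stacked = np.concatenate([avg, mx], axis=1)
    conv = conv2d_oracle(stacked, w, b, dilation=1)
    return sigmoid_oracle(conv)


def aspp_oracle(x, aspp):
    """Re-evaluate an ASPP block branch by branch with the conv oracle."""
    x = np.asarray(x, dtype=np.float64)
    N, C, H, W = x.shape

    def run(conv, inp):
        b = None if conv.bias is None else conv.bias.data
        return conv2d_oracle(inp, conv.weight.data, b, conv.dilation)

    outs = [run(aspp.conv1x1, x)]
    for conv in aspp.dilated:
        outs.append(run(conv, x))
    pooled = x.mean(axis=(2, 3), keepdims=True) if aspp.pool_mode == "avg" \
        else x.max(axis=(2, 3), keepdims=True)
    p = run(aspp.pool_conv, pooled)
    outs.append(np.broadcast_to(p, (N, p.shape[1], H, W)))
    return run(aspp.fuse, np.concatenate(outs, axis=1))


def confusion_oracle(gt, pr):
    """Per-pixel loop tally of TP/TN/FP/FN."""
    gt = np.asarray(gt).ravel()
    pr = np.asarray(pr).ravel()
    tp = tn = fp = fn = 0
    for g, p in zip(gt, pr):
        if g and p:
            tp += 1
        elif not g and not p:
            tn += 1
        elif not g and p:
            fp += 1
        else:
            fn += 1
    return tp, tn, fp, fn


def bce_oracle(p, q, eps=1e-7):
    p = np.clip(np.asarray(p, dtype=np.float64), eps, 1 - eps)
    q = np.asarray(q, dtype=np.float64)
    total, n = 0.0, 0
    for pi, qi in zip(p.ravel(), q.ravel()):
        total += qi * np.log(pi) + (1 - qi) * np.log(1 - pi)
        n += 1
    return -total / n


def cce_oracle(p, q, eps=1e-7):
    p = np.clip(np.asarray(p, dtype=np.float64), eps, 1 - eps)
    q = np.asarray(q, dtype=np.float64)
    N, M = p.shape[0], p.shape[1]
    total = 0.0
    n_pixels = p.size // M
    for idx in np.ndindex(p.shape):
        total += q[idx] * np.log(p[idx])
    return -total / n_pixels
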