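"""Independent brute-force reference implementations.

Deliberately written with explicit nested loops and hand-built kernels,
sharing no code with the package, so they can serve as oracles for the
vectorized loss and metric implementations.
"""

import math

import numpy as np


def hand_gaussian_kernel(size=3, sigma=1.0):
    half = size // 2
    w = np.empty((size, size))
    for i in range(size):
        for j in range(size):
            w[i, j] = math.exp(-((i - half) ** 2 + (j - half) ** 2) / (2 * sigma**2))
    return w / w.sum()


def loop_conv_same(img, kernel):
    """Zero-padded same-size 2-D convolution via explicit loops."""
    kh, kw = kernel.shape
    ph, pw = kh // 2, kw // 2
    h, w = img.shape
    out = np.zeros_like(img, dtype=float)
    for r in range(h):
        for c in range(w):
            acc = 0.0
            for i in range(kh):
                for j in range(kw):
                    rr, cc = r + i - ph, c + j - pw
                    if 0 <= rr < h and 0 <= cc < w:
                        acc += img[rr, cc] * kernel[kh - 1 - i, kw - 1 - j]
            out[r, c] = acc
    return out


def brute_l1l2(pred, truth, lam, kernel):
    total = 0.0
    for p, t in zip(pred, truth):
        bp = loop_conv_same(np.asarray(p, float), kernel)
        bt = loop_conv_same(np.asarray(t, float), kernel)
        sq = 0.0
        l1 = 0.0
        for r in range(bp.shape[0]):
            for c in range(bp.shape[1]):
                sq += (bp[r, c] - bt[r, c]) ** 2
                l1 += abs(p[r][c])
        total += lam / 2.0 * sq + l1
    return total / len(pred)


def brute_ail(student, teacher, truth, lam, alpha, phi, kernel, mode):
    total = 0.0
    for s, t, x in zip(student, teacher, truth):
        s, t, x = np.asarray(s, float), np.asarray(t, float), np.asarray(x, float)
        bs, bt, bx = (loop_conv_same(a, kernel) for a in (s, t, x))
        own_sq = ((bs - bx) ** 2).sum()
        l1_s = np.abs(s).sum()
        own = lam / 2.0 * own_sq + l1_s
        if mode == "as_printed":
            other_sq = ((bt - bx) ** 2).sum()
        else:
            other_sq = ((bs - bt) ** 2).sum()
        other = lam / 2.0 * other_sq + l1_s
        total += alpha * own + (1 - alpha) * phi * other
    return total / len(student)


def brute_hint_mse(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    acc = 0.0
    count = 0
    for idx in np.ndindex(a.shape):
        acc += (a[idx] - b[idx]) ** 2
        count += 1
    return acc / count


def brute_nmse_printed(pred, truth):
    p, t = np.asarray(pred, float), np.asarray(truth, float)
    err = 0.0
    tn = 0.0
    for idx in np.ndindex(p.shape):
        err += (p[idx] - t[idx]) ** 2
        tn += t[idx] ** 2
    return err / math.sqrt(tn)
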