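"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations (nested loops, all-pairs counting,
closed forms) kept separate from the package code paths they check.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats


def glcm_brute(image, mask, n_levels, offsets, symmetric=True):
    """Nested-loop masked co-occurrence accumulation."""
    img = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    vals = img[mask]
    lo, hi = vals.min(), vals.max()
    q = np.zeros(img.shape, dtype=int)
    if hi > lo:
        for r in range(img.shape[0]):
            for c in range(img.shape[1]):
                q[r, c] = min(int((img[r, c] - lo) / (hi - lo) * n_levels), n_levels - 1)
    P = np.zeros((n_levels, n_levels))
    h, w = mask.shape
    for dr, dc in offsets:
        for r in range(h):
            for c in range(w):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < h and 0 <= c2 < w and mask[r, c] and mask[r2, c2]:
                    P[q[r, c], q[r2, c2]] += 1
                    if symmetric:
                        P[q[r2, c2], q[r, c]] += 1
    return P / P.sum()


def haralick_brute(P):
    """All 13 co-occurrence statistics via explicit double sums, base-2 logs."""
    n = P.shape[0]

    def log2(x):
        return math.log2(x) if x > 0 else 0.0

    px = [sum(P[i, j] for j in range(n)) for i in range(n)]
    py = [sum(P[i, j] for i in range(n)) for j in range(n)]
    mu_x = sum(i * px[i] for i in range(n))
    mu_y = sum(j * py[j] for j in range(n))
    var_x = sum((i - mu_x) ** 2 * px[i] for i in range(n))
    var_y = sum((j - mu_y) ** 2 * py[j] for j in range(n))

    asm = sum(P[i, j] ** 2 for i in range(n) for j in range(n))
    contrast = sum((i - j) ** 2 * P[i, j] for i in range(n) for j in range(n))
    if var_x > 0 and var_y > 0:
        corr = (sum(i * j * P[i, j] for i in range(n) for j in range(n))
                - mu_x * mu_y) / math.sqrt(var_x * var_y)
    else:
        corr = 1.0
    idm = sum(P[i, j] / (1 + (i - j) ** 2) for i in range(n) for j in range(n))

    p_sum = [0.0] * (2 * n - 1)
    p_diff = [0.0] * n
    for i in range(n):
        for j in range(n):
            p_sum[i + j] += P[i, j]
            p_diff[abs(i - j)] += P[i, j]
    sum_avg = sum(k * p_sum[k] for k in range(len(p_sum)))
    sum_var = sum((k - sum_avg) ** 2 * p_sum[k] for k in range(len(p_sum)))
    sum_ent = -sum(p_sum[k] * log2(p_sum[k]) for k in range(len(p_sum)))
    entropy = -sum(P[i, j] * log2(P[i, j]) for i in range(n) for j in range(n))
    diff_avg = sum(k * p_diff[k] for k in range(n))
    diff_var = sum((k - diff_avg) ** 2 * p_diff[k] for k in range(n))
    diff_ent = -sum(p_diff[k] * log2(p_diff[k]) for k in range(n))

    hx = -sum(px[i] * log2(px[i]) for i in range(n))
    hy = -sum(py[j] * log2(py[j]) for j in range(n))
    hxy1 = -sum(P[i, j] * log2(px[i] * py[j])
                for i in range(n) for j in range(n) if P[i, j] > 0)
    hxy2 = -sum(px[i] * py[j] * log2(px[i] * py[j])
                for i in range(n) for j in range(n) if px[i] * py[j] > 0)
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > 0 else 0.0
    imc2 = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - entropy))))

    return {
        "asm": asm, "contrast": contrast, "correlation": corr,
        "inverse_difference": idm, "sum_average": sum_avg,
        "sum_variance": sum_var, "sum_entropy": sum_ent, "entropy": entropy,
        "difference_average": diff_avg, "difference_variance": diff_var,
        "difference_entropy": diff_ent, "info_correlation_1": imc1,
        "info_correlation_2": imc2,
    }


def auc_brute(scores, labels, positive="malignant"):
    """All-pairs Mann-Whitney AUC, ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == positive]
    neg = scores[labels != positive]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def welch_p_closed_form(a, b):
    """Welch two-sample t: statistic, Satterthwaite df, two-sided p."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va ** 2 / (len(a) - 1) + vb ** 2 / (len(b) - 1))
    return 2.0 * stats.t.sf(abs(t), df)


def fcm_reference(x, centers0, m=2.0, iters=500):
    """Plain-loop FCM alternating updates from fixed initial centres."""
    x = np.asarray(x, dtype=float)
    centers = np.array(centers0, dtype=float)
    for _ in range(iters):
        d = np.abs(x[:, None] - centers[None, :])
        d = np.maximum(d, 1e-12)
        u = 1.0 / (d ** (2.0 / (m - 1.0)) * np.sum(d ** (-2.0 / (m - 1.0)),
                                                   axis=1, keepdims=True))
        um = u ** m
        centers = (um * x[:, None]).sum(axis=0) / um.sum(axis=0)
    return centers
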