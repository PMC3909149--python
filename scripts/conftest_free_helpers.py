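"""Self-contained helpers for the acceptance script: independent brute-force
oracles and a noiseless phantom configuration."""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import stats

from breastmri.phantom import PhantomConfig


def noiseless_config(n_cases=20, image_size=96, seed=2) -> PhantomConfig:
    cfg = PhantomConfig(n_cases=n_cases, image_size=image_size, seed=seed)
    for attr in ("benign_kinetics", "malignant_kinetics"):
        setattr(cfg, attr, dataclasses.replace(getattr(cfg, attr), noise_sd=0.0))
    for attr in ("benign_texture", "malignant_texture"):
        setattr(cfg, attr, dataclasses.replace(
            getattr(cfg, attr), intra_lesion_noise_sd=0.0, noise_sd_sigma=0.0))
    return cfg


def glcm_brute(image, mask, n_levels, offsets, symmetric=True):
    img = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    vals = img[mask]
    lo, hi = vals.min(), vals.max()
    q = np.zeros(img.shape, dtype=int)
    if hi > lo:
        for r in range(img.shape[0]):
            for c in range(img.shape[1]):
                q[r, c] = min(int((img[r, c] - lo) / (hi - lo) * n_levels),
                              n_levels - 1)
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
    corr = ((sum(i * j * P[i, j] for i in range(n) for j in range(n))
             - mu_x * mu_y) / math.sqrt(var_x * var_y)
            if var_x > 0 and var_y > 0 else 1.0)
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
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == positive]
    neg = scores[labels != positive]
    wins = 0.0
    for p in pos:
        for q in neg:
            wins += 1.0 if p > q else (0.5 if p == q else 0.0)
    return wins / (len(pos) * len(neg))


def welch_p_closed_form(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va ** 2 / (len(a) - 1) + vb ** 2 / (len(b) - 1))
    return 2.0 * stats.t.sf(abs(t), df)
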