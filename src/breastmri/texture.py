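"""GLCM texture features of the segmented lesion.

The gray-level co-occurrence matrix (GLCM) is the joint distribution of
quantized intensity pairs at small spatial offsets, accumulated only over
pixel pairs that both fall inside the lesion mask (the stock library
routines cannot restrict pairs to an arbitrary mask, hence the in-house
accumulation).  From the normalized matrix the 13 classical Haralick
statistics are computed: angular second moment (ASM, a.k.a. energy),
contrast (inertia), correlation, inverse difference moment, sum average,
sum variance, sum entropy, entropy, difference average, difference
variance, difference entropy, and the two information measures of
correlation.  All logarithms are base 2 with 0·log 0 := 0.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

__all__ = ["GLCMSpec", "TextureFeatures", "build_glcm", "haralick_features"]

DEFAULT_OFFSETS: tuple[tuple[int, int], ...] = ((0, 1), (1, 0), (1, 1), (1, -1))


@dataclass
class GLCMSpec:
    n_levels: int = 32
    offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS
    symmetric: bool = True
    normalize: bool = True

    def validate(self) -> list[str]:
        errs = []
        if self.n_levels < 2:
            errs.append("n_levels must be >= 2")
        if not self.offsets:
            errs.append("at least one offset is required")
        return errs


@dataclass
class TextureFeatures:
    asm: float
    contrast: float
    correlation: float
    inverse_difference: float
    sum_average: float
    sum_variance: float
    sum_entropy: float
    entropy: float
    difference_average: float
    difference_variance: float
    difference_entropy: float
    info_correlation_1: float
    info_correlation_2: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def quantize(image: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Linear quantization of the masked intensity range to n_levels bins."""
    img = np.asarray(image, dtype=float)
    vals = img[mask]
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        return np.zeros(img.shape, dtype=np.intp)
    q = np.floor((img - lo) / (hi - lo) * n_levels).astype(np.intp)
    return np.clip(q, 0, n_levels - 1)


def build_glcm(image: np.ndarray, mask: np.ndarray, spec: GLCMSpec | None = None) -> np.ndarray:
    """Masked, direction-averaged, symmetric co-occurrence matrix.

    Intensities inside the mask are linearly quantized to ``spec.n_levels``
    levels; pairs are counted only when both pixels of an offset pair fall
    inside the mask; the four distance-1 offsets are accumulated
    symmetrically and the result is normalized to sum to 1.
    """
    spec = spec or GLCMSpec()
    errs = spec.validate()
    if errs:
        raise ValueError("invalid GLCMSpec: " + "; ".join(errs))
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 2:
        raise ValueError("need at least 2 masked pixels")
    q = quantize(image, mask, spec.n_levels)
    P = np.zeros((spec.n_levels, spec.n_levels), dtype=float)
    h, w = mask.shape
    for dr, dc in spec.offsets:
        r0a, r1a = max(0, -dr), min(h, h - dr)
        c0a, c1a = max(0, -dc), min(w, w - dc)
        src_mask = mask[r0a:r1a, c0a:c1a]
        dst_mask = mask[r0a + dr:r1a + dr, c0a + dc:c1a + dc]
        valid = src_mask & dst_mask
        a = q[r0a:r1a, c0a:c1a][valid]
        b = q[r0a + dr:r1a + dr, c0a + dc:c1a + dc][valid]
        np.add.at(P, (a, b), 1.0)
        if spec.symmetric:
            np.add.at(P, (b, a), 1.0)
    total = P.sum()
    if total == 0:
        raise ValueError("no valid pixel pairs inside the mask")
    if spec.normalize:
        P = P / total
    return P


def _entropy2(p: np.ndarray) -> float:
    nz = p > 0
    return float(-(p[nz] * np.log2(p[nz])).sum())


def haralick_features(glcm: np.ndarray) -> TextureFeatures:
    """The 13 Haralick statistics of a normalized GLCM.

    Indices are 0-based; the sum distribution p_{x+y} lives on k = 0..2N-2
    and the difference distribution p_{|x-y|} on k = 0..N-1.  Sum variance
    is the variance of p_{x+y} about the sum average.  Information measures:
    IMC1 = (HXY − HXY1)/max(HX, HY) and
    IMC2 = sqrt(1 − exp(−2·(HXY2 − HXY))), entropies in bits.
    Degenerate guards: correlation of a zero-variance matrix is 1; IMC1 of a
    single-cell matrix is 0.
    """
    P = np.asarray(glcm, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("glcm must be square")
    if (P < 0).any() or abs(P.sum() - 1.0) > 1e-8:
        raise ValueError("glcm must be non-negative and normalized to sum 1")
    n = P.shape[0]
    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float((np.arange(n) * px).sum())
    mu_y = float((np.arange(n) * py).sum())
    var_x = float(((np.arange(n) - mu_x) ** 2 * px).sum())
    var_y = float(((np.arange(n) - mu_y) ** 2 * py).sum())

    asm = float((P ** 2).sum())
    contrast = float(((i - j) ** 2 * P).sum())
    if var_x > 0 and var_y > 0:
        correlation = float(((i * j * P).sum() - mu_x * mu_y) / np.sqrt(var_x * var_y))
    else:
        correlation = 1.0
    idm = float((P / (1.0 + (i - j) ** 2)).sum())

    # sum / difference distributions
    ksum = (i + j).ravel()
    kdiff = np.abs(i - j).ravel()
    p_sum = np.bincount(ksum, weights=P.ravel(), minlength=2 * n - 1)
    p_diff = np.bincount(kdiff, weights=P.ravel(), minlength=n)
    ks = np.arange(p_sum.size)
    kd = np.arange(p_diff.size)
    sum_average = float((ks * p_sum).sum())
    sum_variance = float(((ks - sum_average) ** 2 * p_sum).sum())
    sum_entropy = _entropy2(p_sum)
    entropy = _entropy2(P.ravel())
    difference_average = float((kd * p_diff).sum())
    difference_variance = float(((kd - difference_average) ** 2 * p_diff).sum())
    difference_entropy = _entropy2(p_diff)

    hx = _entropy2(px)
    hy = _entropy2(py)
    pxpy = px[:, None] * py[None, :]
    nzP = P > 0
    hxy1 = float(-(P[nzP] * np.log2(pxpy[nzP])).sum())
    nzM = pxpy > 0
    hxy2 = float(-(pxpy[nzM] * np.log2(pxpy[nzM])).sum())
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))

    return TextureFeatures(
        asm=asm, contrast=contrast, correlation=correlation,
        inverse_difference=idm, sum_average=sum_average,
        sum_variance=sum_variance, sum_entropy=sum_entropy, entropy=entropy,
        difference_average=difference_average,
        difference_variance=difference_variance,
        difference_entropy=difference_entropy,
        info_correlation_1=float(imc1), info_correlation_2=imc2,
    )
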