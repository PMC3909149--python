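"""Apparent diffusion coefficient (ADC) quantification from a DWI pair.

With diffusion weightings b = 0 and b = b_high (here 800 s/mm²), mono-
exponential decay S_b = S_0 · exp(−b · ADC) inverts pixelwise to
ADC = ln(S_0 / S_b) / b.  The lesion's DWI intensity is dichotomized
against the surrounding background band (a dilation annulus): only pixels
brighter than the background mean on the high-b image count as the
high-signal region, whose mean ADC is the reported feature.  High-signal
regions smaller than 20 mm² are flagged invalid and excluded downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = ["ADCResult", "adc_features"]

MIN_ROI_AREA_MM2 = 20.0
BACKGROUND_BAND_PX = 5


@dataclass
class ADCResult:
    adc_map: np.ndarray        # 1e-3 mm^2/s; NaN where undefined
    mean_adc: float            # mean over the high-signal region
    roi_area_mm2: float        # area of the high-signal region
    high_signal_mask: np.ndarray
    valid: bool
    n_excluded: int = 0        # non-positive-signal pixels dropped


def adc_features(dwi, mask: np.ndarray, pixel_spacing_mm: float | None = None,
                 b_high: float | None = None) -> ADCResult:
    """ADC map and mean lesion ADC with the background-band dichotomization.

    Parameters default to the values stored on the DWI pair.  The returned
    map is in units of 1e-3 mm²/s.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty lesion mask")
    spacing = dwi.pixel_spacing_mm if pixel_spacing_mm is None else pixel_spacing_mm
    b = dwi.b_high if b_high is None else b_high
    if b <= 0 or spacing <= 0:
        raise ValueError("b_high and pixel spacing must be > 0")
    s0 = np.asarray(dwi.b0, dtype=float)
    sb = np.asarray(dwi.b_high_image, dtype=float)

    positive = (s0 > 0) & (sb > 0)
    n_excluded = int((mask & ~positive).sum())
    if n_excluded:
        logger.info("adc_features: excluded %d non-positive-signal pixels", n_excluded)
    adc_map = np.full(s0.shape, np.nan)
    adc_map[positive] = np.log(s0[positive] / sb[positive]) / b * 1e3

    annulus = ndimage.binary_dilation(mask, iterations=BACKGROUND_BAND_PX) & ~mask
    if annulus.any():
        background_level = float(sb[annulus].mean())
    else:
        background_level = float(sb[~mask].mean()) if (~mask).any() else 0.0
    high = mask & positive & (sb >= background_level)
    area = float(high.sum()) * spacing ** 2
    if not high.any():
        raise ValueError("entire lesion excluded by the high-signal dichotomization")
    mean_adc = float(np.nanmean(adc_map[high]))
    valid = area >= MIN_ROI_AREA_MM2
    if not valid:
        logger.warning("adc_features: high-signal region %.1f mm^2 < %.0f mm^2 -> invalid",
                       area, MIN_ROI_AREA_MM2)
    return ADCResult(adc_map=adc_map, mean_adc=mean_adc, roi_area_mm2=area,
                     high_signal_mask=high, valid=valid, n_excluded=n_excluded)
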