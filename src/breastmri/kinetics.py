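"""Kinetic enhancement features of the dynamic series.

Two scalars summarize the lesion's time-signal-intensity course from just
three frames (lesion-mean intensities SI_pre, SI_first, SI_last):

* slope (early-phase enhancement): (SI_first - SI_pre) / SI_pre — the
  relative signal rise from baseline to the first post-contrast frame;
* SER (signal enhancement ratio): (SI_first - SI_pre) / (SI_last - SI_pre)
  — early over late enhancement.  SER > 1 marks washout (a malignancy
  signature), SER < 1 persistent enhancement, SER = 1 a plateau.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["KineticFeatures", "kinetic_features"]

_EPS = 1e-9


@dataclass
class KineticFeatures:
    slope: float
    ser: float
    ser_defined: bool = True


def kinetic_features(series, mask: np.ndarray) -> KineticFeatures:
    """Slope and SER from lesion-mean intensities of the three frames.

    Raises on non-positive baseline; flags SER as undefined (NaN) when the
    late-enhancement denominator vanishes while the early enhancement does
    not.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty lesion mask")
    si_pre = float(series.pre[mask].mean())
    si_first = float(series.first[mask].mean())
    si_last = float(series.last[mask].mean())
    if si_pre <= 0:
        raise ValueError(f"non-positive pre-contrast lesion intensity ({si_pre:.3g})")

    early = si_first - si_pre
    late = si_last - si_pre
    scale = max(abs(si_pre), 1.0)
    slope = early / si_pre
    if abs(early) < _EPS * scale:
        # no enhancement at all: both features are zero by convention
        return KineticFeatures(slope=0.0, ser=0.0)
    if abs(late) < _EPS * scale:
        logger.warning("SER undefined: SI_last == SI_pre with nonzero early enhancement")
        return KineticFeatures(slope=slope, ser=float("nan"), ser_defined=False)
    return KineticFeatures(slope=slope, ser=early / late)
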