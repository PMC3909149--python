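"""Eleven morphological descriptors of a segmented lesion.

The shape group quantifies the boundary and footprint of the lesion mask /
contour: compactness, spiculation, extent, elongation, solidity,
circularity, entropy of the radial-length distribution, fractal dimension,
heterogeneity, area (mm²) and eccentricity.  Region-level quantities come
from ``skimage.measure.regionprops``; boundary quantities are computed on
the closed contour polygon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields

import numpy as np
from skimage import measure

logger = logging.getLogger(__name__)

__all__ = ["MorphFeatures", "morphological_features", "radial_lengths",
           "count_zero_crossings", "box_counting_dimension"]


@dataclass
class MorphFeatures:
    compactness: float
    spiculation: float
    extent: float
    elongation: float
    solidity: float
    circularity: float
    radial_length_entropy: float
    fractal_dimension: float
    heterogeneity: float
    area: float  # mm^2
    eccentricity: float
    radial_flagged: bool = False  # centroid fell outside the mask

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)
                if f.name != "radial_flagged"}


def radial_lengths(contour: np.ndarray, centroid: tuple[float, float]) -> np.ndarray:
    """Distances from the centroid to each contour vertex."""
    d = contour - np.asarray(centroid, dtype=float)
    return np.sqrt((d ** 2).sum(axis=1))


def count_zero_crossings(values: np.ndarray, atol: float = 0.0) -> int:
    """Sign changes of a cyclic sequence about zero (zeros inherit the
    previous sign so a tangency does not double-count).  Deviations within
    ``atol`` count as zero, so float jitter on a constant sequence does not
    fabricate crossings."""
    values = np.where(np.abs(values) <= atol, 0.0, values)
    signs = np.sign(values)
    # propagate the last nonzero sign through exact zeros
    nz = signs != 0
    if not nz.any():
        return 0
    out = signs.copy()
    last = signs[nz][-1]
    for i in range(len(out)):
        if out[i] == 0:
            out[i] = last
        else:
            last = out[i]
    return int((out != np.roll(out, 1)).sum())


def box_counting_dimension(contour_mask: np.ndarray,
                           sizes: tuple[int, ...] = (1, 2, 4, 8, 16)) -> float:
    """Box-counting (Minkowski) dimension of a rasterized contour.

    Least-squares slope of log N(s) against log (1/s) over dyadic box sizes;
    clipped to the planar-curve range [1, 2].
    """
    pts = np.argwhere(contour_mask)
    if pts.size == 0:
        raise ValueError("empty contour raster")
    origin = pts.min(axis=0)
    pts = pts - origin
    counts = []
    for s in sizes:
        boxes = {tuple(p) for p in (pts // s)}
        counts.append(len(boxes))
    log_inv = np.log(1.0 / np.asarray(sizes, dtype=float))
    log_n = np.log(np.asarray(counts, dtype=float))
    slope = np.polyfit(log_inv, log_n, 1)[0]
    return float(np.clip(slope, 1.0, 2.0))


def _contour_raster(image_shape: tuple[int, int], contour: np.ndarray) -> np.ndarray:
    """Rasterize the closed polygon boundary by marching along its edges."""
    raster = np.zeros(image_shape, dtype=bool)
    closed = np.vstack([contour, contour[:1]])
    for p, q in zip(closed[:-1], closed[1:]):
        n_steps = int(np.ceil(np.abs(q - p).max())) + 1
        t = np.linspace(0.0, 1.0, n_steps)
        rr = np.clip(np.round(p[0] + t * (q[0] - p[0])).astype(int), 0, image_shape[0] - 1)
        cc = np.clip(np.round(p[1] + t * (q[1] - p[1])).astype(int), 0, image_shape[1] - 1)
        raster[rr, cc] = True
    return raster


def _perimeter(contour: np.ndarray) -> float:
    closed = np.vstack([contour, contour[:1]])
    return float(np.sqrt((np.diff(closed, axis=0) ** 2).sum(axis=1)).sum())


def morphological_features(geometry, pixel_spacing_mm: float,
                           intensity_image: np.ndarray) -> MorphFeatures:
    """Compute the eleven shape descriptors of one lesion.

    Parameters
    ----------
    geometry : LesionGeometry
        Mask plus closed boundary polygon on the image grid.
    pixel_spacing_mm : float
        In-plane pixel size; areas are reported in mm², perimeters in mm.
    intensity_image : ndarray
        The first post-contrast frame; only used for heterogeneity
        (intra-lesion sd / mean).

    Definitions (A area, P perimeter): circularity = 4πA/P², compactness =
    P²/(4πA), extent = A / bounding-box area, solidity = polygon area /
    convex-hull area (continuous, on the boundary polygon), elongation =
    major/minor axis of the second-moments ellipse,
    eccentricity from the same ellipse.  Radial descriptors use centroid→
    vertex distances r(θ_i): spiculation is the count of zero crossings of
    r − mean(r) divided by the vertex count (resampling-invariant), and the
    radial-length entropy is the base-2 Shannon entropy of the 10-bin
    histogram of max-normalized radii.  Fractal dimension is the
    box-counting slope of the rasterized contour.
    """
    if pixel_spacing_mm <= 0:
        raise ValueError("pixel_spacing_mm must be > 0")
    mask = geometry.mask.astype(bool)
    contour = np.asarray(geometry.contour, dtype=float)
    area_px = int(mask.sum())
    if area_px == 0:
        raise ValueError("empty mask")

    props = measure.regionprops(mask.astype(np.uint8))[0]
    area = area_px * pixel_spacing_mm ** 2
    perim = _perimeter(contour) * pixel_spacing_mm
    if perim <= 0:
        raise ValueError("zero-perimeter contour")
    circularity = min(1.0, 4.0 * np.pi * area / perim ** 2)
    compactness = perim ** 2 / (4.0 * np.pi * area)

    minor = props.axis_minor_length
    elongation = props.axis_major_length / minor if minor > 0 else float("inf")

    # solidity on the continuous boundary polygon (pixelated convex hulls
    # systematically understate the solidity of smooth shapes)
    from shapely.geometry import Polygon
    poly = Polygon(np.column_stack([contour[:, 1], contour[:, 0]]))
    solidity = poly.area / poly.convex_hull.area if poly.convex_hull.area > 0 else float("nan")

    centroid = props.centroid
    flagged = not mask[int(round(centroid[0])), int(round(centroid[1]))]
    if flagged:
        logger.warning("centroid outside mask; radial features flagged")
    r = radial_lengths(contour, centroid)
    crossings = count_zero_crossings(r - r.mean(), atol=1e-6 * r.mean())
    spiculation = crossings / contour.shape[0]
    r_norm = r / r.max()
    hist, _ = np.histogram(r_norm, bins=10, range=(0.0, 1.0))
    p = hist / hist.sum()
    nz = p > 0
    radial_entropy = float(-(p[nz] * np.log2(p[nz])).sum())

    fractal = box_counting_dimension(_contour_raster(mask.shape, contour))

    vals = intensity_image[mask].astype(float)
    mean = vals.mean()
    heterogeneity = float(vals.std() / mean) if mean > 0 else float("nan")

    return MorphFeatures(
        compactness=float(compactness),
        spiculation=float(spiculation),
        extent=float(props.extent),
        elongation=float(elongation),
        solidity=float(min(1.0, solidity)),
        circularity=float(circularity),
        radial_length_entropy=radial_entropy,
        fractal_dimension=fractal,
        heterogeneity=heterogeneity,
        area=float(area),
        eccentricity=float(props.eccentricity),
        radial_flagged=flagged,
    )
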