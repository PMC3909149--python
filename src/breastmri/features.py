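"""The 28-feature registry and per-case / per-cohort extraction.

Each lesion is characterized by five feature groups totalling 28
measurements: 1 pathology (age), 2 kinetic (slope, SER), 11 morphological,
13 GLCM texture, and 1 DWI (mean ADC).  Column names are fixed by a
registry; historical synonyms used in the radiomics literature (energy ≡
angular second moment, inertia ≡ contrast, rectangular degree ≡ extent,
inverse difference ≡ inverse difference moment) resolve through an alias
table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffusion import adc_features
from .kinetics import kinetic_features
from .morphology import morphological_features
from .phantom import Cohort
from .segmentation import LesionGeometry, SegmentationError, SnakeParams, segment_lesion
from .texture import GLCMSpec, build_glcm, haralick_features

logger = logging.getLogger(__name__)

__all__ = [
    "FEATURE_GROUPS",
    "FEATURE_NAMES",
    "FEATURE_ALIASES",
    "canonical_name",
    "feature_group",
    "ExtractionConfig",
    "extract_case",
    "extract_cohort_features",
    "assemble_features",
]

FEATURE_GROUPS: dict[str, tuple[str, ...]] = {
    "pathology": ("age",),
    "kinetic": ("slope", "ser"),
    "morphology": (
        "compactness", "spiculation", "extent", "elongation", "solidity",
        "circularity", "radial_length_entropy", "fractal_dimension",
        "heterogeneity", "area", "eccentricity",
    ),
    "texture": (
        "asm", "contrast", "correlation", "inverse_difference", "sum_average",
        "sum_variance", "sum_entropy", "entropy", "difference_average",
        "difference_variance", "difference_entropy", "info_correlation_1",
        "info_correlation_2",
    ),
    "dwi": ("adc",),
}

FEATURE_NAMES: tuple[str, ...] = tuple(
    name for names in FEATURE_GROUPS.values() for name in names
)
assert len(FEATURE_NAMES) == 28

# literature synonyms -> canonical registry names
FEATURE_ALIASES: dict[str, str] = {
    "energy": "asm",
    "angular_second_moment": "asm",
    "inertia": "contrast",
    "rectangular_degree": "extent",
    "inverse_difference_moment": "inverse_difference",
    "entropy_of_radial_length_distribution": "radial_length_entropy",
    "fractal": "fractal_dimension",
    "information_correlation_1": "info_correlation_1",
    "information_correlation_2": "info_correlation_2",
    "information_measure_of_correlation_1": "info_correlation_1",
    "information_measure_of_correlation_2": "info_correlation_2",
}


def canonical_name(name: str) -> str:
    """Resolve a feature name (or literature synonym) to its registry name."""
    key = name.strip().lower().replace(" ", "_").replace("-", "_")
    key = FEATURE_ALIASES.get(key, key)
    if key not in FEATURE_NAMES:
        raise KeyError(f"unknown feature name: {name!r}")
    return key


def feature_group(name: str) -> str:
    key = canonical_name(name)
    for group, names in FEATURE_GROUPS.items():
        if key in names:
            return group
    raise KeyError(name)  # unreachable


@dataclass
class ExtractionConfig:
    glcm: GLCMSpec = field(default_factory=GLCMSpec)
    snake: SnakeParams = field(default_factory=SnakeParams)
    use_segmentation: bool = True  # False: use the phantom's true contour
    fcm_c: int = 2
    fcm_m: float = 2.0
    seed: int = 0


def extract_case(series, dwi, geometry: LesionGeometry, age: float,
                 pixel_spacing_mm: float,
                 glcm_spec: GLCMSpec | None = None) -> tuple[dict[str, float], bool]:
    """All 28 measurements of one case given its lesion geometry.

    Returns (feature dict, valid flag); the flag is False when any component
    marks itself invalid (undefined SER, DWI region below the minimum area).
    """
    kin = kinetic_features(series, geometry.mask)
    morph = morphological_features(geometry, pixel_spacing_mm, series.first)
    glcm = build_glcm(series.first, geometry.mask, glcm_spec or GLCMSpec())
    tex = haralick_features(glcm)
    adc = adc_features(dwi, geometry.mask, pixel_spacing_mm)

    row: dict[str, float] = {"age": float(age), "slope": kin.slope, "ser": kin.ser}
    row.update(morph.as_dict())
    row.update(tex.as_dict())
    row["adc"] = adc.mean_adc
    valid = kin.ser_defined and adc.valid and all(
        np.isfinite(v) for v in row.values())
    return row, valid


def extract_cohort_features(cohort: Cohort,
                            config: ExtractionConfig | None = None) -> pd.DataFrame:
    """Feature table (cases × 28 + label) for a rendered phantom cohort.

    With ``config.use_segmentation`` the lesion geometry comes from the
    FCM + GVF-snake pipeline on each case's ROI; otherwise the phantom's
    planted contour is rasterized directly (useful to study the downstream
    stages in isolation from segmentation error).  Cases whose extraction
    fails or is flagged invalid are excluded with a logged reason.
    """
    config = config or ExtractionConfig()
    rows = []
    image_shape = (cohort.config.image_size,) * 2
    for case in cohort.cases:
        ph = case.phantom
        try:
            if config.use_segmentation:
                geometry = segment_lesion(
                    case.series, ph.roi_box, fcm_c=config.fcm_c,
                    fcm_m=config.fcm_m, snake_params=config.snake,
                    seed=config.seed)
            else:
                geometry = LesionGeometry.from_contour(image_shape, ph.true_contour)
            row, valid = extract_case(case.series, case.dwi, geometry, ph.age,
                                      cohort.config.pixel_spacing_mm, config.glcm)
        except (SegmentationError, ValueError) as exc:
            logger.warning("case %s excluded: %s", ph.case_id, exc)
            continue
        if not valid:
            logger.warning("case %s excluded: invalid feature flagged", ph.case_id)
            continue
        row["case_id"] = ph.case_id
        row["label"] = ph.label
        rows.append(row)
    return assemble_features(rows)


def assemble_features(rows: list[dict]) -> pd.DataFrame:
    """Assemble per-case feature dicts into the canonical 28-column table."""
    if not rows:
        raise ValueError("no valid cases to assemble")
    df = pd.DataFrame(rows)
    if df["case_id"].duplicated().any():
        dupes = df.loc[df["case_id"].duplicated(), "case_id"].tolist()
        raise ValueError(f"duplicate case_id(s): {dupes}")
    missing = [n for n in FEATURE_NAMES if n not in df.columns]
    if missing:
        raise ValueError(f"missing feature columns: {missing}")
    return df[["case_id", "label", *FEATURE_NAMES]].reset_index(drop=True)


def feature_schema() -> list[dict[str, str]]:
    """Sidecar schema: name, group and units of each registry feature."""
    units = {"age": "years", "area": "mm^2", "adc": "1e-3 mm^2/s"}
    return [
        {"name": name, "group": feature_group(name),
         "units": units.get(name, "dimensionless")}
        for name in FEATURE_NAMES
    ]
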