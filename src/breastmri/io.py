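"""Plain-file I/O for every pipeline stage.

All intermediate artifacts are ordinary files so each stage can run (and be
tested) standalone: frames as NIfTI (optionally 16-bit PNG), masks as 0/255
PNG, contours and ground truth as CSV, the feature table as CSV with a
sidecar JSON schema, configs as YAML, selection traces and reports as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .features import feature_schema
from .phantom import Cohort

__all__ = [
    "save_series", "load_frame", "save_mask_png", "load_mask_png",
    "save_contour_csv", "load_contour_csv", "save_features",
    "load_features", "save_json", "load_json", "save_yaml", "load_yaml",
    "save_cohort",
]

FRAME_ROLES = ("pre", "first", "last", "b0", "b_high")


def _nifti(img: np.ndarray, spacing: float) -> nib.Nifti1Image:
    affine = np.diag([spacing, spacing, 1.0, 1.0])
    return nib.Nifti1Image(np.asarray(img, dtype=np.float32)[..., None], affine)


def save_series(case_dir: Path, series, dwi, png: bool = False) -> None:
    """One NIfTI per frame role (pre/first/last/b0/b_high) for one case."""
    case_dir = Path(case_dir)
    case_dir.mkdir(parents=True, exist_ok=True)
    frames = {**series.frames, "b0": dwi.b0, "b_high": dwi.b_high_image}
    for role, img in frames.items():
        nib.save(_nifti(img, series.pixel_spacing_mm), case_dir / f"{role}.nii")
        if png:
            lo, hi = img.min(), img.max()
            scaled = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)
            iio.imwrite(case_dir / f"{role}.png",
                        (scaled * 65535).astype(np.uint16))


def load_frame(path: Path) -> np.ndarray:
    img = np.asarray(nib.load(str(path)).dataobj, dtype=float)
    return img[..., 0] if img.ndim == 3 else img


def save_mask_png(path: Path, mask: np.ndarray) -> None:
    iio.imwrite(Path(path), (np.asarray(mask, bool) * 255).astype(np.uint8))


def load_mask_png(path: Path) -> np.ndarray:
    return np.asarray(iio.imread(Path(path))) > 127


def save_contour_csv(path: Path, contour: np.ndarray) -> None:
    pd.DataFrame(contour, columns=["row", "col"]).to_csv(Path(path), index=False)


def load_contour_csv(path: Path) -> np.ndarray:
    return pd.read_csv(Path(path))[["row", "col"]].to_numpy(float)


def save_features(path: Path, table: pd.DataFrame) -> None:
    """Feature CSV plus the sidecar `<name>.schema.json`."""
    path = Path(path)
    table.to_csv(path, index=False)
    schema_path = path.with_suffix(".schema.json")
    schema_path.write_text(json.dumps(feature_schema(), indent=2))


def load_features(path: Path) -> pd.DataFrame:
    return pd.read_csv(Path(path))


def save_json(path: Path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True))


def load_json(path: Path):
    return json.loads(Path(path).read_text())


def save_yaml(path: Path, obj) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))


def load_yaml(path: Path):
    return yaml.safe_load(Path(path).read_text())


def save_cohort(outdir: Path, cohort: Cohort, png: bool = False) -> None:
    """Write a rendered cohort: per-case frame files + contours, plus the
    ground-truth table and ROI boxes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rois = []
    for case in cohort.cases:
        cdir = outdir / case.phantom.case_id
        save_series(cdir, case.series, case.dwi, png=png)
        save_contour_csv(cdir / "true_contour.csv", case.phantom.true_contour)
        rois.append({"case_id": case.phantom.case_id,
                     **dict(zip(("r0", "c0", "r1", "c1"), case.phantom.roi_box))})
    cohort.truth.to_csv(outdir / "truth.csv", index=False)
    pd.DataFrame(rois).to_csv(outdir / "roi_boxes.csv", index=False)
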