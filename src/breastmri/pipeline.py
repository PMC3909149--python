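"""Orchestration of the full simulate → segment → extract → select →
evaluate chain, with YAML configuration and a reproducibility manifest.

Every random process takes an explicit seed derived from the single
top-level seed, all intermediate artifacts are plain files, and the run
manifest (config snapshot, per-stage seeds, output checksums, package
version, timestamps) makes a completed run replayable bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import time
from dataclasses import dataclass, field, fields, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .evaluation import build_report
from .features import ExtractionConfig, extract_cohort_features
from .phantom import PhantomConfig, generate_cohort
from .selection import GAConfig, SelectionConfig, run_hybrid_fss
from .texture import GLCMSpec
from . import io as bio

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "EvalSettings", "validate_config", "run_all", "replay"]


@dataclass
class EvalSettings:
    k: int = 10
    inner_k: int = 5

    def validate(self) -> list[str]:
        errs = []
        if self.k < 2:
            errs.append("evaluation.k must be >= 2")
        if self.inner_k < 2:
            errs.append("evaluation.inner_k must be >= 2")
        return errs


@dataclass
class PipelineConfig:
    seed: int = 0
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    evaluation: EvalSettings = field(default_factory=EvalSettings)

    def stage_seeds(self) -> dict[str, int]:
        ss = np.random.SeedSequence(self.seed)
        children = ss.spawn(4)
        names = ("phantom", "extraction", "selection", "evaluation")
        return {n: int(c.generate_state(1)[0] % (2**31 - 1))
                for n, c in zip(names, children)}

    def resolved(self) -> "PipelineConfig":
        """Propagate the per-stage seeds into the stage configs."""
        seeds = self.stage_seeds()
        cfg = dataclasses.replace(self)
        cfg.phantom = dataclasses.replace(self.phantom, seed=seeds["phantom"])
        cfg.extraction = dataclasses.replace(self.extraction, seed=seeds["extraction"])
        ga = dataclasses.replace(self.selection.ga, seed=seeds["selection"])
        cfg.selection = dataclasses.replace(self.selection, ga=ga)
        return cfg


def _to_dict(obj):
    if is_dataclass(obj):
        return {f.name: _to_dict(getattr(obj, f.name)) for f in fields(obj)}
    if isinstance(obj, (list, tuple)):
        return [_to_dict(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _apply(obj, data: dict, prefix: str, errors: list[str]):
    """Generic dataclass updater: unknown keys and type mismatches are
    collected (exhaustively) rather than raised one at a time."""
    valid = {f.name: f for f in fields(obj)}
    for key, value in data.items():
        path = f"{prefix}{key}"
        if key not in valid:
            errors.append(f"unknown key: {path}")
            continue
        current = getattr(obj, key)
        if is_dataclass(current) and isinstance(value, dict):
            _apply(current, value, path + ".", errors)
        elif isinstance(value, dict):
            errors.append(f"{path}: mapping given for scalar field")
        else:
            if isinstance(value, list):
                value = tuple(tuple(v) if isinstance(v, list) else v for v in value)
            setattr(obj, key, value)
    return obj


def validate_config(raw: dict | None) -> tuple[PipelineConfig, list[str], list[str]]:
    """Build and validate a pipeline config from a parsed YAML mapping.

    Returns (config, errors, warnings); errors are exhaustive, not
    first-only.  Unknown keys are errors (no silent typos); a missing seed
    is defaulted with a warning.
    """
    errors: list[str] = []
    warnings: list[str] = []
    cfg = PipelineConfig()
    raw = dict(raw or {})
    if "seed" not in raw:
        warnings.append("seed missing: defaulted to 0 (recorded in manifest)")
    _apply(cfg, raw, "", errors)
    errors += [f"phantom: {e}" for e in cfg.phantom.validate()]
    errors += [f"selection: {e}" for e in cfg.selection.validate()]
    errors += [f"evaluation: {e}" for e in cfg.evaluation.validate()]
    errors += [f"extraction.snake: {e}" for e in cfg.extraction.snake.validate()]
    errors += [f"extraction.glcm: {e}" for e in cfg.extraction.glcm.validate()]
    n_mal = round(cfg.phantom.malignant_fraction * cfg.phantom.n_cases)
    if min(n_mal, cfg.phantom.n_cases - n_mal) < cfg.evaluation.k:
        errors.append("phantom cohort too small: the minority class would have "
                      "fewer cases than evaluation.k folds")
    return cfg, errors, warnings


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _feature_sets(final_subset: list[str]) -> dict[str, list[str]]:
    """The standard comparison sets: each single planted-signal feature and
    the texture trio alongside the combined selected subset."""
    from .features import feature_group

    sets: dict[str, list[str]] = {}
    for name in final_subset:
        group = feature_group(name)
        if group in ("kinetic", "dwi", "pathology") or name == "slope":
            sets[f"{name}_only"] = [name]
    texture = [n for n in final_subset if feature_group(n) == "texture"]
    if texture:
        sets["texture_only"] = texture
    sets["combined"] = list(final_subset)
    return sets


def run_all(config: PipelineConfig, outdir: Path, save_images: bool = False) -> dict:
    """Execute all stages in order, writing features.csv, trace.json,
    report.json and manifest.json under ``outdir``.

    Any stage failure aborts with a stage-labelled error; outputs written
    before the failure are renamed with a ``.partial`` suffix.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = config.resolved()
    manifest: dict = {
        "version": __version__,
        "config": _to_dict(config),
        "stage_seeds": config.stage_seeds(),
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "outputs": {},
    }
    written: list[Path] = []

    def emit(name: str, writer) -> Path:
        path = outdir / name
        writer(path)
        manifest["outputs"][name] = _sha256(path)
        written.append(path)
        return path

    try:
        logger.info("stage simulate: n=%d seed=%d", cfg.phantom.n_cases, cfg.phantom.seed)
        cohort = generate_cohort(cfg.phantom)
        emit("truth.csv", lambda p: cohort.truth.to_csv(p, index=False))
        if save_images:
            bio.save_cohort(outdir / "images", cohort)

        logger.info("stage segment+extract (use_segmentation=%s)",
                    cfg.extraction.use_segmentation)
        table = extract_cohort_features(cohort, cfg.extraction)
        emit("features.csv", lambda p: bio.save_features(p, table))

        logger.info("stage select: alpha=%.3g", cfg.selection.alpha)
        feats = table.drop(columns=["case_id", "label"])
        trace = run_hybrid_fss(feats, table["label"], cfg.selection)
        emit("trace.json", lambda p: bio.save_json(p, trace.as_dict()))

        logger.info("stage evaluate: final subset %s", trace.final_subset)
        report = build_report(
            table, table["label"], trace.final_subset,
            _feature_sets(trace.final_subset),
            k=cfg.evaluation.k, inner_k=cfg.evaluation.inner_k,
            seed=config.stage_seeds()["evaluation"])
        emit("report.json", lambda p: bio.save_json(p, report))
    except Exception:
        for path in written:
            path.rename(path.with_suffix(path.suffix + ".partial"))
        raise

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    bio.save_json(outdir / "manifest.json", manifest)
    return manifest


def replay(manifest_path: Path, outdir: Path) -> dict:
    """Re-run a manifest's config and verify output checksums match."""
    manifest = bio.load_json(manifest_path)
    cfg, errors, _ = validate_config(manifest["config"])
    if errors:
        raise ValueError("manifest config invalid: " + "; ".join(errors))
    new_manifest = run_all(cfg, outdir)
    mismatches = {
        name: (digest, new_manifest["outputs"].get(name))
        for name, digest in manifest["outputs"].items()
        if new_manifest["outputs"].get(name) != digest
    }
    new_manifest["replay_mismatches"] = mismatches
    if mismatches:
        logger.warning("replay: checksum mismatches in %s", sorted(mismatches))
    return new_manifest
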