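"""Synthetic DCE-MRI / DWI phantom cohorts of breast mass lesions.

Real multiparametric breast-MRI cohorts are rarely shareable, so every
downstream stage of the package (segmentation, feature extraction, feature
selection, evaluation) is exercised against phantoms that carry the
statistical structure the analysis assumes:

* lesion shapes with class-dependent boundary irregularity — benign masses
  are smooth, near-elliptical; malignant masses are star-shaped (spiculated),
* class-dependent enhancement kinetics — malignant lesions wash out after a
  strong early rise (signal enhancement ratio SER > 1), benign lesions keep
  enhancing (SER < 1),
* class-dependent intra-lesion texture heterogeneity,
* class-dependent apparent diffusion coefficient (ADC), lower in malignant
  tissue, with the diffusion pair obeying S_b = S_0 * exp(-b * ADC) before
  noise,
* class-dependent age distributions, truncated to the plausible clinical
  range.

A phantom case is a single representative 2-D slice: three dynamic frames
(pre-contrast, first post-contrast, last post-contrast — the only frames any
kinetic formula here consumes) plus a diffusion pair at b = 0 and
b = 800 s/mm².
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter
from skimage.draw import polygon2mask

__all__ = [
    "ShapeParams",
    "KineticParams",
    "TextureParams",
    "ADCParams",
    "AgeParams",
    "PhantomConfig",
    "CasePhantom",
    "DynamicSeries",
    "DWIPair",
    "CohortCase",
    "Cohort",
    "HISTOPATHOLOGY_COUNTS",
    "histopathology_table",
    "make_lesion_shape",
    "render_case",
    "generate_cohort",
    "sample_feature_table",
]


# Histopathological composition of the study cohort the phantom emulates:
# 149 malignant and 85 benign masses (234 lesions).  Used as the default
# class balance and for cohort-composition arithmetic.
HISTOPATHOLOGY_COUNTS: dict[str, dict[str, int]] = {
    "malignant": {
        "invasive_ductal_carcinoma": 120,
        "intraductal_carcinoma": 17,
        "ductal_carcinoma_in_situ": 4,
        "mucinous_carcinoma": 3,
        "medullary_carcinoma": 1,
        "others": 4,
    },
    "benign": {
        "fibroadenoma": 26,
        "fibrocystic_changes": 24,
        "fibroadenosis": 3,
        "intraductal_papilloma": 4,
        "hyperplasia": 3,
        "phyllodes_tumor": 2,
        "adenomyosis_epithelioma": 1,
        "inflammation": 1,
        "follow_up": 21,
    },
}


def histopathology_table() -> pd.DataFrame:
    """Histopathology composition with per-group counts and percentages.

    Percentages are recomputed from the raw counts (out of the full cohort),
    rounded to two decimals.
    """
    rows = []
    total = sum(sum(v.values()) for v in HISTOPATHOLOGY_COUNTS.values())
    for group, entries in HISTOPATHOLOGY_COUNTS.items():
        group_n = sum(entries.values())
        rows.append(
            {"group": group, "diagnosis": "all", "count": group_n,
             "percentage": round(100.0 * group_n / total, 2)}
        )
        for diagnosis, n in entries.items():
            rows.append(
                {"group": group, "diagnosis": diagnosis, "count": n,
                 "percentage": round(100.0 * n / total, 2)}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# configuration dataclasses
# ---------------------------------------------------------------------------


@dataclass
class ShapeParams:
    """Radial lesion-boundary model r(θ) = R·(1 + a·cos(kθ + φ)) + noise.

    The per-case spike count and amplitude are sampled around the
    configured values (``spike_count_jitter``, ``spike_amplitude_sd``) so
    the two classes overlap in shape, as real benign/malignant masses do.
    """

    mean_radius_px: float = 16.0
    radius_sd_px: float = 2.5
    spike_count: int = 0            # k: mean number of angular spikes
    spike_count_jitter: int = 0     # uniform +- jitter on k per case
    spike_amplitude: float = 0.0    # a: mean fractional radial modulation
    spike_amplitude_sd: float = 0.0
    boundary_noise: float = 0.0     # sd of smooth random radial perturbation, fraction of R


@dataclass
class KineticParams:
    """Three-point enhancement kinetics of the lesion interior.

    SI_first = SI_pre * (1 + enhancement); SI_last interpolates/extrapolates
    along the post-contrast course via the washout fraction w:
    SI_last = SI_first - w * (SI_first - SI_pre).  w > 0 is washout
    (SER = 1/(1-w) > 1), w < 0 is persistent enhancement (SER < 1).
    """

    si_pre_mean: float = 100.0
    enhancement_fraction: float = 1.0
    enhancement_sd: float = 0.2
    washout_fraction: float = 0.0
    washout_sd: float = 0.15
    noise_sd: float = 0.05  # multiplicative pixel noise, all frames


@dataclass
class TextureParams:
    """Intra-lesion texture field: relative amplitude and spatial scale.

    Per-case values are drawn lognormally around the class means (the
    ``*_sigma`` fields are log-scale sds) so texture heterogeneity is a
    noisy, overlapping marker rather than a deterministic class label.
    """

    intra_lesion_noise_sd: float = 0.05   # relative sd of the texture field
    noise_sd_sigma: float = 0.0           # lognormal spread of the per-case sd
    correlation_length_px: float = 2.0    # Gaussian smoothing length of the field
    corr_len_sigma: float = 0.0           # lognormal spread of the per-case length


@dataclass
class ADCParams:
    """ADC distribution, units 1e-3 mm^2/s."""

    mean: float = 1.5
    sd: float = 0.15


@dataclass
class AgeParams:
    mean: float = 46.0
    sd: float = 10.9
    lower: float = 18.0
    upper: float = 78.0


def _default_benign_shape() -> ShapeParams:
    # smooth, near-elliptical to mildly lobulated outlines
    return ShapeParams(mean_radius_px=16.0, radius_sd_px=2.5,
                       spike_count=5, spike_count_jitter=3,
                       spike_amplitude=0.07, spike_amplitude_sd=0.04,
                       boundary_noise=0.025)


def _default_malignant_shape() -> ShapeParams:
    # somewhat more spiculated on average; wide overlap with the benign
    # range, as in cohorts where shape alone is a weak discriminator
    return ShapeParams(mean_radius_px=16.0, radius_sd_px=2.5,
                       spike_count=7, spike_count_jitter=3,
                       spike_amplitude=0.10, spike_amplitude_sd=0.05,
                       boundary_noise=0.03)


def _default_benign_kinetics() -> KineticParams:
    # persistent-enhancement regime: mean SER ≈ 1/(1+0.30) ≈ 0.77
    return KineticParams(si_pre_mean=100.0, enhancement_fraction=0.85,
                         enhancement_sd=0.40, washout_fraction=-0.30,
                         washout_sd=0.45, noise_sd=0.05)


def _default_malignant_kinetics() -> KineticParams:
    # washout regime: mean SER ≈ 1/(1-0.15) ≈ 1.18; wide overlap with benign
    return KineticParams(si_pre_mean=100.0, enhancement_fraction=1.10,
                         enhancement_sd=0.40, washout_fraction=0.15,
                         washout_sd=0.45, noise_sd=0.05)


@dataclass
class PhantomConfig:
    """Cohort-level phantom configuration.

    Defaults reproduce the emulated study conditions: 234 cases with a
    149/234 malignant fraction, malignant ADC centred at 1.0e-3 mm²/s versus
    benign 1.7e-3 mm²/s, washout versus persistent kinetics, higher malignant
    texture heterogeneity and boundary spiculation, and older malignant
    patients (population mean age ≈ 46, range 18–78).
    """

    n_cases: int = 234
    malignant_fraction: float = 149.0 / 234.0
    image_size: int = 128
    pixel_spacing_mm: float = 1.0
    seed: int = 0
    benign_shape: ShapeParams = field(default_factory=_default_benign_shape)
    malignant_shape: ShapeParams = field(default_factory=_default_malignant_shape)
    benign_kinetics: KineticParams = field(default_factory=_default_benign_kinetics)
    malignant_kinetics: KineticParams = field(default_factory=_default_malignant_kinetics)
    benign_texture: TextureParams = field(
        default_factory=lambda: TextureParams(0.055, 0.35, 2.5, 0.30))
    malignant_texture: TextureParams = field(
        default_factory=lambda: TextureParams(0.095, 0.35, 2.5, 0.30))
    benign_adc: ADCParams = field(default_factory=lambda: ADCParams(1.7, 0.40))
    malignant_adc: ADCParams = field(default_factory=lambda: ADCParams(1.0, 0.35))
    # class-weighted mean ≈ 46.4 y, matching the emulated cohort's 46.2 ± 10.9
    benign_age: AgeParams = field(default_factory=lambda: AgeParams(40.0, 11.0))
    malignant_age: AgeParams = field(default_factory=lambda: AgeParams(50.0, 11.0))
    # background (normal fibroglandular) tissue: flat kinetics, higher ADC
    background_si: tuple[float, float, float] = (60.0, 70.0, 74.0)
    background_adc: float = 2.0
    background_s0: float = 300.0
    lesion_s0: float = 500.0
    b_high: float = 800.0  # s/mm^2
    roi_margin_px: int = 6

    def validate(self) -> list[str]:
        """Return the exhaustive list of invariant violations (empty if valid)."""
        errs = []
        if self.n_cases < 20:
            errs.append("n_cases must be >= 20 (10-fold CV infeasible below)")
        if not (0.0 < self.malignant_fraction < 1.0):
            errs.append("malignant_fraction must lie in (0, 1)")
        if self.image_size < 64:
            errs.append("image_size must be >= 64")
        if self.pixel_spacing_mm <= 0:
            errs.append("pixel_spacing_mm must be > 0")
        for name in ("benign_adc", "malignant_adc"):
            p = getattr(self, name)
            if p.mean <= 0:
                errs.append(f"{name}.mean must be > 0")
            if p.sd < 0:
                errs.append(f"{name}.sd must be >= 0")
        for name in ("benign_kinetics", "malignant_kinetics"):
            p = getattr(self, name)
            if p.noise_sd < 0 or p.enhancement_sd < 0 or p.washout_sd < 0:
                errs.append(f"{name}: standard deviations must be >= 0")
            if p.si_pre_mean <= 0:
                errs.append(f"{name}.si_pre_mean must be > 0")
        for name in ("benign_texture", "malignant_texture"):
            if getattr(self, name).intra_lesion_noise_sd < 0:
                errs.append(f"{name}.intra_lesion_noise_sd must be >= 0")
        for name in ("benign_age", "malignant_age"):
            p = getattr(self, name)
            if p.sd < 0:
                errs.append(f"{name}.sd must be >= 0")
            if p.lower >= p.upper:
                errs.append(f"{name}: truncation bounds must satisfy lower < upper")
        if self.b_high <= 0:
            errs.append("b_high must be > 0")
        return errs

    def require_valid(self) -> "PhantomConfig":
        errs = self.validate()
        if errs:
            raise ValueError("invalid PhantomConfig: " + "; ".join(errs))
        return self


# ---------------------------------------------------------------------------
# per-case containers
# ---------------------------------------------------------------------------


@dataclass
class DynamicSeries:
    """Three-frame dynamic contrast-enhanced series."""

    pre: np.ndarray
    first: np.ndarray
    last: np.ndarray
    pixel_spacing_mm: float

    @property
    def frames(self) -> dict[str, np.ndarray]:
        return {"pre": self.pre, "first": self.first, "last": self.last}


@dataclass
class DWIPair:
    """Diffusion-weighted pair at b = 0 and b = b_high s/mm^2."""

    b0: np.ndarray
    b_high_image: np.ndarray
    b_high: float
    pixel_spacing_mm: float


@dataclass
class CasePhantom:
    case_id: str
    label: str  # "benign" | "malignant"
    true_contour: np.ndarray  # (n, 2) float, (row, col), implicitly closed
    true_adc_mean: float      # 1e-3 mm^2/s
    true_kinetics: tuple[float, float, float]  # (SI_pre, SI_first, SI_last)
    age: float
    roi_box: tuple[int, int, int, int]  # (r0, c0, r1, c1), half-open
    render_seed: int = 0
    texture: TextureParams = field(default_factory=TextureParams)
    noise_sd: float = 0.05

    def validate(self, image_size: int) -> list[str]:
        errs = []
        r0, c0, r1, c1 = self.roi_box
        rows, cols = self.true_contour[:, 0], self.true_contour[:, 1]
        if rows.min() < r0 or rows.max() > r1 - 1 or cols.min() < c0 or cols.max() > c1 - 1:
            errs.append("roi_box does not contain true_contour")
        if rows.min() < 0 or cols.min() < 0 or rows.max() > image_size - 1 or cols.max() > image_size - 1:
            errs.append("lesion exceeds image bounds")
        return errs


@dataclass
class CohortCase:
    phantom: CasePhantom
    series: DynamicSeries
    dwi: DWIPair


@dataclass
class Cohort:
    config: PhantomConfig
    cases: list[CohortCase]
    truth: pd.DataFrame  # case_id, label, age, true_adc, area_px

    def __len__(self) -> int:
        return len(self.cases)


# ---------------------------------------------------------------------------
# lesion geometry
# ---------------------------------------------------------------------------


def make_lesion_shape(
    label: str,
    shape_params: ShapeParams,
    rng: np.random.Generator,
    n_vertices: int = 96,
    radius_px: float | None = None,
    center: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Sample one closed lesion-boundary polygon.

    The boundary is a radial function of angle,
    ``r(θ) = R·(1 + a·cos(kθ + φ)) + ε(θ)``, with k spikes of fractional
    amplitude a and a smooth random perturbation ε.  Benign parameter sets
    use low k/a (near-elliptical outline); malignant sets use high k/a
    (spiculated, star-shaped outline).

    Returns an (n_vertices, 2) array of (row, col) vertices; the polygon is
    implicitly closed (last vertex connects back to the first) and simple by
    construction as long as the radial function stays positive.
    """
    if label not in ("benign", "malignant"):
        raise ValueError(f"unknown class label: {label!r}")
    if shape_params.spike_count < 0:
        raise ValueError("spike_count must be >= 0")
    R = float(shape_params.mean_radius_px if radius_px is None else radius_px)
    if R < 5.0:
        raise ValueError(f"degenerate lesion radius {R:.2f} px (< 5 px)")

    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    r = R * (1.0 + shape_params.spike_amplitude
             * np.cos(shape_params.spike_count * theta + phase))
    if shape_params.boundary_noise > 0:
        # smooth perturbation from a handful of low-order random harmonics
        eps = np.zeros_like(theta)
        for harmonic in range(2, 6):
            eps += (rng.normal(0.0, 1.0) * np.cos(harmonic * theta)
                    + rng.normal(0.0, 1.0) * np.sin(harmonic * theta))
        eps *= shape_params.boundary_noise * R / np.sqrt(8.0)
        r = r + eps
    r = np.maximum(r, 2.0)  # keep the radial function positive -> simple polygon
    rows = center[0] + r * np.sin(theta)
    cols = center[1] + r * np.cos(theta)
    return np.column_stack([rows, cols])


def _texture_field(shape: tuple[int, int], params: TextureParams,
                   rng: np.random.Generator) -> np.ndarray:
    """Unit-sd spatially correlated Gaussian field, scaled by the noise sd."""
    if params.intra_lesion_noise_sd <= 0:
        return np.zeros(shape)
    g = rng.normal(0.0, 1.0, size=shape)
    if params.correlation_length_px > 0:
        g = gaussian_filter(g, params.correlation_length_px, mode="reflect")
        sd = g.std()
        if sd > 0:
            g = g / sd
    return params.intra_lesion_noise_sd * g


def render_case(phantom: CasePhantom, config: PhantomConfig) -> tuple[DynamicSeries, DWIPair]:
    """Render the dynamic series and diffusion pair of one phantom case.

    Inside the lesion the three dynamic frames follow the case's planted
    kinetics modulated by a multiplicative intra-lesion texture field;
    background tissue follows the flat configured background course.  The
    diffusion pair satisfies ``S_b = S_0 · exp(-b · ADC)`` pixelwise before
    noise, with ADC in mm²/s (the stored values are in 1e-3 mm²/s).
    Fully deterministic given the phantom's render seed.
    """
    errs = phantom.validate(config.image_size)
    if errs:
        raise ValueError(f"cannot render case {phantom.case_id}: " + "; ".join(errs))
    n = config.image_size
    shape = (n, n)
    rng = np.random.default_rng(phantom.render_seed)
    mask = polygon2mask(shape, phantom.true_contour)
    if not mask.any():
        raise ValueError(f"case {phantom.case_id}: empty lesion raster")

    si_pre, si_first, si_last = phantom.true_kinetics
    bg_pre, bg_first, bg_last = config.background_si
    tex = 1.0 + _texture_field(shape, phantom.texture, rng)

    frames = []
    for si_lesion, si_bg in ((si_pre, bg_pre), (si_first, bg_first), (si_last, bg_last)):
        img = np.full(shape, si_bg, dtype=float)
        img[mask] = si_lesion * tex[mask]
        if phantom.noise_sd > 0:
            img = img * (1.0 + phantom.noise_sd * rng.normal(0.0, 1.0, size=shape))
        frames.append(np.maximum(img, 0.0))
    series = DynamicSeries(frames[0], frames[1], frames[2], config.pixel_spacing_mm)

    s0 = np.full(shape, config.background_s0, dtype=float)
    s0[mask] = config.lesion_s0 * tex[mask]
    adc_map = np.full(shape, config.background_adc, dtype=float)  # 1e-3 mm^2/s
    adc_map[mask] = phantom.true_adc_mean
    sb = s0 * np.exp(-config.b_high * adc_map * 1e-3)
    if phantom.noise_sd > 0:
        s0 = s0 * (1.0 + phantom.noise_sd * rng.normal(0.0, 1.0, size=shape))
        sb = sb * (1.0 + phantom.noise_sd * rng.normal(0.0, 1.0, size=shape))
    dwi = DWIPair(np.maximum(s0, 1e-6), np.maximum(sb, 1e-6),
                  config.b_high, config.pixel_spacing_mm)
    return series, dwi


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


def _truncated_normal(mean: float, sd: float, lo: float, hi: float,
                      rng: np.random.Generator) -> float:
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def _class_params(config: PhantomConfig, label: str):
    p = "malignant" if label == "malignant" else "benign"
    return (getattr(config, f"{p}_shape"), getattr(config, f"{p}_kinetics"),
            getattr(config, f"{p}_texture"), getattr(config, f"{p}_adc"),
            getattr(config, f"{p}_age"))


def sample_case(label: str, case_id: str, config: PhantomConfig,
                rng: np.random.Generator) -> CasePhantom:
    """Sample one case's geometry, kinetics, ADC and age (no rendering)."""
    shape_p, kin_p, tex_p, adc_p, age_p = _class_params(config, label)
    n = config.image_size
    radius = max(6.0, rng.normal(shape_p.mean_radius_px, shape_p.radius_sd_px))
    # per-case shape realization: spike depth and count vary within class
    amp = max(0.0, rng.normal(shape_p.spike_amplitude, shape_p.spike_amplitude_sd))
    jit = shape_p.spike_count_jitter
    spikes = max(0, shape_p.spike_count + int(rng.integers(-jit, jit + 1))) if jit else shape_p.spike_count
    case_shape = dataclasses.replace(shape_p, spike_amplitude=amp, spike_count=spikes)
    max_r = radius * (1.0 + amp + 4.0 * shape_p.boundary_noise) + 2.0
    margin = max_r + config.roi_margin_px + 1
    if 2 * margin >= n:
        raise ValueError(
            f"lesion (max radius {max_r:.1f} px) cannot fit a {n}x{n} image with margin")
    cr = rng.uniform(margin, n - margin)
    cc = rng.uniform(margin, n - margin)
    contour = make_lesion_shape(label, case_shape, rng, radius_px=radius, center=(cr, cc))

    si_pre = kin_p.si_pre_mean
    enh = max(0.05, rng.normal(kin_p.enhancement_fraction, kin_p.enhancement_sd))
    wash = rng.normal(kin_p.washout_fraction, kin_p.washout_sd)
    wash = float(np.clip(wash, -0.9, 0.9))
    si_first = si_pre * (1.0 + enh)
    si_last = si_first - wash * (si_first - si_pre)

    adc = max(0.2, rng.normal(adc_p.mean, adc_p.sd))
    age = _truncated_normal(age_p.mean, age_p.sd, age_p.lower, age_p.upper, rng)

    # per-case texture realization (lognormal around the class means)
    tex_sd = tex_p.intra_lesion_noise_sd * float(
        np.exp(rng.normal(0.0, tex_p.noise_sd_sigma))) if tex_p.intra_lesion_noise_sd > 0 else 0.0
    tex_len = tex_p.correlation_length_px * float(
        np.exp(rng.normal(0.0, tex_p.corr_len_sigma)))
    case_texture = dataclasses.replace(
        tex_p, intra_lesion_noise_sd=tex_sd, correlation_length_px=tex_len,
        noise_sd_sigma=0.0, corr_len_sigma=0.0)

    r0 = int(np.floor(contour[:, 0].min())) - config.roi_margin_px
    c0 = int(np.floor(contour[:, 1].min())) - config.roi_margin_px
    r1 = int(np.ceil(contour[:, 0].max())) + config.roi_margin_px + 1
    c1 = int(np.ceil(contour[:, 1].max())) + config.roi_margin_px + 1
    roi = (max(r0, 0), max(c0, 0), min(r1, n), min(c1, n))

    return CasePhantom(
        case_id=case_id,
        label=label,
        true_contour=contour,
        true_adc_mean=adc,
        true_kinetics=(si_pre, si_first, si_last),
        age=age,
        roi_box=roi,
        render_seed=int(rng.integers(0, 2**31 - 1)),
        texture=case_texture,
        noise_sd=kin_p.noise_sd,
    )


def generate_cohort(config: PhantomConfig) -> Cohort:
    """Generate and render a full phantom cohort.

    Class counts are the rounding of ``malignant_fraction * n_cases``; case
    order is a seeded shuffle so folds see both classes everywhere.  Bitwise
    reproducible for a fixed config (including seed).
    """
    config.require_valid()
    rng = np.random.default_rng(config.seed)
    n_mal = int(round(config.malignant_fraction * config.n_cases))
    n_ben = config.n_cases - n_mal
    labels = ["malignant"] * n_mal + ["benign"] * n_ben
    order = rng.permutation(config.n_cases)
    cases: list[CohortCase] = []
    rows = []
    for i, idx in enumerate(order):
        label = labels[idx]
        case_id = f"case_{i:04d}"
        phantom = sample_case(label, case_id, config, rng)
        series, dwi = render_case(phantom, config)
        mask = polygon2mask((config.image_size,) * 2, phantom.true_contour)
        cases.append(CohortCase(phantom, series, dwi))
        rows.append({
            "case_id": case_id,
            "label": label,
            "age": phantom.age,
            "true_adc": phantom.true_adc_mean,
            "area_px": int(mask.sum()),
        })
    truth = pd.DataFrame(rows)
    return Cohort(config=config, cases=cases, truth=truth)


# ---------------------------------------------------------------------------
# tabular companion generator (no imaging)
# ---------------------------------------------------------------------------


def sample_feature_table(
    n_cases: int = 234,
    n_informative: int = 24,
    n_noise: int = 4,
    effect_size: float = 0.8,
    malignant_fraction: float = 149.0 / 234.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Draw a Gaussian feature table with planted class differences.

    A fast tabular companion to the imaging phantom for experiments that
    probe the selection statistics directly (filter type-I-error calibration,
    wrapper recovery at scale): ``n_informative`` features differ between
    classes by ``effect_size`` standard deviations, ``n_noise`` features are
    pure noise.  Returns (features, labels, noise feature names).
    """
    rng = np.random.default_rng(seed)
    n_mal = int(round(malignant_fraction * n_cases))
    y = pd.Series(["malignant"] * n_mal + ["benign"] * (n_cases - n_mal), name="label")
    p = n_informative + n_noise
    X = rng.normal(0.0, 1.0, size=(n_cases, p))
    X[:n_mal, :n_informative] += effect_size
    names = [f"signal_{i:02d}" for i in range(n_informative)] + \
            [f"noise_{i:02d}" for i in range(n_noise)]
    return pd.DataFrame(X, columns=names), y, names[n_informative:]
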