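import dataclasses
import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from breastmri.phantom import (CasePhantom, PhantomConfig, TextureParams,
                               generate_cohort, make_lesion_shape, ShapeParams)


def noiseless_config(n_cases=20, image_size=96, seed=2, **kw) -> PhantomConfig:
    """Default phantom config with all pixel/texture noise switched off."""
    cfg = PhantomConfig(n_cases=n_cases, image_size=image_size, seed=seed, **kw)
    for attr in ("benign_kinetics", "malignant_kinetics"):
        setattr(cfg, attr, dataclasses.replace(getattr(cfg, attr), noise_sd=0.0))
    for attr in ("benign_texture", "malignant_texture"):
        setattr(cfg, attr, dataclasses.replace(
            getattr(cfg, attr), intra_lesion_noise_sd=0.0, noise_sd_sigma=0.0))
    return cfg


def circle_phantom(radius=20.0, image_size=96, si=(100.0, 250.0, 175.0),
                   adc=1.5, noise_sd=0.0, tex_sd=0.0, case_id="circle",
                   label="benign", age=45.0, seed=0) -> CasePhantom:
    """A hand-built circular lesion phantom at the image centre."""
    c = image_size / 2.0
    rng = np.random.default_rng(seed)
    contour = make_lesion_shape(label, ShapeParams(mean_radius_px=radius),
                                rng, radius_px=radius, center=(c, c))
    m = int(radius) + 8
    return CasePhantom(
        case_id=case_id, label=label, true_contour=contour,
        true_adc_mean=adc, true_kinetics=si, age=age,
        roi_box=(int(c - m), int(c - m), int(c + m) + 1, int(c + m) + 1),
        render_seed=seed,
        texture=TextureParams(intra_lesion_noise_sd=tex_sd),
        noise_sd=noise_sd)


@pytest.fixture(scope="session")
def small_cohort():
    """Default-noise 20-case cohort shared across tests."""
    return generate_cohort(PhantomConfig(n_cases=20, image_size=96, seed=1))


@pytest.fixture(scope="session")
def noiseless_cohort():
    return generate_cohort(noiseless_config(n_cases=20, seed=2))
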