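"""Kinetic, morphological, texture and ADC features; table assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import breastmri as bm
from breastmri.diffusion import adc_features
from breastmri.features import (FEATURE_GROUPS, FEATURE_NAMES, assemble_features,
                                canonical_name, extract_case, feature_group)
from breastmri.kinetics import kinetic_features
from breastmri.morphology import morphological_features
from breastmri.phantom import DWIPair, DynamicSeries, render_case
from breastmri.segmentation import LesionGeometry
from breastmri.texture import GLCMSpec, build_glcm, haralick_features

from conftest import circle_phantom, noiseless_config
from oracles import glcm_brute, haralick_brute


def _series(pre, first, last, spacing=1.0):
    return DynamicSeries(np.asarray(pre, float), np.asarray(first, float),
                         np.asarray(last, float), spacing)


class TestKinetics:
    @pytest.mark.parametrize("si,expected", [
        ((100.0, 250.0, 175.0), (1.5, 2.0)),   # washout regime
        ((100.0, 100.0, 140.0), (0.0, 0.0)),   # no early enhancement
        ((100.0, 250.0, 250.0), (1.5, 1.0)),   # plateau boundary
    ])
    def test_closed_forms(self, si, expected):
        img = lambda v: np.full((4, 4), v)
        series = _series(img(si[0]), img(si[1]), img(si[2]))
        mask = np.ones((4, 4), bool)
        kin = kinetic_features(series, mask)
        assert (kin.slope, kin.ser) == pytest.approx(expected)

    def test_nonpositive_baseline_rejected(self):
        series = _series(np.zeros((4, 4)), np.ones((4, 4)), np.ones((4, 4)))
        with pytest.raises(ValueError, match="pre-contrast"):
            kinetic_features(series, np.ones((4, 4), bool))

    def test_vanishing_ser_denominator_flagged(self):
        img = lambda v: np.full((4, 4), v)
        series = _series(img(100.0), img(250.0), img(100.0))
        kin = kinetic_features(series, np.ones((4, 4), bool))
        assert not kin.ser_defined and np.isnan(kin.ser)


class TestMorphology:
    def _geom_disk(self, radius=20.0, n=96):
        ph = circle_phantom(radius=radius, image_size=n)
        return LesionGeometry.from_contour((n, n), ph.true_contour)

    def test_disk_descriptors(self):
        geom = self._geom_disk()
        img = np.ones(geom.mask.shape)
        m = morphological_features(geom, 1.0, img)
        assert m.circularity >= 0.95
        assert m.solidity >= 0.98
        assert m.eccentricity <= 0.1
        assert m.elongation <= 1.05
        assert m.radial_length_entropy <= 0.5
        assert m.area == pytest.approx(np.pi * 400, rel=0.02)
        assert m.compactness == pytest.approx(1.0 / m.circularity, rel=1e-9)
        assert 1.0 <= m.fractal_dimension <= 2.0

    def test_star_spiculation_counts_crossings_exactly(self):
        t = np.linspace(0, 2 * np.pi, 96, endpoint=False)
        r = 20.0 * (1 + 0.3 * np.cos(8 * t))
        contour = np.column_stack([48 + r * np.sin(t), 48 + r * np.cos(t)])
        geom = LesionGeometry.from_contour((96, 96), contour)
        m = morphological_features(geom, 1.0, np.ones((96, 96)))
        assert m.spiculation == pytest.approx(16 / 96)

    def test_rectangle_extent_and_solidity_are_one(self):
        contour = np.array([[20.0, 20.0], [20.0, 60.0], [50.0, 60.0], [50.0, 20.0]])
        geom = LesionGeometry.from_contour((96, 96), contour)
        m = morphological_features(geom, 1.0, np.ones((96, 96)))
        assert m.extent == pytest.approx(1.0)
        assert m.solidity == pytest.approx(1.0)

    def test_doubling_spacing_quadruples_area_and_keeps_shape(self):
        geom = self._geom_disk()
        img = np.ones(geom.mask.shape)
        m1 = morphological_features(geom, 1.0, img)
        m2 = morphological_features(geom, 2.0, img)
        assert m2.area == pytest.approx(4 * m1.area, rel=1e-12)
        for name in ("circularity", "solidity", "extent"):
            assert getattr(m2, name) == pytest.approx(getattr(m1, name), rel=0.02)

    def test_invalid_spacing_rejected(self):
        with pytest.raises(ValueError):
            morphological_features(self._geom_disk(), 0.0, np.ones((96, 96)))


class TestGLCM:
    def test_two_pixel_pairs_hand_enumeration(self):
        img = np.array([[0.0, 0.0], [1.0, 1.0]])
        spec = GLCMSpec(n_levels=2, offsets=((0, 1),), symmetric=True)
        P = build_glcm(img, np.ones((2, 2), bool), spec)
        np.testing.assert_allclose(P, [[0.5, 0.0], [0.0, 0.5]])

    def test_constant_image_single_cell(self):
        P = build_glcm(np.full((4, 4), 7.0), np.ones((4, 4), bool), GLCMSpec())
        assert P[0, 0] == pytest.approx(1.0)
        assert P.sum() == pytest.approx(1.0)

    def test_mask_restricts_pairs(self):
        img = np.array([[0.0, 0.0, 9.0], [0.0, 0.0, 9.0]])
        mask = np.array([[True, True, False], [True, True, False]])
        P = build_glcm(img, mask, GLCMSpec(n_levels=2))
        assert P[0, 0] == pytest.approx(1.0)  # the bright column never pairs

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_glcm_always_symmetric_and_normalized(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.random((8, 8))
        mask = rng.random((8, 8)) > 0.3
        if mask.sum() < 4:
            mask[:2, :2] = True
        P = build_glcm(img, mask, GLCMSpec(n_levels=8))
        np.testing.assert_allclose(P, P.T, atol=1e-15)
        assert P.sum() == pytest.approx(1.0)


class TestHaralick:
    def test_uniform_two_level_matrix(self):
        P = np.full((2, 2), 0.25)
        f = haralick_features(P)
        assert f.asm == pytest.approx(0.25)
        assert f.entropy == pytest.approx(2.0)
        assert f.contrast == pytest.approx(0.5)
        assert f.inverse_difference == pytest.approx(0.75)

    def test_degenerate_single_cell_matrix(self):
        P = np.zeros((4, 4))
        P[1, 1] = 1.0
        f = haralick_features(P)
        assert f.asm == 1.0 and f.entropy == 0.0
        assert f.contrast == 0.0 and f.inverse_difference == 1.0

    def test_unnormalized_matrix_rejected(self):
        with pytest.raises(ValueError):
            haralick_features(np.ones((3, 3)))

    def test_matches_brute_force_oracle_on_random_masked_images(self):
        rng = np.random.default_rng(42)
        spec = GLCMSpec(n_levels=8)
        for _ in range(15):
            img = rng.random((8, 8)) * rng.uniform(1, 100)
            mask = rng.random((8, 8)) > 0.25
            if mask.sum() < 4:
                continue
            P = build_glcm(img, mask, spec)
            P_ref = glcm_brute(img, mask, 8, spec.offsets)
            np.testing.assert_allclose(P, P_ref, atol=1e-12)
            ours = haralick_features(P).as_dict()
            ref = haralick_brute(P)
            for name, val in ref.items():
                assert ours[name] == pytest.approx(val, abs=1e-10), name


class TestADC:
    def _pair(self, s0, sb, spacing=1.0):
        return DWIPair(np.asarray(s0, float), np.asarray(sb, float), 800.0, spacing)

    def test_uniform_decay_inverts_to_planted_adc(self):
        s0 = np.full((10, 10), 1000.0)
        dwi = self._pair(s0, s0 * np.exp(-0.8 * 1.5))
        mask = np.zeros((10, 10), bool)
        mask[2:8, 2:8] = True
        res = adc_features(dwi, mask)
        assert res.mean_adc == pytest.approx(1.5, abs=1e-4)

    def test_no_decay_gives_zero_adc(self):
        s0 = np.full((8, 8), 500.0)
        dwi = self._pair(s0, s0.copy())
        mask = np.ones((8, 8), bool)
        mask[0, 0] = False
        res = adc_features(dwi, mask)
        assert np.nanmax(np.abs(res.adc_map)) == pytest.approx(0.0, abs=1e-12)

    def test_small_high_signal_region_flagged_invalid(self):
        # bright 19-pixel region at 1 mm spacing -> 19 mm^2 < 20 mm^2
        s0 = np.full((16, 16), 1000.0)
        sb = np.full((16, 16), 10.0)
        mask = np.zeros((16, 16), bool)
        mask.ravel()[:19] = True
        sb[mask] = 400.0  # bright against the background band
        res = adc_features(self._pair(s0, sb), mask)
        assert res.roi_area_mm2 == pytest.approx(19.0)
        assert not res.valid

    def test_planted_adc_recovered_from_rendered_case(self):
        cfg = noiseless_config()
        ph = circle_phantom(adc=1.23)
        _, dwi = render_case(ph, cfg)
        geom = LesionGeometry.from_contour((96, 96), ph.true_contour)
        res = adc_features(dwi, geom.mask)
        assert res.valid
        assert abs(res.mean_adc - 1.23) / 1.23 < 0.01


class TestAssembly:
    def test_registry_group_sizes(self):
        sizes = {g: len(names) for g, names in FEATURE_GROUPS.items()}
        assert sizes == {"pathology": 1, "kinetic": 2, "morphology": 11,
                         "texture": 13, "dwi": 1}
        assert len(FEATURE_NAMES) == 28

    @pytest.mark.parametrize("alias,canonical", [
        ("Energy", "asm"), ("Inertia", "contrast"),
        ("Rectangular degree", "extent"),
        ("Inverse Difference", "inverse_difference"),
        ("Information Correlation 1", "info_correlation_1"),
        ("Entropy of Radial Length Distribution", "radial_length_entropy"),
    ])
    def test_literature_aliases_resolve(self, alias, canonical):
        assert canonical_name(alias) == canonical
        assert feature_group(alias) == feature_group(canonical)

    def test_extract_case_produces_all_28(self, small_cohort):
        case = small_cohort.cases[0]
        shape = (small_cohort.config.image_size,) * 2
        geom = LesionGeometry.from_contour(shape, case.phantom.true_contour)
        row, valid = extract_case(case.series, case.dwi, geom,
                                  case.phantom.age, 1.0)
        assert valid
        assert sorted(row) == sorted(FEATURE_NAMES)

    def test_cohort_table_shape_and_labels(self, small_cohort):
        table = bm.extract_cohort_features(
            small_cohort, bm.ExtractionConfig(use_segmentation=False))
        assert table.shape == (20, 30)  # case_id + label + 28
        assert set(table.label) == {"benign", "malignant"}

    def test_duplicate_case_id_rejected(self):
        row = {name: 1.0 for name in FEATURE_NAMES}
        rows = [dict(row, case_id="a", label="benign"),
                dict(row, case_id="a", label="malignant")]
        with pytest.raises(ValueError, match="duplicate"):
            assemble_features(rows)

    def test_missing_feature_column_rejected(self):
        row = {name: 1.0 for name in FEATURE_NAMES[:-1]}
        with pytest.raises(ValueError, match="missing"):
            assemble_features([dict(row, case_id="a", label="benign")])


class TestRotationInvariance:
    def test_quarter_turn_changes_little(self, small_cohort):
        case = small_cohort.cases[0]
        shape = (small_cohort.config.image_size,) * 2
        geom = LesionGeometry.from_contour(shape, case.phantom.true_contour)
        img = case.series.first
        n = shape[0]
        # rotate image, mask and contour by 90 degrees
        img_r = np.rot90(img).copy()
        contour_r = np.column_stack([n - 1 - case.phantom.true_contour[:, 1],
                                     case.phantom.true_contour[:, 0]])
        geom_r = LesionGeometry.from_contour(shape, contour_r)

        tex = haralick_features(build_glcm(img, geom.mask)).as_dict()
        tex_r = haralick_features(build_glcm(img_r, geom_r.mask)).as_dict()
        for name, val in tex.items():
            assert tex_r[name] == pytest.approx(val, rel=0.01, abs=1e-6), name

        m = morphological_features(geom, 1.0, img).as_dict()
        m_r = morphological_features(geom_r, 1.0, img_r).as_dict()
        for name in ("area", "circularity", "solidity", "extent",
                     "eccentricity", "elongation", "compactness",
                     "spiculation", "radial_length_entropy", "heterogeneity"):
            assert m_r[name] == pytest.approx(m[name], rel=0.02, abs=1e-6), name
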