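"""Stain normalization, cropping, blank-patch QC and fold assignment."""

import numpy as np
import pytest

from dieanet.preprocessing import (
    CaseRecord, DegenerateStainError, InsufficientTissueError, StainBasis,
    assign_folds, blank_fraction, estimate_stain_basis, fit_concentrations,
    normalize_stain, od_to_rgb, qc_pass, random_crops, rgb_to_od,
)
from dieanet.synthetic import CANONICAL_HE_BASIS, SynthSpec, synth_image


class TestOpticalDensity:
    def test_white_maps_to_zero(self):
        img = np.full((2, 2, 3), 255, np.uint8)
        np.testing.assert_allclose(rgb_to_od(img), 0.0)

    def test_decade_value(self):
        img = np.full((1, 1, 3), 25.5)
        np.testing.assert_allclose(rgb_to_od(img), 1.0, atol=1e-12)

    def test_round_trip(self, rng):
        img = rng.integers(1, 256, size=(8, 8, 3)).astype(np.uint8)
        np.testing.assert_array_equal(od_to_rgb(rgb_to_od(img)), img)

    def test_rejects_non_rgb(self):
        with pytest.raises(ValueError):
            rgb_to_od(np.zeros((4, 4)))


def _two_stain_image(rng, n=128, basis=None):
    """Synthesize directly from known sparse concentrations."""
    basis = basis or CANONICAL_HE_BASIS
    ch = np.where(rng.random((n, n)) < 0.25, rng.uniform(0.4, 1.2, (n, n)), 0.0)
    ce = np.where(rng.random((n, n)) < 0.25, rng.uniform(0.3, 0.9, (n, n)), 0.0)
    od = ch[..., None] * basis.W[:, 0] + ce[..., None] * basis.W[:, 1]
    return od_to_rgb(od)


class TestStainBasis:
    def test_recovers_known_basis(self, rng):
        img = _two_stain_image(rng)
        basis = estimate_stain_basis(img, seed=3)
        for i in range(2):
            cos = abs(basis.W[:, i] @ CANONICAL_HE_BASIS.W[:, i])
            assert cos >= 0.99
        np.testing.assert_allclose(np.linalg.norm(basis.W, axis=0), 1.0, atol=1e-9)

    def test_single_stain_image_flagged(self, rng):
        ch = np.where(rng.random((128, 128)) < 0.4, rng.uniform(0.4, 1.2, (128, 128)), 0.0)
        od = ch[..., None] * CANONICAL_HE_BASIS.W[:, 0]
        with pytest.raises(DegenerateStainError):
            estimate_stain_basis(od_to_rgb(od), seed=3)

    def test_blank_image_rejected(self):
        img = np.full((128, 128, 3), 255, np.uint8)
        with pytest.raises(InsufficientTissueError):
            estimate_stain_basis(img)

    def test_basis_validation(self):
        with pytest.raises(ValueError):
            StainBasis(W=np.ones((3, 2)))          # columns not unit norm
        with pytest.raises(ValueError):
            StainBasis(W=-CANONICAL_HE_BASIS.W)    # negative entries

    def test_nnls_concentrations_nonnegative_and_exact_in_span(self, rng):
        basis = CANONICAL_HE_BASIS
        c_true = rng.uniform(0, 1.5, (500, 2))
        od = c_true @ basis.W.T
        c = fit_concentrations(od, basis)
        np.testing.assert_allclose(c, c_true, atol=1e-10)
        od_noisy = od + rng.normal(0, 0.05, od.shape)
        assert (fit_concentrations(od_noisy, basis) >= 0).all()


class TestNormalizeStain:
    def test_identity_when_target_equals_source(self, rng):
        img = _two_stain_image(rng)
        basis = StainBasis(W=CANONICAL_HE_BASIS.W.copy())
        out = normalize_stain(img, basis, basis)
        assert np.abs(out.astype(int) - img.astype(int)).max() <= 2

    def test_white_background_stays_white(self, rng):
        img = _two_stain_image(rng)
        img[:40] = 255
        src = estimate_stain_basis(img, seed=1)
        tgt = estimate_stain_basis(_two_stain_image(rng), seed=1)
        out = normalize_stain(img, src, tgt)
        assert np.abs(out[:40].astype(int) - 255).max() <= 2

    def test_normalization_reduces_color_spread(self, rng):
        spec = SynthSpec(image_size=(384, 384), basis_jitter=0.08,
                         blank_region_fraction=0.0)
        imgs = [synth_image("high", spec, seed=i)[0] for i in range(10)]
        bases = [estimate_stain_basis(im, seed=1) for im in imgs]
        normed = [normalize_stain(im, b, bases[0]) for im, b in zip(imgs, bases)]

        def spread(ims):
            means = np.array([rgb_to_od(im).reshape(-1, 3).mean(0) for im in ims])
            return means.var(axis=0).sum()

        assert spread(normed) <= 0.5 * spread(imgs)


class TestCropping:
    def test_deterministic_under_seed(self, rng):
        img = rng.integers(0, 255, (400, 500, 3)).astype(np.uint8)
        a = random_crops(img, 3, 256, seed=7)
        b = random_crops(img, 3, 256, seed=7)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_degenerate_source_size(self, rng):
        img = rng.integers(0, 255, (256, 256, 3)).astype(np.uint8)
        crops = random_crops(img, 3, 256, seed=0)
        for c in crops:
            np.testing.assert_array_equal(c, img)

    def test_full_scale_source(self, rng):
        img = np.zeros((1393, 1665, 3), np.uint8)
        crops = random_crops(img, 3, 256, seed=1)
        assert len(crops) == 3 and all(c.shape == (256, 256, 3) for c in crops)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            random_crops(np.zeros((100, 300, 3), np.uint8), 3, 256)


class TestBlankRule:
    def test_extremes(self):
        assert blank_fraction(np.full((10, 10, 3), 255, np.uint8)) == 1.0
        assert blank_fraction(np.zeros((10, 10, 3), np.uint8)) == 0.0
        assert not qc_pass(1.0)
        assert qc_pass(0.0)

    def test_boundary_is_strictly_more_than_75_percent(self):
        patch = np.zeros((10, 10, 3), np.uint8)
        patch[:, :, :] = 10
        flat = patch.reshape(-1, 3)
        flat[:75] = 255                       # exactly 75% white
        assert blank_fraction(patch) == 0.75
        assert qc_pass(blank_fraction(patch))
        flat[75] = 255                        # 76% white
        assert blank_fraction(patch) == 0.76
        assert not qc_pass(blank_fraction(patch))

    def test_threshold_uses_min_channel(self):
        patch = np.full((4, 4, 3), 230, np.uint8)
        patch[..., 2] = 100                   # one dark channel -> not blank
        assert blank_fraction(patch) == 0.0


def _cases(n_per_grade, start=0):
    out = []
    for g, n in zip(("low", "intermediate", "high"), n_per_grade):
        for i in range(n):
            out.append(CaseRecord(f"{g}_{start + i}", g, ["x.png"]))
    return out


class TestFolds:
    def test_stratification_balance(self):
        # the study's case load per grade
        cases = _cases((30, 38, 39))
        fold_of = assign_folds(cases, k=5, seed=3)
        for g, n in (("low", 30), ("intermediate", 38), ("high", 39)):
            sizes = np.bincount([fold_of[c.case_id] for c in cases
                                 if c.grade == g], minlength=5)
            assert sizes.sum() == n
            assert sizes.max() - sizes.min() <= 1

    def test_partition_no_case_in_two_folds(self):
        cases = _cases((6, 7, 8))
        fold_of = assign_folds(cases, k=5, seed=0)
        assert set(fold_of) == {c.case_id for c in cases}

    def test_deterministic(self):
        cases = _cases((6, 7, 8))
        assert assign_folds(cases, 5, seed=9) == assign_folds(cases, 5, seed=9)

    def test_too_few_cases_rejected(self):
        with pytest.raises(ValueError, match="fewer"):
            assign_folds(_cases((3, 6, 6)), k=5)


class TestPipeline:
    def test_manifest_schema_and_leakage(self, mini_pipeline):
        m = mini_pipeline["manifest"]
        assert {"patch_path", "case_id", "grade", "fold", "blank_fraction",
                "qc_pass"} <= set(m.columns)
        assert ((m["blank_fraction"] <= 0.75) == m["qc_pass"]).all()
        # every case sits in exactly one fold
        assert (m.groupby("case_id")["fold"].nunique() == 1).all()

    def test_patch_counts(self, mini_pipeline):
        m = mini_pipeline["manifest"]
        # 15 cases x 2 images x 3 crops
        assert len(m) == 90
        assert m["qc_pass"].sum() > 45        # most patches survive QC

    def test_fold_level_leakage_freedom(self, mini_pipeline):
        m = mini_pipeline["manifest"]
        for f in m["fold"].unique():
            tr = set(m.loc[m["fold"] != f, "case_id"])
            va = set(m.loc[m["fold"] == f, "case_id"])
            assert not (tr & va)
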