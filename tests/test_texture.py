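"""GLCM construction and Haralick features against independent oracles."""

import numpy as np
import pandas as pd
import pytest

from ppsw.texture import (
    FEATURE_NAMES,
    Glcm,
    GlcmSpec,
    compute_glcm,
    extract_features,
    feature_columns,
    haralick_features,
    quantize,
)

OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0)}


def brute_force_glcm(q, d, theta, levels):
    """Enumerate every pixel pair explicitly; symmetrize; normalize."""
    dr, dc = (o * d for o in OFFSETS[theta])
    m, n = q.shape
    counts = np.zeros((levels, levels))
    for y in range(m):
        for x in range(n):
            y2, x2 = y + dr, x + dc
            if 0 <= y2 < m and 0 <= x2 < n:
                counts[q[y, x], q[y2, x2]] += 1
    counts = counts + counts.T
    return counts / counts.sum()


def brute_force_features(p):
    """Double-loop evaluation of the six statistics."""
    g = p.shape[0]
    mu_i = sum(i * p[i, j] for i in range(g) for j in range(g))
    mu_j = sum(j * p[i, j] for i in range(g) for j in range(g))
    var_i = sum((i - mu_i) ** 2 * p[i, j] for i in range(g) for j in range(g))
    var_j = sum((j - mu_j) ** 2 * p[i, j] for i in range(g) for j in range(g))
    asm = sum(p[i, j] ** 2 for i in range(g) for j in range(g))
    con = sum(p[i, j] * (i - j) ** 2 for i in range(g) for j in range(g))
    dis = sum(p[i, j] * abs(i - j) for i in range(g) for j in range(g))
    hom = sum(p[i, j] / (1 + (i - j) ** 2) for i in range(g) for j in range(g))
    cov = sum((i - mu_i) * (j - mu_j) * p[i, j] for i in range(g) for j in range(g))
    cor = 1.0 if var_i * var_j == 0 else cov / np.sqrt(var_i * var_j)
    return {"ASM": asm, "CON": con, "COR": cor, "DIS": dis,
            "ENR": np.sqrt(asm), "HOM": hom}


class TestGlcm:
    def test_two_by_two_horizontal_pairs(self):
        p = compute_glcm(np.array([[0, 0], [1, 1]]), 1, 0, GlcmSpec(levels=2)).p
        np.testing.assert_allclose(p, [[0.5, 0.0], [0.0, 0.5]])

    def test_two_by_two_vertical_pairs(self):
        p = compute_glcm(np.array([[0, 0], [1, 1]]), 1, 90, GlcmSpec(levels=2)).p
        np.testing.assert_allclose(p, [[0.0, 0.5], [0.5, 0.0]])

    def test_constant_image_single_diagonal_cell(self):
        p = compute_glcm(np.full((5, 5), 3.0), 2, 45, GlcmSpec(levels=4)).p
        assert p[0, 0] == 1.0
        assert p.sum() == 1.0

    def test_normalization_and_symmetry_on_random_images(self, rng):
        spec = GlcmSpec(levels=16)
        for _ in range(10):
            q = rng.integers(0, 16, (10, 12))
            g = compute_glcm(q, 2, 45, spec)
            assert abs(g.p.sum() - 1.0) <= 1e-12
            np.testing.assert_allclose(g.p, g.p.T, atol=0)

    def test_matches_skimage_at_axis_aligned_offsets(self, rng):
        from skimage.feature import graycomatrix

        img = rng.integers(0, 8, (16, 16)).astype(np.uint8)
        for d in (1, 3):
            for theta, ang in ((0, 0.0), (90, np.pi / 2)):
                mine = compute_glcm(img, d, theta, GlcmSpec(levels=8)).p
                ref = graycomatrix(img, [d], [ang], levels=8,
                                   symmetric=True, normed=True)[:, :, 0, 0]
                np.testing.assert_allclose(mine, ref, atol=1e-12)

    def test_displacement_beyond_extent_rejected(self):
        with pytest.raises(ValueError, match="no pixel pairs"):
            compute_glcm(np.zeros((3, 3), dtype=int), 5, 90, GlcmSpec(levels=2))

    def test_quantization_spans_levels(self, rng):
        q = quantize(rng.random((20, 20)), 32)
        assert q.min() == 0 and q.max() == 31
        assert np.all(quantize(np.full((4, 4), 7.0), 32) == 0)


class TestHaralick:
    def test_constant_image_limits(self):
        g = compute_glcm(np.full((6, 6), 9.0), 1, 0, GlcmSpec(levels=8))
        f = haralick_features(g)
        assert f == {"ASM": 1.0, "CON": 0.0, "COR": 1.0, "DIS": 0.0, "ENR": 1.0, "HOM": 1.0}

    def test_hand_worked_diagonal_matrix(self):
        g = Glcm(p=np.array([[0.5, 0.0], [0.0, 0.5]]), distance=1, angle=0,
                 symmetric=True, normalized=True)
        f = haralick_features(g)
        assert f["ASM"] == pytest.approx(0.5)
        assert f["ENR"] == pytest.approx(np.sqrt(0.5))
        assert f["CON"] == 0.0 and f["DIS"] == 0.0 and f["HOM"] == 1.0
        assert f["COR"] == pytest.approx(1.0)

    def test_unnormalized_matrix_rejected(self):
        g = Glcm(p=np.array([[2.0, 0.0], [0.0, 2.0]]), distance=1, angle=0,
                 symmetric=True, normalized=False)
        with pytest.raises(ValueError):
            haralick_features(g)

    def test_matches_brute_force_on_random_images(self, rng):
        spec = GlcmSpec(levels=8)
        for _ in range(50):
            q = rng.integers(0, 8, (8, 8))
            for d in spec.distances:
                for theta in spec.angles:
                    ref = brute_force_features(brute_force_glcm(q, d, theta, 8))
                    mine = haralick_features(compute_glcm(q, d, theta, spec))
                    for name in FEATURE_NAMES:
                        assert mine[name] == pytest.approx(ref[name], abs=1e-12)

    def test_feature_ranges_on_random_images(self, rng):
        spec = GlcmSpec(levels=16)
        for _ in range(20):
            q = rng.integers(0, 16, (12, 12))
            f = haralick_features(compute_glcm(q, 1, 45, spec))
            assert 0.0 <= f["ASM"] <= 1.0
            assert 0.0 <= f["ENR"] <= 1.0
            assert 0.0 <= f["HOM"] <= 1.0
            assert f["CON"] >= 0.0 and f["DIS"] >= 0.0
            assert -1.0 <= f["COR"] <= 1.0
            assert f["ENR"] ** 2 == pytest.approx(f["ASM"], abs=1e-12)


class TestExtractFeatures:
    def test_single_image_shape_contract(self, rng):
        table = extract_features([rng.random((32, 32))], density_labels=["low"],
                                 spec=GlcmSpec(levels=32))
        assert len(table) == 1
        assert len(feature_columns()) == 90
        assert [c for c in table.columns if c not in ("density_label", "source_variant")] \
            == feature_columns()

    def test_duplicated_image_gives_identical_rows(self, rng):
        img = rng.random((32, 32))
        table = extract_features([img, img], variant="dftmod_u", spec=GlcmSpec(levels=32))
        pd.testing.assert_series_equal(table.iloc[0], table.iloc[1], check_names=False)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            extract_features([])

    def test_unknown_variant_rejected(self, rng):
        with pytest.raises(ValueError, match="unknown source variant"):
            extract_features([rng.random((16, 16))], variant="dftmod_bogus")

    def test_contrast_separates_density_classes(self):
        """Co-occurrence contrast distributions differ between low- and
        high-density scenes (the density signal GLCM features rely on);
        the sign of the shift is a property of the generator's rendering,
        only the separation is asserted."""
        from scipy.stats import mannwhitneyu

        from ppsw.synth import SceneConfig, generate_scene

        vals = {}
        for density in ("low", "high"):
            imgs = [
                generate_scene(SceneConfig(density_class=density, vignette_strength=0.0,
                                           artifact_set=(), seed=s)).image
                for s in range(30)
            ]
            table = extract_features(imgs, spec=GlcmSpec(levels=64))
            vals[density] = table["CON_d1_a0"].to_numpy()
        assert mannwhitneyu(vals["low"], vals["high"]).pvalue < 0.05
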