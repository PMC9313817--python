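"""Overlap and boundary-distance metrics against independent oracles."""
import numpy as np
import pytest

from muscleseg import BinaryMask, CTSlice, bone_mask, dsc, extract_boundary, remove_bone, rms_dta, sma, smd


def mask(arr, spacing=(1.0, 1.0), role="ground_truth"):
    return BinaryMask(labels=np.asarray(arr, dtype=np.uint8), spacing=spacing, role=role)


def brute_force_dsc(a, b):
    inter = int(np.sum(a.bool() & b.bool()))
    tot = int(a.area_px + b.area_px)
    return 1.0 if tot == 0 else 2.0 * inter / tot


def brute_force_rms_dta(pred, ref):
    """Quadratic all-pairs nearest-distance oracle, in cm."""

    def boundary(m):
        lab = m.bool()
        pts = []
        h, w = lab.shape
        for i in range(h):
            for j in range(w):
                if not lab[i, j]:
                    continue
                edge = i == 0 or i == h - 1 or j == 0 or j == w - 1
                if not edge:
                    edge = not (
                        lab[i - 1, j] and lab[i + 1, j] and lab[i, j - 1] and lab[i, j + 1]
                    )
                if edge:
                    pts.append((i * m.spacing[0], j * m.spacing[1]))
        return pts

    pb, rb = boundary(pred), boundary(ref)
    dists = [min(np.hypot(p[0] - q[0], p[1] - q[1]) for q in rb) for p in pb]
    return float(np.sqrt(np.mean(np.square(dists))) / 10.0)


class TestDSC:
    def test_identical_and_disjoint(self):
        a = mask(np.eye(5))
        assert dsc(a, a) == 1.0
        b = mask(1 - np.eye(5))
        assert dsc(a, b) == 0.0

    def test_subset_counts(self):
        big = np.zeros((20, 20), dtype=int)
        big[:10, :15] = 1  # 150 px
        small = np.zeros((20, 20), dtype=int)
        small[:5, :10] = 1  # 50 px, contained
        assert dsc(mask(small), mask(big)) == pytest.approx(2 * 50 / 200)

    def test_empty_conventions(self):
        e = mask(np.zeros((4, 4)))
        assert dsc(e, e) == 1.0
        assert dsc(e, mask(np.ones((4, 4)))) == 0.0

    def test_symmetry_random_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a = mask(rng.random((12, 12)) < 0.5)
            b = mask(rng.random((12, 12)) < 0.5)
            assert dsc(a, b) == dsc(b, a)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            dsc(mask(np.ones((3, 3))), mask(np.ones((4, 4))))


class TestBoundary:
    def test_single_pixel(self):
        m = np.zeros((5, 5))
        m[2, 2] = 1
        assert extract_boundary(mask(m)).K == 1

    def test_filled_square_perimeter(self):
        m = np.zeros((5, 5))
        m[1:4, 1:4] = 1  # 3x3 square: all 8 ring pixels + centre is interior
        assert extract_boundary(mask(m)).K == 8

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            extract_boundary(mask(np.zeros((4, 4))))

    def test_spacing_scales_coordinates(self):
        m = np.zeros((4, 4))
        m[1, 2] = 1
        b = extract_boundary(mask(m, spacing=(2.0, 3.0)))
        assert b.points.tolist() == [[2.0, 6.0]]


class TestRmsDta:
    def test_identical_masks_zero(self):
        m = mask(np.tri(8))
        assert rms_dta(m, m) == 0.0

    def test_parallel_lines_constant_distance(self):
        a = np.zeros((10, 10))
        a[:, 2] = 1
        b = np.zeros((10, 10))
        b[:, 7] = 1  # 5 px apart at 1 mm spacing -> 0.5 cm
        assert rms_dta(mask(a), mask(b)) == pytest.approx(0.5)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            a = mask(rng.random((10, 10)) < 0.45, spacing=(1.5, 2.0))
            b = mask(rng.random((10, 10)) < 0.45, spacing=(1.5, 2.0))
            if not (a.area_px and b.area_px):
                continue
            assert rms_dta(a, b) == pytest.approx(brute_force_rms_dta(a, b), abs=1e-12)

    def test_empty_mask_error_names_side(self):
        full = mask(np.ones((4, 4)))
        with pytest.raises(ValueError, match="reference"):
            rms_dta(full, mask(np.zeros((4, 4))))
        with pytest.raises(ValueError, match="predicted"):
            rms_dta(mask(np.zeros((4, 4))), full)

    def test_printed_formula_variant_near_zero_for_shifted_lines(self):
        a = np.zeros((10, 10))
        a[:, 2] = 1
        b = np.zeros((10, 10))
        b[:, 7] = 1
        # forward and backward nearest distances cancel for symmetric mismatch
        assert rms_dta(mask(a), mask(b), formula="printed") < 0.2


class TestBonePostprocessing:
    def test_soft_tissue_slice_empty(self):
        ct = CTSlice(pixels=np.full((8, 8), 100.0), spacing=(1, 1), slice_id="s")
        assert bone_mask(ct).area_px == 0

    def test_single_hot_pixel_dilates_to_digital_disc(self):
        px = np.zeros((9, 9))
        px[4, 4] = 500.0
        ct = CTSlice(pixels=px, spacing=(1.0, 1.0), slice_id="s")
        out = bone_mask(ct, threshold=175.0, expand_mm=2.0)
        assert out.area_px == 13  # radius-2 digital disc

    def test_expansion_is_monotone(self):
        rng = np.random.default_rng(3)
        px = rng.normal(100, 150, size=(16, 16))
        ct = CTSlice(pixels=px, spacing=(1.0, 1.0), slice_id="s")
        raw = px > 175.0
        assert np.all(bone_mask(ct).bool() >= raw)

    def test_remove_bone_set_identity(self):
        rng = np.random.default_rng(4)
        pred = mask(rng.random((12, 12)) < 0.5)
        bone = mask(rng.random((12, 12)) < 0.3, role="bone")
        out = remove_bone(pred, bone)
        overlap = int(np.sum(pred.bool() & bone.bool()))
        assert out.area_px == pred.area_px - overlap
        assert not np.any(out.bool() & bone.bool())
        # disjoint masks pass through unchanged
        empty = mask(np.zeros((12, 12)), role="bone")
        assert np.array_equal(remove_bone(pred, empty).labels, pred.labels)


class TestMuscleCharacteristics:
    def test_smd_is_mean_hu(self):
        px = np.full((4, 4), 40.0)
        ct = CTSlice(pixels=px, spacing=(1, 1), slice_id="s")
        assert smd(ct, mask(np.ones((4, 4)))) == 40.0
        px2 = px.copy()
        px2[0, 0], px2[0, 1] = 30.0, 50.0
        two = np.zeros((4, 4))
        two[0, :2] = 1
        assert smd(CTSlice(pixels=px2, spacing=(1, 1), slice_id="s"), mask(two)) == 40.0

    def test_smd_matches_brute_force(self):
        rng = np.random.default_rng(5)
        px = rng.normal(40, 20, (10, 10))
        m = rng.random((10, 10)) < 0.5
        ct = CTSlice(pixels=px, spacing=(1, 1), slice_id="s")
        assert smd(ct, mask(m)) == pytest.approx(px[m].mean())

    def test_sma_pixel_area(self):
        hundred = np.zeros((20, 20))
        hundred.flat[:100] = 1
        assert sma(mask(hundred, spacing=(1.0, 1.0))) == pytest.approx(1.0)
        assert sma(mask(np.zeros((4, 4)))) == 0.0
        m42 = np.zeros((10, 10))
        m42.flat[:42] = 1
        assert sma(mask(m42, spacing=(3.0, 3.0))) == pytest.approx(3.78)
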