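"""Metric correctness against closed forms and a brute-force surface oracle."""

from __future__ import annotations

import numpy as np
import pytest

from rgmcmp.core import LabelMask
from rgmcmp.metrics import EmptyMaskError, asd, dsc, hd95, surface_distances, surface_voxels

from conftest import random_mask


# -- independent O(n²) oracle ------------------------------------------------

def brute_surface(mask: np.ndarray) -> np.ndarray:
    """Surface voxels: mask voxels with a face-adjacent background neighbour
    (the outside of the grid counts as background)."""
    m = mask.astype(bool)
    out = np.zeros_like(m)
    idx = np.argwhere(m)
    for i, j, k in idx:
        for d in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            ni, nj, nk = i + d[0], j + d[1], k + d[2]
            if not (0 <= ni < m.shape[0] and 0 <= nj < m.shape[1] and 0 <= nk < m.shape[2]):
                out[i, j, k] = True
                break
            if not m[ni, nj, nk]:
                out[i, j, k] = True
                break
    return out


def brute_distances(a: np.ndarray, b: np.ndarray, spacing):
    """All-pairs Euclidean distances from each surface voxel of a to the
    nearest surface voxel of b, and vice versa."""
    sa = np.argwhere(brute_surface(a)) * np.asarray(spacing)
    sb = np.argwhere(brute_surface(b)) * np.asarray(spacing)
    d_ab = np.array([np.sqrt(((p - sb) ** 2).sum(axis=1)).min() for p in sa])
    d_ba = np.array([np.sqrt(((p - sa) ** 2).sum(axis=1)).min() for p in sb])
    return d_ab, d_ba


def brute_dsc(a, b) -> float:
    a, b = a.astype(bool), b.astype(bool)
    if a.sum() + b.sum() == 0:
        return 1.0
    return 2.0 * (a & b).sum() / (a.sum() + b.sum())


# -- closed forms ------------------------------------------------------------

class TestDsc:
    def test_identical_masks(self):
        m = np.zeros((8, 8, 8), np.uint8)
        m[2:5, 2:5, 2:5] = 1
        assert dsc(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((8, 8, 8), np.uint8)
        b = np.zeros((8, 8, 8), np.uint8)
        a[0, 0, 0] = 1
        b[5, 5, 5] = 1
        assert dsc(a, b) == 0.0

    def test_partial_overlap_closed_form(self):
        # |A| = 4, |B| = 6, |A∩B| = 3 → 2·3/(4+6) = 0.6
        a = np.zeros((8, 8, 8), np.uint8)
        b = np.zeros((8, 8, 8), np.uint8)
        a[0, 0, :4] = 1
        b[0, 0, 1:7] = 1
        assert dsc(a, b) == pytest.approx(0.6)

    def test_both_empty_defined_as_one(self):
        z = np.zeros((4, 4, 4), np.uint8)
        assert dsc(z, z) == 1.0

    def test_lattice_mismatch_raises(self):
        a = LabelMask(np.ones((4, 4, 4), np.uint8), (1, 1, 1))
        b = LabelMask(np.ones((4, 4, 4), np.uint8), (2, 2, 2))
        with pytest.raises(ValueError):
            dsc(a, b)


class TestSurfaceDistances:
    def test_identical_masks_all_zero(self):
        m = np.zeros((8, 8, 8), np.uint8)
        m[2:6, 2:6, 2:6] = 1
        d_ab, d_ba = surface_distances(m, m, (1, 1, 1))
        assert np.all(d_ab == 0) and np.all(d_ba == 0)

    def test_single_voxel_pair(self):
        a = np.zeros((10, 4, 4), np.uint8)
        b = np.zeros((10, 4, 4), np.uint8)
        a[1, 1, 1] = 1
        b[6, 1, 1] = 1  # 5 voxels apart along x
        d_ab, d_ba = surface_distances(a, b, (1, 1, 1))
        assert d_ab.tolist() == [5.0] and d_ba.tolist() == [5.0]

    def test_anisotropic_spacing_scales_axial_offset(self):
        a = np.zeros((4, 4, 6), np.uint8)
        b = np.zeros((4, 4, 6), np.uint8)
        a[1, 1, 1] = 1
        b[1, 1, 2] = 1  # one slice apart
        d_ab, _ = surface_distances(a, b, (1, 1, 5))
        assert d_ab.tolist() == [5.0]

    def test_empty_mask_rejected(self):
        m = np.zeros((4, 4, 4), np.uint8)
        full = m.copy()
        full[1, 1, 1] = 1
        with pytest.raises(EmptyMaskError):
            surface_distances(m, full, (1, 1, 1))

    def test_surface_extraction_matches_bruteforce(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            m = random_mask(rng, (10, 10, 10))
            assert np.array_equal(surface_voxels(m.astype(bool)), brute_surface(m))


class TestHd95Asd:
    def test_identical_masks_zero(self):
        m = np.zeros((8, 8, 8), np.uint8)
        m[3:6, 3:6, 3:6] = 1
        assert hd95(m, m, (1, 1, 1)) == 0.0
        assert asd(m, m, (1, 1, 1)) == 0.0

    def test_single_voxel_separation(self):
        a = np.zeros((10, 4, 4), np.uint8)
        b = np.zeros((10, 4, 4), np.uint8)
        a[1, 1, 1] = 1
        b[6, 1, 1] = 1
        assert hd95(a, b, (1, 1, 1)) == pytest.approx(5.0)
        a2 = np.zeros((10, 4, 4), np.uint8)
        b2 = np.zeros((10, 4, 4), np.uint8)
        a2[1, 1, 1] = 1
        b2[5, 1, 1] = 1
        assert asd(a2, b2, (1, 1, 1)) == pytest.approx(4.0)

    def test_shifted_cube_matches_bruteforce(self):
        a = np.zeros((16, 16, 16), np.uint8)
        b = np.zeros((16, 16, 16), np.uint8)
        a[2:12, 2:12, 2:12] = 1
        b[4:14, 2:12, 2:12] = 1  # shifted 2 voxels along x
        d = np.concatenate(brute_distances(a, b, (1, 1, 1)))
        assert hd95(a, b, (1, 1, 1)) == pytest.approx(np.percentile(d, 95), abs=1e-9)
        assert asd(a, b, (1, 1, 1)) == pytest.approx(d.mean(), abs=1e-9)

    @pytest.mark.parametrize("spacing", [(1.0, 1.0, 1.0), (0.8, 1.2, 2.5)])
    def test_random_masks_match_bruteforce(self, spacing):
        rng = np.random.default_rng(11)
        checked = 0
        while checked < 25:
            a = random_mask(rng, (12, 12, 12))
            b = random_mask(rng, (12, 12, 12))
            if not a.any() or not b.any():
                continue
            checked += 1
            assert dsc(a, b) == pytest.approx(brute_dsc(a, b), abs=0)
            d = np.concatenate(brute_distances(a, b, spacing))
            assert hd95(a, b, spacing) == pytest.approx(np.percentile(d, 95), abs=1e-9)
            assert asd(a, b, spacing) == pytest.approx(d.mean(), abs=1e-9)


class TestPropertyBased:
    """Randomized invariants via hypothesis (derandomized for CI stability)."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_dsc_bounds_and_self_identity(self, seed):
        rng = np.random.default_rng(seed)
        a = random_mask(rng, (8, 8, 8), p=float(rng.uniform(0.05, 0.6)))
        b = random_mask(rng, (8, 8, 8), p=float(rng.uniform(0.05, 0.6)))
        v = dsc(a, b)
        assert 0.0 <= v <= 1.0
        assert dsc(a, a) == 1.0
        assert v == dsc(b, a)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_distance_metrics_nonnegative_and_bounded_by_diameter(self, seed):
        rng = np.random.default_rng(seed)
        a = random_mask(rng, (8, 8, 8), p=0.3)
        b = random_mask(rng, (8, 8, 8), p=0.3)
        if not (a.any() and b.any()):
            return
        spacing = (1.0, 1.5, 2.0)
        diameter = np.sqrt(sum((7 * s) ** 2 for s in spacing))
        h, m = hd95(a, b, spacing), asd(a, b, spacing)
        assert 0.0 <= m <= diameter
        assert 0.0 <= h <= diameter


class TestInvariances:
    def test_symmetry(self):
        rng = np.random.default_rng(3)
        a, b = random_mask(rng), random_mask(rng)
        assert dsc(a, b) == dsc(b, a)
        assert hd95(a, b, (1, 1, 2)) == pytest.approx(hd95(b, a, (1, 1, 2)))
        assert asd(a, b, (1, 1, 2)) == pytest.approx(asd(b, a, (1, 1, 2)))

    def test_joint_translation_invariance(self):
        rng = np.random.default_rng(5)
        a, b = random_mask(rng, (10, 10, 10)), random_mask(rng, (10, 10, 10))
        pad = ((3, 1), (2, 2), (0, 4))
        a2, b2 = np.pad(a, pad), np.pad(b, pad)
        assert dsc(a, b) == pytest.approx(dsc(a2, b2))
        if a.any() and b.any():
            assert hd95(a, b, (1, 1, 1)) == pytest.approx(hd95(a2, b2, (1, 1, 1)))
            assert asd(a, b, (1, 1, 1)) == pytest.approx(asd(a2, b2, (1, 1, 1)))
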