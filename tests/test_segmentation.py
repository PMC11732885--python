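"""Isocontour thresholding, lesion diameters, and the compartment algebra."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from y90dosim.grids import VoxelGrid
from y90dosim.phantom import Lesion, generate_phantom
from y90dosim.segmentation import (
    CompartmentSet,
    ThresholdSpec,
    derive_compartments,
    lesion_diameter,
    threshold_segment,
)

from conftest import small_phantom_config


def _grid_1d(values):
    """Embed a 1-D count profile along x of a 3-D grid."""
    arr = np.zeros((len(values), 1, 1))
    arr[:, 0, 0] = values
    return VoxelGrid(arr, 4.0)


FULL_BOX_1D = ((0, 5), (0, 1), (0, 1))


class TestThresholdSegment:
    def test_zero_threshold_selects_whole_box(self):
        g = _grid_1d([1, 2, 5, 10, 4])
        mask = threshold_segment(g, ThresholdSpec(FULL_BOX_1D, 0.0))
        assert mask.sum() == 5

    def test_unit_threshold_selects_unique_maximum(self):
        g = _grid_1d([1, 2, 5, 10, 4])
        mask = threshold_segment(g, ThresholdSpec(FULL_BOX_1D, 1.0))
        assert np.argwhere(mask).tolist() == [[3, 0, 0]]

    def test_half_threshold_keeps_ties_inclusive(self):
        # Enumeration oracle: threshold 0.5 * 10 = 5; counts {5, 10} pass.
        g = _grid_1d([1, 2, 5, 10, 4])
        mask = threshold_segment(g, ThresholdSpec(FULL_BOX_1D, 0.5))
        assert sorted(g.values[mask].tolist()) == [5.0, 10.0]

    def test_clip_mask_applies(self):
        g = _grid_1d([1, 2, 5, 10, 4])
        clip = np.zeros(g.shape, dtype=bool)
        clip[2, 0, 0] = True
        mask = threshold_segment(g, ThresholdSpec(FULL_BOX_1D, 0.5, clip=clip))
        assert g.values[mask].tolist() == [5.0]

    def test_box_outside_grid_rejected(self):
        g = _grid_1d([1, 2, 3])
        with pytest.raises(ValueError, match="outside grid"):
            threshold_segment(g, ThresholdSpec(((0, 9), (0, 1), (0, 1)), 0.5))

    def test_all_zero_box_warns_and_returns_empty(self):
        g = VoxelGrid(np.zeros((4, 4, 4)), 4.0)
        with pytest.warns(UserWarning, match="all-zero"):
            mask = threshold_segment(g, ThresholdSpec(((0, 4), (0, 4), (0, 4)), 0.5))
        assert not mask.any()

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        t1=st.floats(0.0, 1.0),
        t2=st.floats(0.0, 1.0),
        seed=st.integers(0, 100),
    )
    def test_threshold_monotonicity(self, t1, t2, seed):
        # Nesting: larger fraction implies a subset mask.
        rng = np.random.default_rng(seed)
        g = VoxelGrid(rng.integers(0, 50, size=(6, 6, 6)).astype(float), 4.0)
        lo, hi = sorted([t1, t2])
        box = ((0, 6), (0, 6), (0, 6))
        m_hi = threshold_segment(g, ThresholdSpec(box, hi))
        m_lo = threshold_segment(g, ThresholdSpec(box, lo))
        assert not (m_hi & ~m_lo).any()


class TestLesionDiameter:
    def test_single_voxel_is_zero(self):
        m = np.zeros((5, 5, 5), dtype=bool)
        m[2, 2, 2] = True
        assert lesion_diameter(m, 4.0) == 0.0

    def test_two_voxels_on_axis(self):
        m = np.zeros((15, 5, 5), dtype=bool)
        m[2, 2, 2] = m[12, 2, 2] = True
        assert lesion_diameter(m, 4.0) == pytest.approx(4.0)

    def test_digitized_sphere_matches_nominal(self):
        ph = generate_phantom(small_phantom_config())
        big = next(l for l in ph.lesions if l.id == "big")
        d = lesion_diameter(big.mask, 4.0)
        assert abs(d - 3.6) <= 0.4  # within one voxel pitch of nominal

    def test_hull_shortcut_matches_bruteforce(self, rng):
        from scipy.spatial.distance import pdist

        mask = rng.random((12, 12, 12)) < 0.4
        mask[0, 0, 0] = True  # non-empty
        pts = np.argwhere(mask).astype(float)
        brute = pdist(pts).max() * 4.0 / 10.0
        assert lesion_diameter(mask, 4.0) == pytest.approx(brute)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            lesion_diameter(np.zeros((3, 3, 3), dtype=bool), 4.0)


def _lesion(shape, voxels, diameter_cm, id):
    m = np.zeros(shape, dtype=bool)
    for v in voxels:
        m[v] = True
    return Lesion(id, m, diameter_cm)


class TestDeriveCompartments:
    def test_size_rule_set_arithmetic(self):
        # Set-arithmetic oracle: 1000-voxel perfused; tumors of 100 (3.5 cm),
        # 30 (2.5 cm) and 10 (1.5 cm) voxels -> normal 870, total tumor 100.
        shape = (10, 10, 10)
        liver = np.ones(shape, dtype=bool)
        perfused = np.ones(shape, dtype=bool)
        coords = [(i, j, k) for i in range(10) for j in range(10) for k in range(10)]
        a = _lesion(shape, coords[:100], 3.5, "A")
        b = _lesion(shape, coords[100:130], 2.5, "B")
        c = _lesion(shape, coords[130:140], 1.5, "C")
        comps = derive_compartments(liver, perfused, [a, b, c])
        assert comps.perfused_normal.sum() == 870
        assert comps.total_perfused_tumor.sum() == 100
        assert comps.whole_liver_normal.sum() == 870

    def test_no_tumors_degenerate(self):
        shape = (6, 6, 6)
        liver = np.ones(shape, dtype=bool)
        perfused = np.zeros(shape, dtype=bool)
        perfused[:3] = True
        comps = derive_compartments(liver, perfused, [])
        assert np.array_equal(comps.perfused_normal, perfused)
        assert not comps.total_perfused_tumor.any()

    def test_tumor_covering_perfused(self):
        shape = (6, 6, 6)
        liver = np.ones(shape, dtype=bool)
        perfused = np.zeros(shape, dtype=bool)
        perfused[:3] = True
        t = Lesion("T", perfused.copy(), 4.0)
        comps = derive_compartments(liver, perfused, [t])
        assert not comps.perfused_normal.any()
        assert np.array_equal(comps.total_perfused_tumor, perfused)

    def test_perfused_outside_liver_rejected(self):
        shape = (4, 4, 4)
        liver = np.zeros(shape, dtype=bool)
        liver[:2] = True
        perfused = np.ones(shape, dtype=bool)
        with pytest.raises(ValueError, match="inside the whole liver"):
            derive_compartments(liver, perfused, [])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_partition_invariants_random_phantoms(self, seed):
        """Exhaustive voxel check of the compartment algebra on random masks."""
        rng = np.random.default_rng(seed)
        shape = (8, 8, 8)
        liver = rng.random(shape) < 0.8
        perfused = liver & (rng.random(shape) < 0.7)
        tumors = []
        for i, d in enumerate(rng.uniform(1.0, 4.5, size=rng.integers(0, 4))):
            m = perfused & (rng.random(shape) < 0.15)
            if m.any():
                tumors.append(Lesion(f"T{i}", m, float(d)))
        comps = derive_compartments(liver, perfused, tumors)
        ge2 = np.zeros(shape, dtype=bool)
        for t in tumors:
            if t.diameter_cm >= 2.0:
                ge2 |= t.mask
        # perfused_normal ∪ (tumors >= 2 cm ∩ perfused) == perfused
        assert np.array_equal(comps.perfused_normal | (ge2 & perfused), perfused)
        assert not (comps.perfused_normal & comps.total_perfused_tumor).any()
        assert not (comps.total_perfused_tumor & ~perfused).any()


class TestMethodEquivalenceOnCleanPhantom:
    def test_threshold_recovers_anatomic_tumor_mask(self):
        """With strict in/out count contrast the isocontour equals the anatomic mask."""
        from y90dosim.phantom import LesionSpec

        cfg = small_phantom_config(
            tumor_to_normal=10.0,
            lesions=[LesionSpec((76.0, 62.0, 62.0), 4.0, "big")],
        )
        ph = generate_phantom(cfg)
        big = ph.lesions[0]
        idx = np.argwhere(big.mask)
        lo, hi = idx.min(0) - 3, idx.max(0) + 4
        box = tuple((int(a), int(b)) for a, b in zip(lo, hi))
        mask = threshold_segment(
            ph.pre_counts, ThresholdSpec(box, 0.5, clip=ph.perfused)
        )
        assert np.array_equal(mask, big.mask)
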