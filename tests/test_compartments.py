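"""Nuclei / cell-body / cytoplasm segmentation and the Otsu primitive."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import polysumo as ps
from polysumo.compartments import cell_body_threshold
from polysumo.errors import DegenerateHistogram, ParentLinkageBroken

from conftest import make_disk


def brute_force_otsu(image, n_classes, n_bins=256):
    """Independent oracle: exhaustive search over histogram boundaries."""
    hist, edges = np.histogram(
        np.clip(image, 0.0, 1.0), bins=n_bins, range=(0.0, 1.0)
    )
    p = hist / hist.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])

    def score(cuts):
        bounds = [0, *[c + 1 for c in cuts], n_bins]
        total = 0.0
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            w = p[lo:hi].sum()
            if w > 0:
                mu = (p[lo:hi] * centers[lo:hi]).sum() / w
                total += w * mu * mu
        return total

    best, best_cuts = -1.0, None
    if n_classes == 2:
        for k in range(n_bins - 1):
            s = score((k,))
            if s > best + 1e-15:
                best, best_cuts = s, (k,)
        return [edges[best_cuts[0] + 1]]
    for k1 in range(n_bins - 1):
        for k2 in range(k1 + 1, n_bins - 1):
            s = score((k1, k2))
            if s > best + 1e-15:
                best, best_cuts = s, (k1, k2)
    return [edges[best_cuts[0] + 1], edges[best_cuts[1] + 1]]


class TestOtsuThresholds:
    def test_two_masses_two_classes(self):
        img = np.concatenate([np.full(50, 0.2), np.full(50, 0.8)])
        (t,) = ps.otsu_thresholds(img.reshape(10, 10), 2)
        assert 0.2 < t <= 0.8
        assert t == pytest.approx(brute_force_otsu(img, 2)[0])

    def test_three_masses_three_classes(self):
        img = np.concatenate([np.full(30, 0.1), np.full(30, 0.5), np.full(30, 0.9)])
        t1, t2 = ps.otsu_thresholds(img.reshape(9, 10), 3)
        assert 0.1 < t1 <= 0.5 < t2 <= 0.9
        oracle = brute_force_otsu(img, 3)
        assert [t1, t2] == pytest.approx(oracle)

    def test_constant_image_degenerate(self):
        with pytest.raises(DegenerateHistogram, match="degenerate histogram"):
            ps.otsu_thresholds(np.full((8, 8), 0.5), 2)

    @given(st.integers(0, 10_000))
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force_two_class(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.uniform(0, 1, size=(32, 32))
        assert ps.otsu_thresholds(img, 2) == pytest.approx(
            brute_force_otsu(img, 2)
        )

    @given(st.integers(0, 10_000))
    @settings(max_examples=15, deadline=None)
    def test_matches_brute_force_three_class(self, seed):
        # the pair search is O(n_bins^2); a coarse histogram keeps the
        # oracle loop tractable while exercising the same code path
        rng = np.random.default_rng(seed)
        img = rng.uniform(0, 1, size=(32, 32))
        assert ps.otsu_thresholds(img, 3, n_bins=64) == pytest.approx(
            brute_force_otsu(img, 3, n_bins=64)
        )


class TestSegmentNucleiClassical:
    def test_single_disk(self):
        img = make_disk((128, 128), (64, 64), 20, value=1000.0)
        mask = ps.segment_nuclei_classical(img, ps.SegmentationParams())
        assert mask.n_objects == 1
        # the single label covers the disk interior
        disk_px = img > 0
        inner = np.zeros_like(disk_px)
        inner[disk_px] = True
        assert (mask.labels[64, 64]) == 1
        assert mask.areas()[1] == pytest.approx(disk_px.sum(), rel=0.1)

    def test_two_separated_disks_match_components_oracle(self):
        from scipy import ndimage as ndi

        img = make_disk((160, 160), (50, 50), 20, 1000.0)
        img += make_disk((160, 160), (50, 100), 20, 1000.0)  # 10 px gap
        mask = ps.segment_nuclei_classical(img, ps.SegmentationParams())
        assert mask.n_objects == 2
        # oracle: connected components of the true support
        oracle, n = ndi.label(img > 0)
        assert n == 2
        for lbl in (1, 2):
            covered = mask.labels[oracle == lbl]
            ids = np.unique(covered[covered > 0])
            assert ids.size == 1  # one segmented nucleus per true disk

    def test_blank_field_empty(self):
        mask = ps.segment_nuclei_classical(
            np.zeros((64, 64)), ps.SegmentationParams()
        )
        assert mask.n_objects == 0


class TestFilterLabelsByArea:
    def test_strict_threshold_boundary(self):
        # nuclei of area 1199 / 1200 / 1201 px^2 in one mask
        labels = np.zeros((80, 80), dtype=np.int32)
        labels.ravel()[:1199] = 1
        labels.ravel()[1199 : 1199 + 1200] = 2
        labels.ravel()[2399 : 2399 + 1201] = 3
        out = ps.filter_labels_by_area(ps.LabelMask(labels), 1200)
        assert set(out.label_ids.tolist()) == {2, 3}
        assert out.areas() == {2: 1200, 3: 1201}

    def test_zero_threshold_is_identity(self):
        labels = np.array([[1, 0], [0, 2]], dtype=np.int32)
        out = ps.filter_labels_by_area(ps.LabelMask(labels), 0)
        np.testing.assert_array_equal(out.labels, labels)

    def test_all_below_threshold(self):
        labels = np.array([[1, 0], [0, 2]], dtype=np.int32)
        out = ps.filter_labels_by_area(ps.LabelMask(labels), 10)
        assert out.n_objects == 0

    @given(st.integers(0, 300), st.integers(0, 300))
    @settings(max_examples=40, deadline=None)
    def test_idempotent_and_monotone(self, a1, a2):
        rng = np.random.default_rng(9)
        labels = rng.integers(0, 5, size=(24, 24)).astype(np.int32)
        lo, hi = sorted((a1, a2))
        once = ps.filter_labels_by_area(ps.LabelMask(labels), hi)
        twice = ps.filter_labels_by_area(once, hi)
        np.testing.assert_array_equal(once.labels, twice.labels)
        big = set(once.label_ids.tolist())
        small = set(
            ps.filter_labels_by_area(ps.LabelMask(labels), lo).label_ids.tolist()
        )
        assert big <= small  # raising the cutoff never adds labels


class TestCombineAndCellBodies:
    def test_mean_combination(self):
        params = ps.SegmentationParams(pre_smooth_sigma=1e-9)
        gfp = np.full((8, 8), 0.2)
        rfp = np.full((8, 8), 0.4)
        out = ps.combine_gfp_rfp(gfp, rfp, params)
        np.testing.assert_allclose(out, 0.3, atol=1e-6)

    def test_zero_rfp_gives_half_gfp(self):
        params = ps.SegmentationParams(pre_smooth_sigma=1e-9)
        gfp = np.full((8, 8), 0.6)
        out = ps.combine_gfp_rfp(gfp, np.zeros((8, 8)), params)
        np.testing.assert_allclose(out, 0.3, atol=1e-6)

    def test_constant_unchanged_by_smoothing(self):
        params = ps.SegmentationParams()
        out = ps.combine_gfp_rfp(np.full((16, 16), 0.5), np.full((16, 16), 0.5), params)
        np.testing.assert_allclose(out, 0.5, atol=1e-9)

    def test_correction_factor_scales_lower_otsu_boundary(self, rng):
        img = rng.uniform(0, 1, size=(64, 64))
        params = ps.SegmentationParams()
        applied, raw = cell_body_threshold(img, params)
        assert applied == pytest.approx(0.5 * raw)
        assert raw == ps.otsu_thresholds(img, 3)[0]

    def test_one_nucleus_one_blob(self):
        combined = make_disk((96, 96), (48, 48), 30, 0.8)
        nuclei = ps.LabelMask(
            make_disk((96, 96), (48, 48), 12).astype(np.int32), kind="nuclei"
        )
        cells = ps.segment_cell_bodies(combined, nuclei, ps.SegmentationParams())
        assert set(cells.label_ids.tolist()) == {1}
        # cell covers blob and contains the nucleus
        assert np.all(cells.labels[nuclei.labels > 0] == 1)

    def test_two_nuclei_one_blob_partition(self):
        # two seeds inside one connected bright region: watershed splits it,
        # pixel-disjointly, covering the whole blob
        combined = np.zeros((64, 64))
        combined[20:44, 8:56] = 0.8
        nuclei_arr = np.zeros((64, 64), dtype=np.int32)
        nuclei_arr[28:36, 14:22] = 1
        nuclei_arr[28:36, 42:50] = 2
        nuclei = ps.LabelMask(nuclei_arr, kind="nuclei")
        cells = ps.segment_cell_bodies(combined, nuclei, ps.SegmentationParams())
        assert set(cells.label_ids.tolist()) == {1, 2}
        blob = combined >= 0.4
        assert np.all(cells.labels[blob] > 0)  # pixel conservation
        # each cell contains its own nucleus
        for lbl in (1, 2):
            assert np.all(cells.labels[nuclei_arr == lbl] == lbl)
        # symmetric geometry: split near the vertical midline
        left = cells.labels[:, :32]
        assert np.all(left[left > 0] == 1)

    def test_nucleus_without_foreground_keeps_nucleus(self):
        combined = np.zeros((64, 64))
        combined[5, 5] = 1.0  # just to avoid a degenerate histogram
        nuclei_arr = np.zeros((64, 64), dtype=np.int32)
        nuclei_arr[30:40, 30:40] = 1
        cells = ps.segment_cell_bodies(
            combined, ps.LabelMask(nuclei_arr), ps.SegmentationParams()
        )
        np.testing.assert_array_equal(
            (cells.labels == 1), (nuclei_arr == 1)
        )

    def test_empty_nuclei_empty_cells(self):
        cells = ps.segment_cell_bodies(
            np.random.default_rng(1).uniform(size=(32, 32)),
            ps.LabelMask(np.zeros((32, 32), dtype=np.int32)),
            ps.SegmentationParams(),
        )
        assert cells.n_objects == 0


class TestDeriveCytoplasm:
    def test_ring_subtraction(self):
        cells = np.zeros((9, 9), dtype=np.int32)
        cells[2:7, 2:7] = 1  # 5x5 square
        nuclei = np.zeros((9, 9), dtype=np.int32)
        nuclei[3:6, 3:6] = 1  # central 3x3
        cyt = ps.derive_cytoplasm(ps.LabelMask(cells), ps.LabelMask(nuclei))
        assert cyt.areas()[1] == 16
        assert np.all(cyt.labels[nuclei > 0] == 0)

    def test_cell_equals_nucleus_gives_empty_cytoplasm(self):
        square = np.zeros((6, 6), dtype=np.int32)
        square[1:4, 1:4] = 1
        cyt = ps.derive_cytoplasm(ps.LabelMask(square), ps.LabelMask(square))
        assert cyt.n_objects == 0

    def test_orphan_cell_label_rejected(self):
        cells = np.array([[2]], dtype=np.int32)
        nuclei = np.array([[1]], dtype=np.int32)
        with pytest.raises(ParentLinkageBroken, match="parent linkage broken"):
            ps.derive_cytoplasm(ps.LabelMask(cells), ps.LabelMask(nuclei))


class TestCompartmentInvariants:
    def test_segment_field_satisfies_algebra(self, small_scene):
        spec, fld, truth = small_scene
        proj = ps.average_z_projection(fld)
        cs = ps.segment_field(proj, ps.SegmentationParams(), truth.nuclei_mask)
        cs.validate()  # raises on any violated invariant
        assert cs.nuclei.n_objects == len(truth.nuclei)
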