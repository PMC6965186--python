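"""Airway segmentation: tubularity filter, flood fill, skeleton-to-tree."""

import numpy as np
import pytest

from lung4dxv.airway_seg import (
    SegmentationError,
    VesselnessParams,
    flood_fill_segment,
    multiscale_tubularity,
    segment_airways,
    skeletonize_to_tree,
)
from lung4dxv.core import Volume4D
from lung4dxv.phantom import (
    PhantomSpec,
    airway_lumen_mask,
    generate_airway_tree,
    render_reference_volume,
)

SCALES_SMALL = tuple(np.geomspace(1.0, 6.0, 5))


def _dark_cylinder(n=64, radius=4.0, background=0.6, lumen=0.1):
    """Dark tube of given radius along z in a bright background."""
    vol = np.full((n, n, n), background, np.float32)
    y, x = np.mgrid[0:n, 0:n].astype(float)
    tube = (y - n / 2) ** 2 + (x - n / 2) ** 2 <= radius**2
    vol[:, tube] = lumen
    return vol


def _dark_plate(n=64, half_thickness=4.0, background=0.6, lumen=0.1):
    vol = np.full((n, n, n), background, np.float32)
    x = np.arange(n, dtype=float)
    vol[:, :, np.abs(x - n / 2) <= half_thickness] = lumen
    return vol


@pytest.fixture(scope="module")
def gen4_phantom():
    spec = PhantomSpec(tree_generations=4)
    tree = generate_airway_tree(spec)
    return spec, tree


class TestVesselnessParams:
    def test_scales_must_increase(self):
        with pytest.raises(ValueError):
            VesselnessParams(scales=(3.0, 1.0))

    def test_scales_must_be_positive_nonempty(self):
        with pytest.raises(ValueError):
            VesselnessParams(scales=())
        with pytest.raises(ValueError):
            VesselnessParams(scales=(-1.0, 2.0))


class TestTubularity:
    def test_constant_volume_has_zero_response(self):
        params = VesselnessParams(scales=SCALES_SMALL)
        tub = multiscale_tubularity(np.full((48, 48, 48), 0.5), params)
        assert tub.response.max() == 0.0

    def test_dark_tube_outranks_dark_plate(self):
        """Tube-vs-plate contrast on the structure axes is at least 2x."""
        params = VesselnessParams(scales=SCALES_SMALL)
        rt = multiscale_tubularity(_dark_cylinder(), params)
        rp = multiscale_tubularity(_dark_plate(), params)
        tube_med = np.median(rt.response[10:54, 32, 32])
        plate_med = np.median(rp.response[10:54, 32, 32])
        assert tube_med >= 2.0 * max(plate_med, 1e-9)

    def test_response_maximal_on_centerline(self):
        params = VesselnessParams(scales=SCALES_SMALL)
        rt = multiscale_tubularity(_dark_cylinder(radius=4.0), params)
        assert rt.response[32, 32, 32] > rt.response[32, 32, 36]

    def test_winning_scale_tracks_tube_radius(self):
        params = VesselnessParams(scales=SCALES_SMALL)
        rt = multiscale_tubularity(_dark_cylinder(radius=4.0), params)
        assert 1.5 <= rt.scale[32, 32, 32] <= 6.0

    def test_invariant_to_additive_offset(self):
        params = VesselnessParams(scales=SCALES_SMALL)
        vol = _dark_cylinder(n=48)
        r1 = multiscale_tubularity(vol, params).response
        r2 = multiscale_tubularity(vol + 0.2, params).response
        assert np.allclose(r1, r2, atol=1e-10)

    def test_response_monotone_in_contrast(self):
        params = VesselnessParams(scales=SCALES_SMALL)
        meds = []
        for contrast in (0.1, 0.3, 0.5):
            vol = _dark_cylinder(n=48, background=0.5, lumen=0.5 - contrast)
            r = multiscale_tubularity(vol, params)
            meds.append(np.median(r.response[10:38, 24, 24]))
        assert meds[0] <= meds[1] <= meds[2]

    def test_volume_smaller_than_kernel_support_errors(self):
        params = VesselnessParams(scales=(1.0, 16.0))
        with pytest.raises(SegmentationError, match="kernel"):
            multiscale_tubularity(np.zeros((24, 24, 24)), params)


class TestFloodFill:
    def test_only_seeded_component_kept(self):
        resp = np.zeros((32, 32, 32))
        resp[4:12, 16, 16] = 0.9  # seeded tube
        resp[20:28, 16, 16] = 0.9  # disconnected second tube
        mask = flood_fill_segment(resp, (5, 16, 16), threshold=0.5)
        assert mask[5:12, 16, 16].all()
        assert not mask[20:28, 16, 16].any()

    def test_zero_threshold_fills_entire_support(self):
        resp = np.random.default_rng(0).random((16, 16, 16))
        mask = flood_fill_segment(resp, (8, 8, 8), threshold=0.0)
        assert mask.all()

    def test_seed_below_threshold_errors(self):
        resp = np.zeros((16, 16, 16))
        with pytest.raises(SegmentationError, match="below threshold"):
            flood_fill_segment(resp, (8, 8, 8), threshold=0.5)

    def test_phantom_lumen_recall_with_otsu_default(self, gen4_phantom):
        """Flood fill from the trachea recovers >=90% of proximal lumen voxels."""
        spec, tree = gen4_phantom
        vol = render_reference_volume(tree, spec)
        params = VesselnessParams(scales=tuple(np.geomspace(1.0, 8.0, 6)))
        tub = multiscale_tubularity(vol, params)
        root = tuple(np.round(tree.segments[tree.root_id].points[1]).astype(int))
        mask = flood_fill_segment(tub, root)  # Otsu threshold
        proximal = np.zeros(spec.grid_shape, bool)
        prox_tree_ids = [s.id for s in tree.segments.values() if s.generation <= 3]
        sub = {i: tree.segments[i] for i in prox_tree_ids}
        from lung4dxv.core import AirwayTree

        prox_lumen = airway_lumen_mask(
            AirwayTree({i: sub[i] for i in sub}, tree.root_id), spec
        )
        recall = (mask & prox_lumen).sum() / prox_lumen.sum()
        assert recall >= 0.9


class TestSkeletonToTree:
    def test_straight_cylinder_is_one_segment(self):
        mask = np.zeros((64, 32, 32), bool)
        y, x = np.mgrid[0:32, 0:32].astype(float)
        mask[4:60, (y - 16) ** 2 + (x - 16) ** 2 <= 9] = True
        tree = skeletonize_to_tree(mask, (5, 16, 16))
        assert tree.n_segments == 1 and tree.n_bifurcations == 0

    def test_y_phantom_three_segments_one_bifurcation(self):
        mask = np.zeros((64, 64, 64), bool)
        for z in range(5, 33):
            mask[z, 30:35, 30:35] = True
        for i in range(28):
            off = int(i * 0.7)
            mask[32 + i, 30:35, 30 + off:35 + off] = True
            mask[32 + i, 30:35, 30 - off:35 - off] = True
        tree = skeletonize_to_tree(mask, (6, 32, 32))
        assert tree.n_segments == 3
        assert tree.n_bifurcations == 1
        assert sorted(s.generation for s in tree.segments.values()) == [0, 1, 1]

    def test_phantom_tree_bifurcations_recovered_exactly(self, gen4_phantom):
        """Skeleton of the clean generation-4 lumen finds all 2^4-1 bifurcations."""
        spec, tree = gen4_phantom
        lumen = airway_lumen_mask(tree, spec)
        root = tuple(np.round(tree.segments[tree.root_id].points[1]).astype(int))
        rec = skeletonize_to_tree(lumen, root)
        assert rec.n_bifurcations == 15
        assert rec.n_segments == 31
        g = rec.to_networkx()
        assert g.number_of_edges() == g.number_of_nodes() - 1

    def test_generations_count_bifurcations_from_root(self, gen4_phantom):
        spec, tree = gen4_phantom
        lumen = airway_lumen_mask(tree, spec)
        root = tuple(np.round(tree.segments[tree.root_id].points[1]).astype(int))
        rec = skeletonize_to_tree(lumen, root)
        for seg in rec.segments.values():
            depth = 0
            cur = seg
            while cur.parent_id is not None:
                cur = rec.segments[cur.parent_id]
                depth += 1
            assert seg.generation == depth

    def test_disconnected_mask_errors(self):
        mask = np.zeros((32, 32, 32), bool)
        mask[2:8, 14:18, 14:18] = True
        mask[20:26, 14:18, 14:18] = True
        with pytest.raises(SegmentationError, match="connected"):
            skeletonize_to_tree(mask, (3, 16, 16))

    def test_empty_mask_errors(self):
        with pytest.raises(SegmentationError, match="empty"):
            skeletonize_to_tree(np.zeros((8, 8, 8), bool), (4, 4, 4))


class TestSegmentAirways:
    def test_only_phase_zero_is_used(self):
        """Replacing later phases with noise leaves the tree unchanged."""
        vol = _dark_cylinder(n=48)
        rng = np.random.default_rng(0)
        v1 = Volume4D(np.stack([vol, vol]), phase_times=[0.0, 1.0])
        v2 = Volume4D(
            np.stack([vol, rng.random((48, 48, 48)).astype(np.float32)]),
            phase_times=[0.0, 1.0],
        )
        params = VesselnessParams(scales=SCALES_SMALL)
        t1 = segment_airways(v1, params, (24, 24, 24), threshold=0.3)
        t2 = segment_airways(v2, params, (24, 24, 24), threshold=0.3)
        assert t1.n_segments == t2.n_segments
        assert np.array_equal(
            t1.segments[t1.root_id].points, t2.segments[t2.root_id].points
        )

    def test_noise_only_volume_errors(self):
        rng = np.random.default_rng(1)
        vol4d = Volume4D(rng.random((1, 40, 40, 40)).astype(np.float32),
                         phase_times=[0.0])
        params = VesselnessParams(scales=SCALES_SMALL)
        with pytest.raises(SegmentationError):
            segment_airways(vol4d, params, (20, 20, 20), threshold=0.95)

    def test_phantom_tree_recovered_through_full_chain(self, gen4_phantom):
        """Noise-free rendered phantom segments down to its deepest generations."""
        spec, tree = gen4_phantom
        vol = render_reference_volume(tree, spec)
        vol4d = Volume4D(vol[None], phase_times=[0.0])
        params = VesselnessParams(scales=tuple(np.geomspace(1.0, 8.0, 6)))
        root = tuple(np.round(tree.segments[tree.root_id].points[1]).astype(int))
        rec = segment_airways(vol4d, params, root, threshold=0.1, prune_factor=2.5)
        assert rec.max_generation >= spec.tree_generations
        assert rec.n_bifurcations >= 15
        # every true terminal is near some recovered centerline point
        rec_pts = np.concatenate([s.points for s in rec.segments.values()])
        for tid in tree.terminal_ids():
            d = np.linalg.norm(rec_pts - tree.segments[tid].end, axis=1).min()
            assert d < 8.0
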