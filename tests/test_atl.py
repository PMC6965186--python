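"""Airway Tree Link: region assignment, flow summation, time constants."""

import numpy as np
import pytest

from lung4dxv.atl import (
    ATLError,
    EXPIRED_FRACTION,
    BranchFlowSeries,
    aeration_map,
    assign_regions,
    expiratory_time_constant,
    flow_sum,
    regional_volumes,
)
from lung4dxv.core import AirwaySegment, AirwayTree
from lung4dxv.phantom import DefectSpec, PhantomSpec, VentilationProtocol, simulate_breath_series
from lung4dxv.velocimetry import DisplacementField, ExpansionField, build_grid, XVParams


def _line_tree(end=(10.0, 5.0, 5.0)) -> AirwayTree:
    seg = AirwaySegment(0, None, 0, [[0.0, 5.0, 5.0], list(end)], [1.0, 1.0])
    return AirwayTree({0: seg}, 0)


def _two_terminal_tree() -> AirwayTree:
    """Root bifurcating into terminals at x=8 and x=24 (symmetric about x=16)."""
    segs = {
        0: AirwaySegment(0, None, 0, [[2.0, 16.0, 16.0], [8.0, 16.0, 16.0]], [2.0, 2.0]),
        1: AirwaySegment(1, 0, 1, [[8.0, 16.0, 16.0], [16.0, 16.0, 8.0]], [1.5, 1.5]),
        2: AirwaySegment(2, 0, 1, [[8.0, 16.0, 16.0], [16.0, 16.0, 24.0]], [1.5, 1.5]),
    }
    return AirwayTree(segs, 0)


PHASE_TIMES = np.arange(15) * 500.0 / 15.0
PROTOCOL = VentilationProtocol()


def _breath_profile(tau: float) -> np.ndarray:
    """Raised-cosine inspiration then exponential expiration."""
    t = PHASE_TIMES
    return np.where(
        t <= 250.0,
        0.5 * (1 - np.cos(np.pi * t / 250.0)),
        np.exp(-(t - 250.0) / tau),
    )


class TestAssignRegions:
    def test_single_terminal_takes_whole_mask(self):
        mask = np.zeros((16, 12, 12), bool)
        mask[4:12, 2:10, 2:10] = True
        a = assign_regions(mask, _line_tree())
        assert np.all(a.labels[mask] == 0)
        assert np.all(a.labels[~mask] == -1)

    def test_symmetric_terminals_split_halfspace(self):
        mask = np.ones((32, 32, 32), bool)
        a = assign_regions(mask, _two_terminal_tree())
        assert np.all(a.labels[:, :, :16] == 1)
        assert np.all(a.labels[:, :, 17:] == 2)

    def test_empty_mask_errors(self):
        with pytest.raises(ATLError, match="empty"):
            assign_regions(np.zeros((8, 8, 8), bool), _line_tree())

    def test_agreement_with_generator_partition(self, breath):
        """Recomputed assignment matches the phantom's own region labels."""
        a = assign_regions(breath.lung_mask, breath.tree)
        agree = (a.labels[breath.lung_mask] == breath.region_labels[breath.lung_mask]).mean()
        assert agree >= 0.8


class TestRegionalVolumes:
    def _uniform_expansion(self, value, shape=(32, 32, 32)):
        grid = build_grid(shape, XVParams(window=16))
        return ExpansionField(
            grid=grid,
            values=np.full(grid.shape, value),
            valid=np.ones(grid.shape, bool),
        )

    def test_zero_expansion_zero_series(self):
        mask = np.ones((32, 32, 32), bool)
        a = assign_regions(mask, _two_terminal_tree())
        series = regional_volumes([self._uniform_expansion(0.0)] * 3, a)
        for v in series.values():
            assert np.all(v == 0.0)
            assert len(v) == 4

    def test_uniform_expansion_proportional_to_region_size(self):
        mask = np.ones((32, 32, 32), bool)
        mask[:, :, 20:] = False  # asymmetric regions
        a = assign_regions(mask, _two_terminal_tree())
        series = regional_volumes([self._uniform_expansion(0.01)], a)
        sizes = a.region_sizes()
        ratio = series[1][-1] / series[2][-1]
        assert ratio == pytest.approx(sizes[1] / sizes[2], rel=0.05)

    def test_empty_series_errors(self):
        mask = np.ones((8, 8, 8), bool)
        a = assign_regions(mask, _line_tree())
        with pytest.raises(ATLError, match="empty"):
            regional_volumes([], a)


class TestFlowSum:
    def test_trachea_equals_sum_of_terminals(self, breath):
        flow = flow_sum(breath.tree, breath.regional_volumes, breath.phase_times)
        total = sum(breath.regional_volumes[t] for t in breath.tree.terminal_ids())
        assert np.allclose(flow.volumes[breath.tree.root_id], total, rtol=1e-12)

    def test_conservation_at_every_bifurcation(self, breath):
        """Parent volume = sum of daughters at every phase (residual < 1e-9)."""
        flow = flow_sum(breath.tree, breath.regional_volumes, breath.phase_times)
        for sid in breath.tree.segments:
            kids = breath.tree.children(sid)
            if not kids:
                continue
            parent = flow.volumes[sid]
            combined = sum(flow.volumes[k] for k in kids)
            scale = max(np.abs(parent).max(), 1e-30)
            assert np.abs(parent - combined).max() / scale < 1e-9

    def test_missing_terminal_series_errors(self):
        tree = _two_terminal_tree()
        with pytest.raises(ATLError, match="terminal"):
            flow_sum(tree, {1: np.zeros(3)}, [0.0, 1.0, 2.0])

    def test_defect_side_inhales_less(self):
        """An expansion defect reduces tidal volume of the supplying branch."""
        spec = PhantomSpec(tree_generations=2, grid_shape=(96, 96, 96))
        c, semi = spec.lung_center, spec.lung_semiaxes
        defect = DefectSpec(
            center=(c[0], c[1], c[2] - 0.55 * semi[2]),
            radius=0.5 * semi[2], expansion_scale=0.5,
        )
        bs = simulate_breath_series(
            PhantomSpec(tree_generations=2, grid_shape=(96, 96, 96), defects=(defect,))
        )
        flow = flow_sum(bs.tree, bs.regional_volumes, bs.phase_times)
        g1 = bs.tree.children(bs.tree.root_id)
        sides = {
            sid: bs.tree.segments[sid].end[2] - c[2] for sid in g1
        }
        defect_side = min(sides, key=sides.get)  # lower x = defect side
        other = [s for s in g1 if s != defect_side][0]
        assert flow.tidal_volume(defect_side) < flow.tidal_volume(other)


class TestExpiratoryTimeConstant:
    def test_threshold_is_63_percent(self):
        assert round(100 * EXPIRED_FRACTION) == 63

    @pytest.mark.parametrize("tau", [80.0, 100.0, 160.0])
    def test_exponential_deflation_recovered_within_5_percent(self, tau):
        series = BranchFlowSeries(
            phase_times=PHASE_TIMES, volumes={0: 2.5 * _breath_profile(tau)}
        )
        tc = expiratory_time_constant(series, PROTOCOL)
        assert tc.valid[0]
        assert tc.tau_ms[0] == pytest.approx(tau, rel=0.05)

    def test_flat_series_flagged_invalid(self):
        t = PHASE_TIMES
        flat = np.where(t <= 250.0, t / 250.0, 1.0)  # never deflates
        series = BranchFlowSeries(phase_times=PHASE_TIMES, volumes={0: flat})
        tc = expiratory_time_constant(series, PROTOCOL)
        assert not tc.valid[0]
        assert np.isnan(tc.tau_ms[0])

    def test_zero_tidal_volume_flagged_invalid(self):
        series = BranchFlowSeries(phase_times=PHASE_TIMES, volumes={0: np.zeros(15)})
        tc = expiratory_time_constant(series, PROTOCOL)
        assert not tc.valid[0]

    def test_scaling_volumes_leaves_tau_unchanged(self):
        """tau is scale-free: doubling all volumes doubles series, not tau."""
        v = _breath_profile(120.0)
        tc1 = expiratory_time_constant(
            BranchFlowSeries(phase_times=PHASE_TIMES, volumes={0: v}), PROTOCOL
        )
        tc2 = expiratory_time_constant(
            BranchFlowSeries(phase_times=PHASE_TIMES, volumes={0: 2 * v}), PROTOCOL
        )
        assert tc1.tau_ms[0] == pytest.approx(tc2.tau_ms[0], rel=1e-12)

    def test_expfit_method_agrees_on_pure_exponential(self):
        series = BranchFlowSeries(
            phase_times=PHASE_TIMES, volumes={0: _breath_profile(100.0)}
        )
        tc = expiratory_time_constant(series, PROTOCOL, method="expfit")
        assert tc.valid[0]
        assert tc.tau_ms[0] == pytest.approx(100.0, rel=0.05)

    def test_two_group_phantom_classified_without_error(self, breath):
        """Regions with tau in {80, 160} ms separate perfectly at 120 ms."""
        flow = flow_sum(breath.tree, breath.regional_volumes, breath.phase_times)
        tc = expiratory_time_constant(flow, breath.truth.spec.ventilation)
        defect = breath.truth.spec.defects[0]
        endpoints = breath.tree.terminal_endpoints()
        slow_truth = {
            t for t, p in endpoints.items()
            if np.linalg.norm(p - np.array(defect.center)) <= defect.radius
        }
        assert 0 < len(slow_truth) < len(endpoints)
        for tid in endpoints:
            assert tc.valid[tid]
            assert (tc.tau_ms[tid] > 120.0) == (tid in slow_truth)

    def test_defect_branches_slower_than_contralateral(self, breath):
        flow = flow_sum(breath.tree, breath.regional_volumes, breath.phase_times)
        tc = expiratory_time_constant(flow, breath.truth.spec.ventilation)
        defect = breath.truth.spec.defects[0]
        endpoints = breath.tree.terminal_endpoints()
        slow = [t for t, p in endpoints.items()
                if np.linalg.norm(p - np.array(defect.center)) <= defect.radius]
        fast = [t for t in endpoints if t not in slow]
        assert min(tc.tau_ms[t] for t in slow) > max(tc.tau_ms[t] for t in fast)


class TestAerationMap:
    def test_zero_at_functional_residual_capacity(self, breath):
        flow = flow_sum(breath.tree, breath.regional_volumes, breath.phase_times)
        aer = aeration_map(flow, breath.tree)
        assert all(v == 0.0 for v in aer[0].values())

    def test_nondecreasing_during_inspiration(self, breath):
        flow = flow_sum(breath.tree, breath.regional_volumes, breath.phase_times)
        aer = aeration_map(flow, breath.tree)
        insp = [i for i, t in enumerate(breath.phase_times) if t <= 250.0]
        for sid in breath.tree.segments:
            vals = [aer[i][sid] for i in insp]
            assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_trachea_value_equals_total_volume_change(self, breath):
        flow = flow_sum(breath.tree, breath.regional_volumes, breath.phase_times)
        aer = aeration_map(flow, breath.tree)
        for i in range(len(breath.phase_times)):
            assert aer[i][breath.tree.root_id] == pytest.approx(
                breath.total_volume[i], rel=1e-9, abs=1e-9
            )
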