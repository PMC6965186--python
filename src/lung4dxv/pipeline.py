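"""End-to-end pipeline: phantom -> (recon) -> segmentation -> XV -> ATL.

A single structured YAML config mirrors every stage's parameters; all
randomness flows from one seed (stages derive sub-seeds
deterministically), so a full run is reproducible bit for bit. Each
stage writes its outputs under the configured directory and contributes
summary statistics to a JSON manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .core import AirwayTree, Volume4D
from . import atl as atl_mod
from . import io as io_mod
from .airway_seg import VesselnessParams, segment_airways
from .gated_recon import GatingSchedule, ReconGeometry, reconstruct_4d
from .phantom import (
    DefectSpec,
    PhantomSpec,
    VentilationProtocol,
    forward_project,
    simulate_breath_series,
)
from .velocimetry import XVParams, track_breath

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "load_config", "save_config"]

log = logging.getLogger("lung4dxv")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class VentilationSection(_Section):
    pip: float = 12.0
    peep: float = 2.0
    t_insp: float = 250.0
    t_exp: float = 250.0
    respiratory_rate: float = 120.0
    frame_rate: float = 30.0

    def build(self) -> VentilationProtocol:
        return VentilationProtocol(**self.model_dump())


class DefectSection(_Section):
    center: tuple[float, float, float]
    radius: float
    expansion_scale: float = 0.5
    tau_scale: float = 1.0

    def build(self) -> DefectSpec:
        return DefectSpec(**self.model_dump())


class PhantomSection(_Section):
    grid_shape: tuple[int, int, int] = (128, 128, 128)
    voxel_size: float = 1.0
    tree_generations: int = 6
    tidal_fraction: float = 0.12
    speckle_grain: float = 5.0
    noise_sigma: float = 0.0
    n_phases: int = 15
    tau_ms: float = 80.0
    tau_by_region: bool = True
    defects: list[DefectSection] = Field(default_factory=list)
    ventilation: VentilationSection = Field(default_factory=VentilationSection)

    def build(self, seed: int) -> PhantomSpec:
        return PhantomSpec(
            grid_shape=self.grid_shape,
            voxel_size=self.voxel_size,
            tree_generations=self.tree_generations,
            tidal_fraction=self.tidal_fraction,
            speckle_grain=self.speckle_grain,
            noise_sigma=self.noise_sigma,
            n_phases=self.n_phases,
            tau_ms=self.tau_ms,
            tau_by_region=self.tau_by_region,
            defects=tuple(d.build() for d in self.defects),
            ventilation=self.ventilation.build(),
            seed=seed,
        )


class ReconSection(_Section):
    enabled: bool = False
    r1: float = 200.0
    r2: float = 400.0
    detector_pitch: float = 2.0
    detector_shape: tuple[int, int] = (96, 96)
    n_projections: int = 450
    out_shape: tuple[int, int, int] | None = None

    def geometry(self) -> ReconGeometry:
        return ReconGeometry(
            r1=self.r1, r2=self.r2, detector_pitch=self.detector_pitch,
            detector_shape=self.detector_shape,
        )


class SegmentationSection(_Section):
    enabled: bool = True
    scale_low: float = 1.0
    scale_high: float = 8.0
    n_scales: int = 6
    alpha: float = 0.5
    beta: float = 0.5
    threshold: float | None = 0.1
    prune_factor: float = 2.5
    seed_voxel: tuple[int, int, int] | None = None  # default: inside phantom trachea

    def params(self) -> VesselnessParams:
        return VesselnessParams(
            scales=tuple(np.geomspace(self.scale_low, self.scale_high, self.n_scales)),
            alpha=self.alpha, beta=self.beta,
        )


class XVSection(_Section):
    enabled: bool = True
    window: int = 32
    overlap: float = 0.5
    smooth_sigma: float = 1.0
    band_low: float = 0.02
    band_high: float = 0.25
    peak_quality_min: float = 1.2
    fill_invalid: bool = True
    subpixel: Literal["gaussian", "parabolic"] = "gaussian"

    def params(self, lung_mask: np.ndarray | None) -> XVParams:
        return XVParams(
            window=self.window, overlap=self.overlap, smooth_sigma=self.smooth_sigma,
            band_low=self.band_low, band_high=self.band_high,
            peak_quality_min=self.peak_quality_min, lung_mask=lung_mask,
            fill_invalid=self.fill_invalid, subpixel=self.subpixel,
        )


class ATLSection(_Section):
    enabled: bool = True
    tree_source: Literal["segmented", "phantom"] = "segmented"
    tau_method: Literal["threshold", "expfit"] = "threshold"


class PipelineConfig(_Section):
    """Top-level configuration; unknown keys are rejected."""

    outdir: str = "lung4dxv_out"
    seed: int = 0
    verbosity: str = "INFO"
    phantom: PhantomSection = Field(default_factory=PhantomSection)
    recon: ReconSection = Field(default_factory=ReconSection)
    segmentation: SegmentationSection = Field(default_factory=SegmentationSection)
    xv: XVSection = Field(default_factory=XVSection)
    atl: ATLSection = Field(default_factory=ATLSection)


def load_config(path: str | Path) -> PipelineConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig.model_validate(data)


def save_config(path: str | Path, config: PipelineConfig) -> None:
    Path(path).write_text(yaml.safe_dump(config.model_dump(), sort_keys=False))


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages in order; returns the manifest.

    Stage failures raise :class:`PipelineError` naming the stage. The
    manifest records the package version, config hash, and per-stage
    summary statistics, and is also written to ``outdir/manifest.json``.
    """
    logging.basicConfig(level=getattr(logging, config.verbosity.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stages": {},
    }

    def run_stage(name, fn):
        try:
            log.info("stage %s: start", name)
            summary = fn()
            manifest["stages"][name] = summary
            log.info("stage %s: %s", name, summary)
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    state: dict = {}

    def stage_phantom():
        spec = config.phantom.build(config.seed)
        bs = simulate_breath_series(spec)
        state["breath"] = bs
        io_mod.write_volume4d(outdir / "phantom", bs.volume4d)
        io_mod.tree_to_json(outdir / "phantom" / "tree_truth.json", bs.tree)
        io_mod.tree_to_vtk(outdir / "phantom" / "tree_truth.vtk", bs.tree)
        io_mod.tree_to_csv(outdir / "phantom" / "tree_truth.csv", bs.tree)
        np.savetxt(
            outdir / "phantom" / "total_volume_truth.csv",
            np.column_stack([bs.phase_times, bs.total_volume]),
            delimiter=",", header="phase_time_ms,total_volume", comments="",
        )
        return {
            "grid_shape": list(spec.grid_shape),
            "n_phases": spec.n_phases,
            "n_segments": bs.tree.n_segments,
            "lung_voxels": int(bs.lung_mask.sum()),
            "peak_tidal_volume": float(bs.total_volume.max()),
        }

    def stage_recon():
        bs = state["breath"]
        geom = config.recon.geometry()
        vent = config.phantom.ventilation
        schedule = GatingSchedule(
            frame_rate=vent.frame_rate, respiratory_rate=vent.respiratory_rate,
            n_phases=config.phantom.n_phases,
        )
        n = config.recon.n_projections
        angles = np.arange(n) * 360.0 / n
        projections = forward_project(bs.volume4d, geom, angles, schedule=schedule)
        (outdir / "recon").mkdir(parents=True, exist_ok=True)
        io_mod.write_projections(
            outdir / "recon" / "projections.tif", outdir / "recon" / "projections.csv",
            projections,
        )
        out_shape = config.recon.out_shape or bs.volume4d.grid_shape
        vol4d = reconstruct_4d(projections, schedule, geom, tuple(out_shape))
        state["recon4d"] = vol4d
        io_mod.write_volume4d(outdir / "recon", vol4d, prefix="recon")
        return {
            "n_projections": n,
            "per_phase": int(n // schedule.n_phases),
            "out_shape": list(out_shape),
        }

    def stage_segment():
        bs = state["breath"]
        seed_voxel = config.segmentation.seed_voxel
        if seed_voxel is None:
            root = bs.tree.segments[bs.tree.root_id]
            seed_voxel = tuple(int(round(v)) for v in root.points[len(root.points) // 2])
        tree = segment_airways(
            bs.volume4d, config.segmentation.params(), seed_voxel,
            threshold=config.segmentation.threshold,
            prune_factor=config.segmentation.prune_factor,
        )
        state["segmented_tree"] = tree
        io_mod.tree_to_vtk(outdir / "tree_segmented.vtk", tree)
        io_mod.tree_to_csv(outdir / "tree_segmented.csv", tree)
        io_mod.tree_to_json(outdir / "tree_segmented.json", tree)
        return {
            "n_segments": tree.n_segments,
            "n_bifurcations": tree.n_bifurcations,
            "max_generation": tree.max_generation,
        }

    def stage_xv():
        bs = state["breath"]
        params = config.xv.params(bs.lung_mask)
        trk = track_breath(bs.volume4d, params)
        state["tracking"] = trk
        (outdir / "xv").mkdir(parents=True, exist_ok=True)
        for i, f in enumerate(trk.fields):
            io_mod.field_to_csv(outdir / "xv" / f"field_{i:02d}.csv", f)
        io_mod.expansion_to_vtk(
            outdir / "xv" / "cumulative_expansion.vtk", trk.cumulative_expansion()
        )
        return {
            "n_intervals": trk.n_intervals,
            "grid_shape": list(trk.fields[0].grid.shape),
            "median_valid_fraction": float(
                np.median([f.valid.mean() for f in trk.fields])
            ),
        }

    def stage_atl():
        bs = state["breath"]
        trk = state["tracking"]
        if config.atl.tree_source == "segmented":
            tree: AirwayTree = state.get("segmented_tree") or bs.tree
        else:
            tree = bs.tree
        assign = atl_mod.assign_regions(bs.lung_mask, tree)
        peak = int(np.argmax(bs.total_volume))
        series = atl_mod.regional_volumes(
            trk.expansions, assign, config.phantom.voxel_size
        )
        flow = atl_mod.flow_sum(tree, series, bs.phase_times)
        tc = atl_mod.expiratory_time_constant(
            flow, config.phantom.ventilation.build(), method=config.atl.tau_method
        )
        (outdir / "atl").mkdir(parents=True, exist_ok=True)
        rows = []
        for sid in sorted(tree.segments):
            rows.append(
                {
                    "segment_id": sid,
                    "generation": tree.segments[sid].generation,
                    "tidal_volume": flow.tidal_volume(sid),
                    "tau_ms": tc.tau_ms[sid],
                    "valid": tc.valid[sid],
                }
            )
        import pandas as pd

        pd.DataFrame(rows).to_csv(outdir / "atl" / "branches.csv", index=False)
        aer = atl_mod.aeration_map(flow, tree)
        io_mod.tree_to_vtk(
            outdir / "atl" / "tree_aeration_peak.vtk", tree,
            segment_scalars={"cumulative_volume": aer[peak]},
        )
        io_mod.tree_to_vtk(
            outdir / "atl" / "tree_tau.vtk", tree,
            segment_scalars={"tau_ms": {s: (tc.tau_ms[s] if tc.valid[s] else 0.0)
                                        for s in tree.segments}},
        )
        root_id = tree.root_id
        return {
            "tree_source": config.atl.tree_source,
            "n_terminals": len(tree.terminal_ids()),
            "trachea_tidal_volume": flow.tidal_volume(root_id),
            "trachea_tau_ms": tc.tau_ms[root_id],
        }

    run_stage("phantom", stage_phantom)
    if config.recon.enabled:
        run_stage("recon", stage_recon)
    if config.segmentation.enabled:
        run_stage("segment", stage_segment)
    if config.xv.enabled:
        run_stage("xv", stage_xv)
    if config.atl.enabled and config.xv.enabled:
        run_stage("atl", stage_atl)

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
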