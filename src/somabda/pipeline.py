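"""End-to-end boundary delimitation pipeline on a single scan.

The four steps: locate the nucleus proxy C_90, estimate the heading
direction, rotate/translate/interpolate onto the heading-aligned lattice,
then delimit the soma line-wise and integrate its volume.  Live recordings
are plane-corrected and floor-filtered first; noiseless phantoms skip both
(and extension-free phantoms may skip the heading/rotation steps entirely,
evaluating the contour fits directly on the source lattice).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import nucleus, scan_model, soma_contour
from .heading import DEFAULT_DTHETA, heading_direction
from .regrid import RotatedGrid, rotate_scan
from .scan_model import ScanGrid
from .volume import VolumeReport, soma_volume

__all__ = ["PipelineConfig", "run_pipeline", "bda_report", "bda_report_norot"]

log = logging.getLogger("somabda")


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable parameters of the pipeline (defaults suit live 30 µm scans)."""

    T: float = 0.9                 # relative threshold of the nucleus proxy
    min_height: float = 1.0        # µm; dish cut for floor filter and heading
    degree: int = 3                # polynomial degree of the contour fits
    dtheta: float = DEFAULT_DTHETA
    plane_correction: bool = True
    substrate_quantile: float = 0.3

    def __post_init__(self):
        if not 0 < self.T < 1:
            raise ValueError("T must lie in (0, 1)")
        if self.degree < 1:
            raise ValueError("degree must be >= 1")
        if self.dtheta <= 0:
            raise ValueError("dtheta must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def bda_report(
    grid: ScanGrid,
    config: PipelineConfig = PipelineConfig(),
    preprocess: bool = True,
) -> tuple[VolumeReport, RotatedGrid, "soma_contour.SomaRegion"]:
    """Run the four delimitation steps on an in-memory grid.

    With ``preprocess=False`` the plane correction and floor filter are
    skipped and the heading search counts every positive pixel — the setting
    for noiseless phantoms.
    """
    if preprocess:
        if config.plane_correction:
            grid = scan_model.plane_correct(grid, config.substrate_quantile)
        grid = scan_model.floor_filter(grid, config.min_height)
        min_height = config.min_height
    else:
        min_height = 0.0
    if grid.z.max() <= 0:
        raise ValueError("no cell in frame: grid is all zero after filtering")
    c90 = nucleus.c90(grid, config.T)
    log.info("step 1: C_90 = (%.3f, %.3f)", *c90)
    head = heading_direction(grid, c90, min_height=min_height, dtheta=config.dtheta)
    log.info("step 2: theta_h = %.4f rad (%.1f deg)", head.theta_h, np.degrees(head.theta_h))
    rgrid = rotate_scan(grid, c90, head.theta_h)
    log.info("step 3: rotated lattice %d x %d", rgrid.xlevels.size, rgrid.ylevels.size)
    region = soma_contour.soma_region(rgrid, n=config.degree)
    report = soma_volume(rgrid, region, grid)
    log.info(
        "step 4: V_total = %.2f fL (front %.2f, rear %.2f), discarded=%s",
        report.V_total, report.V_front, report.V_rear, report.discarded,
    )
    return report, rgrid, region


def bda_report_norot(
    grid: ScanGrid,
    config: PipelineConfig = PipelineConfig(),
) -> tuple[VolumeReport, RotatedGrid, "soma_contour.SomaRegion"]:
    """Contour delimitation directly on the source lattice (no rotation).

    The source grid is viewed in nucleus-proxy-centred coordinates without
    resampling; appropriate for objects whose heading is already axis-aligned
    or undefined (extension-free phantoms).
    """
    if grid.z.max() <= 0:
        raise ValueError("no cell in frame: grid is all zero")
    cx, cy = nucleus.c90(grid, config.T)
    view = RotatedGrid(
        xlevels=grid.x - cx,
        ylevels=grid.y - cy,
        z=grid.z,
        theta_h=0.0,
        center=(cx, cy),
    )
    region = soma_contour.soma_region(view, n=config.degree)
    report = soma_volume(view, region, grid)
    return report, view, region


def run_pipeline(path, config: PipelineConfig = PipelineConfig(), preprocess: bool = True):
    """Read a scan file and run the full pipeline."""
    grid = scan_model.read_scan(path)
    return bda_report(grid, config, preprocess=preprocess)
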