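"""Model/Results interface tying geometry, simulation and inversion together.

:class:`CoolingModel` is constructed from the case data (a scaled surface
mesh with registered markers, or a prepared voxel grid), forward-simulates
the individualised cooling look-up tables once, and ``fit()`` inverts a
set of measured skin temperatures into a :class:`PMIResults` object
carrying the per-record estimates, the case median PMI with its MAD
spread, the estimated time-of-death interval, and a ``summary()`` table.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import geometry
from .geometry import MarkerObservation, TriangleMesh, VoxelGrid
from .pmi import (DEFAULT_SLOPE_FLOOR_C_PER_H, DEFAULT_TOLERANCE_C, CaseResult,
                  MeasurementRecord, reconstruct_case)
from .thermo import (Material, SimulationConfig, SimulationResult,
                     default_materials, simulate)

log = logging.getLogger(__name__)


class CoolingModel:
    """Individualised post-mortem cooling model for one body/scene.

    Parameters
    ----------
    grid : VoxelGrid
        Voxelized body with materials assigned.
    probes : mapping site -> (i, j, k)
        Skin-surface grid cells co-registered with the thermometry sites.
    materials : mapping label -> Material, optional
        Thermal properties; defaults to the shipped table.
    config : SimulationConfig, optional
        Solver settings (step, span, initial temperatures, ambient
        schedule); defaults to 36 h at 60 s steps, 37/20 deg C.
    """

    def __init__(self, grid: VoxelGrid, probes: Mapping[str, tuple],
                 materials: Mapping[str, Material] | None = None,
                 config: SimulationConfig | None = None):
        self.grid = grid
        self.probes = dict(probes)
        self.materials = dict(materials or default_materials())
        self.config = config or SimulationConfig(duration_h=36.0)
        self.config.probes = self.probes
        self._result: SimulationResult | None = None

    @classmethod
    def from_mesh(cls, mesh: TriangleMesh,
                  markers: Sequence[MarkerObservation], *,
                  dx: float = geometry.DEFAULT_DX,
                  padding: int = geometry.DEFAULT_PADDING_CUBES,
                  floor_height: float | None = None,
                  adipose_shell_m: float = 0.02,
                  materials=None, config=None) -> "CoolingModel":
        """Voxelize a surface mesh and register its markers in one step."""
        grid = geometry.voxelize(mesh, dx=dx, padding=padding)
        if floor_height is not None:
            grid = geometry.assign_substrate(grid, floor_height)
        grid = geometry.assign_adipose_shell(grid, adipose_shell_m)
        probes = {m.site: geometry.register_marker(grid, m)
                  for m in markers if m.site in geometry.BODY_SITES}
        return cls(grid, probes, materials=materials, config=config)

    def simulate(self) -> SimulationResult:
        """Run (and cache) the forward cooling simulation."""
        if self._result is None:
            self._result = simulate(self.grid, self.materials, self.config)
        return self._result

    @property
    def curves(self) -> dict:
        return self.simulate().curves_by_site()

    def fit(self, records: Sequence[MeasurementRecord],
            tolerance_C: float = DEFAULT_TOLERANCE_C,
            slope_floor: float = DEFAULT_SLOPE_FLOOR_C_PER_H) -> "PMIResults":
        """Invert measured skin temperatures into a case PMI estimate."""
        case = reconstruct_case(self.curves, records, tolerance_C,
                                slope_floor)
        return PMIResults(self, case)


@dataclass
class PMIResults:
    """Fitted PMI reconstruction for one case."""

    model: CoolingModel
    case: CaseResult

    @property
    def median_pmi_h(self) -> float:
        return self.case.median_pmi_h

    @property
    def mad_h(self) -> float:
        return self.case.mad_h

    @property
    def time_of_death(self) -> pd.Timestamp:
        return self.case.time_of_death

    def to_frame(self) -> pd.DataFrame:
        return self.case.to_frame()

    def diagnostics(self) -> dict:
        sim = self.model.simulate()
        frame = self.to_frame()
        return {
            "stability_limit_s": sim.stability_limit_s,
            "substeps_per_step": sim.substeps,
            "tissue_cubes": int(self.model.grid.tissue_mask.sum()),
            "grid_dims": list(self.model.grid.dims),
            "per_site_min_residual_C": {
                site: float(sub["min_residual_C"].min())
                for site, sub in frame.groupby("site")},
            "status_counts": frame["status"].value_counts().to_dict(),
        }

    def to_report(self) -> dict:
        case = self.case
        return {
            "median_pmi_h": case.median_pmi_h,
            "mad_h": case.mad_h,
            "reference_time": case.reference_time.isoformat(),
            "time_of_death": case.time_of_death.isoformat(),
            "time_of_death_earliest": case.earliest.isoformat(),
            "time_of_death_latest": case.latest.isoformat(),
            "n_records": len(case.records),
            "diagnostics": self.diagnostics(),
        }

    def summary(self) -> str:
        """Plain-text summary table in the spirit of statistical model fits."""
        case = self.case
        frame = self.to_frame()
        diag = self.diagnostics()
        lines = [
            "Individualised cooling-model PMI reconstruction",
            "=" * 55,
            f"records:            {len(case.records)}"
            f"  (ok: {diag['status_counts'].get('ok', 0)})",
            f"tissue cubes:       {diag['tissue_cubes']}"
            f"  grid {tuple(diag['grid_dims'])}",
            f"median PMI:         {case.median_pmi_h:8.2f} h",
            f"MAD:                {case.mad_h:8.2f} h",
            f"time of death:      {case.time_of_death}",
            f"interval:           {case.earliest}  ..  {case.latest}",
            "-" * 55,
            f"{'site':<12}{'n':>4}{'median PMI h':>14}{'min resid C':>13}",
        ]
        ref = case.reference_time
        frame = frame.assign(rel_pmi_h=frame["pmi_h"] + (
            (ref - frame["clock_time"]).dt.total_seconds() / 3600.0))
        for site, sub in frame.groupby("site"):
            lines.append(f"{site:<12}{len(sub):>4}"
                         f"{sub['rel_pmi_h'].median():>14.2f}"
                         f"{sub['min_residual_C'].min():>13.3f}")
        return "\n".join(lines)

    def save_report(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_report(), fh, indent=1, sort_keys=True)
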