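"""Explicit finite-difference simulation of post-mortem heat exchange.

The body and its surroundings are discretised into cubes of edge ``dx``
(1 cm by default).  Every time step, the heat exchanged across each shared
cube face is computed and converted into a temperature update:

* conduction between material cubes, ``Q = k_eff A (T_j - T_i) / dx * dt``
  with ``k_eff`` the harmonic mean of the two conductivities;
* convection at faces exposed to air, ``Q = h A (T_air - T_i) * dt``;
* radiation at exposed faces, ``Q = eps sigma A (T_rad^4 - T_i^4) * dt``
  with temperatures in kelvin (full T^4, no linearisation).

Air cubes are boundary cubes pinned to the ambient temperature schedule
rather than simulated fluid.  Time integration is explicit forward Euler
with automatic sub-stepping below the Fourier stability bound
``dx^2 * min(rho c / 6 k)``.  Temperatures are stored in deg C and
converted to kelvin only inside the radiation term.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .geometry import TISSUE_MATERIALS, VoxelGrid

log = logging.getLogger(__name__)

#: Stefan-Boltzmann constant, W m^-2 K^-4.
SIGMA_SB = 5.670374419e-8
_KELVIN = 273.15
#: Hard cap on automatic sub-steps per configured step.
MAX_SUBSTEPS = 1000


class NumericalError(RuntimeError):
    """The explicit scheme produced a non-finite temperature."""


@dataclass(frozen=True)
class Material:
    """Thermal properties of one cube material.

    ``k=0`` marks a non-conducting boundary fluid (air); ``pinned``
    materials track the ambient schedule instead of being integrated
    (air, or solid Dirichlet boundaries); ``body`` materials receive the
    initial body temperature.
    """

    k: float                 # thermal conductivity, W m^-1 K^-1
    rho: float               # density, kg m^-3
    c: float                 # specific heat capacity, J kg^-1 K^-1
    emissivity: float = 0.0  # dimensionless, 0..1
    h_conv: float = 0.0      # convective film coefficient, W m^-2 K^-1
    pinned: bool = False
    body: bool = False

    def __post_init__(self):
        if self.k < 0 or self.rho <= 0 or self.c <= 0:
            raise ValueError("require k >= 0, rho > 0, c > 0")
        if not 0.0 <= self.emissivity <= 1.0:
            raise ValueError("emissivity must be in [0, 1]")
        if self.h_conv < 0:
            raise ValueError("h_conv must be >= 0")


def default_materials() -> dict:
    """Default material table (all values overridable defaults).

    Tissue and substrate properties are representative literature values
    for soft tissue, adipose tissue and a concrete-like floor; they are
    configuration defaults, not measured constants.
    """
    return {
        "tissue_core": Material(k=0.5, rho=1050.0, c=3600.0,
                                emissivity=0.98, h_conv=5.0, body=True),
        "tissue_adipose": Material(k=0.21, rho=920.0, c=2300.0,
                                   emissivity=0.98, h_conv=5.0, body=True),
        "substrate": Material(k=1.0, rho=2300.0, c=880.0,
                              emissivity=0.9, h_conv=0.0),
        "air": Material(k=0.0, rho=1.2, c=1005.0, pinned=True),
    }


class AmbientSchedule:
    """Piecewise-linear ambient (and optional radiative) temperature vs time.

    Times are hours since simulation start (death); temperatures deg C.
    Outside the breakpoint span the schedule holds its end values.
    """

    def __init__(self, times_h, temps_C, rad_temps_C=None):
        self.times_h = np.asarray(times_h, dtype=float)
        self.temps_C = np.asarray(temps_C, dtype=float)
        if self.times_h.ndim != 1 or self.times_h.shape != self.temps_C.shape:
            raise ValueError("times and temperatures must be 1D, same length")
        if len(self.times_h) == 0 or np.any(np.diff(self.times_h) <= 0):
            raise ValueError("breakpoint times must be strictly increasing")
        self.rad_temps_C = (None if rad_temps_C is None
                            else np.asarray(rad_temps_C, dtype=float))

    @classmethod
    def constant(cls, temp_C: float) -> "AmbientSchedule":
        return cls([0.0], [float(temp_C)])

    def air(self, t_h: float) -> float:
        return float(np.interp(t_h, self.times_h, self.temps_C))

    def radiative(self, t_h: float) -> float:
        if self.rad_temps_C is None:
            return self.air(t_h)
        return float(np.interp(t_h, self.times_h, self.rad_temps_C))

    @classmethod
    def from_csv(cls, path) -> "AmbientSchedule":
        df = pd.read_csv(path)
        return cls(df["time_h"].to_numpy(), df["temp_C"].to_numpy())


@dataclass
class SimulationConfig:
    """Solver settings for one forward cooling simulation."""

    duration_h: float
    dt_s: float = 60.0
    t_body0_C: float = 37.0
    t_env0_C: float = 20.0
    ambient: AmbientSchedule | None = None
    probes: Mapping[str, tuple] = field(default_factory=dict)
    snapshot_times_h: tuple = ()

    def __post_init__(self):
        if self.dt_s <= 0 or self.duration_h <= 0:
            raise ValueError("dt_s and duration_h must be positive")
        if self.ambient is None:
            self.ambient = AmbientSchedule.constant(self.t_env0_C)


@dataclass
class CoolingCurve:
    """Simulated probe temperature vs time since death (the look-up table)."""

    site: str
    index: tuple
    times_h: np.ndarray
    temps_C: np.ndarray

    def __post_init__(self):
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.temps_C = np.asarray(self.temps_C, dtype=float)
        if self.times_h.shape != self.temps_C.shape:
            raise ValueError("times and temps must have equal length")

    def __call__(self, t_h) -> np.ndarray:
        return np.interp(t_h, self.times_h, self.temps_C)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"site": self.site, "time_h": self.times_h,
                             "temp_C": self.temps_C})


@dataclass
class SimulationResult:
    curves: list
    snapshots: dict          # time_h -> (nx, ny, nz) temperature array
    stability_limit_s: float
    substeps: int

    def curve(self, site: str) -> CoolingCurve:
        for c in self.curves:
            if c.site == site:
                return c
        raise KeyError(site)

    def curves_by_site(self) -> dict:
        return {c.site: c for c in self.curves}


def stability_limit(materials: Mapping[str, Material], dx: float,
                    labels=None) -> float:
    """Largest stable explicit step, ``dx^2 * min(rho c / 6 k)`` (seconds)."""
    mats = [materials[l] for l in (labels if labels is not None else materials)]
    bounds = [dx * dx * m.rho * m.c / (6.0 * m.k) for m in mats if m.k > 0]
    return min(bounds) if bounds else math.inf


class _Solver:
    """Precomputed per-cube arrays for the explicit update."""

    def __init__(self, grid: VoxelGrid, materials: Mapping[str, Material]):
        self.grid = grid
        self.dx = grid.dx
        labels = np.unique(grid.material)
        missing = [l for l in labels if l not in materials]
        if missing:
            raise KeyError(f"materials missing for labels: {missing}")
        shape = grid.dims
        self.k = np.zeros(shape)
        self.rhoc = np.ones(shape)
        self.eps = np.zeros(shape)
        self.h = np.zeros(shape)
        self.pinned = np.zeros(shape, dtype=bool)
        self.fluid = np.zeros(shape, dtype=bool)
        self.body = np.zeros(shape, dtype=bool)
        for label in labels:
            m = materials[label]
            sel = grid.material == label
            self.k[sel] = m.k
            self.rhoc[sel] = m.rho * m.c
            self.eps[sel] = m.emissivity
            self.h[sel] = m.h_conv
            self.pinned[sel] = m.pinned
            self.fluid[sel] = m.pinned and m.k == 0.0
            self.body[sel] = m.body
        self.active = ~self.pinned & ~self.fluid
        self.used_labels = list(labels)

        dx = self.dx
        area = dx * dx
        self.keff = []
        for axis in range(3):
            ka = self._lo(self.k, axis)
            kb = self._hi(self.k, axis)
            with np.errstate(divide="ignore", invalid="ignore"):
                keff = np.where((ka > 0) & (kb > 0),
                                2.0 * ka * kb / np.maximum(ka + kb, 1e-300),
                                0.0)
            self.keff.append(keff * area / dx)  # W/K per face
        # Number of faces each active cube exposes to fluid (air).
        n_exp = np.zeros(shape)
        for axis in range(3):
            lo = self._lo_idx(axis)
            hi = self._hi_idx(axis)
            n_exp[lo] += self.fluid[hi]
            n_exp[hi] += self.fluid[lo]
        n_exp[~self.active] = 0.0
        self.conv_coef = self.h * area * n_exp           # W/K
        self.rad_coef = self.eps * SIGMA_SB * area * n_exp  # W/K^4
        self.cap = self.rhoc * dx ** 3                    # J/K per cube

    @staticmethod
    def _lo_idx(axis):
        s = [slice(None)] * 3
        s[axis] = slice(None, -1)
        return tuple(s)

    @staticmethod
    def _hi_idx(axis):
        s = [slice(None)] * 3
        s[axis] = slice(1, None)
        return tuple(s)

    def _lo(self, arr, axis):
        return arr[self._lo_idx(axis)]

    def _hi(self, arr, axis):
        return arr[self._hi_idx(axis)]

    def step(self, T: np.ndarray, t_air: float, t_rad: float,
             dt: float) -> np.ndarray:
        """One explicit sub-step; returns the updated field (new array)."""
        power = np.zeros_like(T)  # net heat rate per cube, W
        for axis in range(3):
            lo = self._lo_idx(axis)
            hi = self._hi_idx(axis)
            flux = self.keff[axis] * (T[hi] - T[lo])  # W into the lo cube
            power[lo] += flux
            power[hi] -= flux
        power += self.conv_coef * (t_air - T)
        t_rad_k4 = (t_rad + _KELVIN) ** 4
        power += self.rad_coef * (t_rad_k4 - (T + _KELVIN) ** 4)
        out = T + np.where(self.active, power * dt / self.cap, 0.0)
        out[self.fluid] = t_air
        out[self.pinned & ~self.fluid] = t_air
        return out


def step_temperature(T: np.ndarray, grid: VoxelGrid,
                     materials: Mapping[str, Material],
                     ambient_now, dt: float) -> np.ndarray:
    """Advance one temperature field by a single explicit step.

    ``ambient_now`` is the (air, radiative-environment) temperature pair in
    deg C; a scalar is treated as both.
    """
    if np.isscalar(ambient_now):
        t_air = t_rad = float(ambient_now)
    else:
        t_air, t_rad = (float(v) for v in ambient_now)
    solver = _Solver(grid, materials)
    out = solver.step(np.asarray(T, dtype=float), t_air, t_rad, dt)
    if not np.isfinite(out).all():
        bad = tuple(int(v) for v in np.argwhere(~np.isfinite(out))[0])
        raise NumericalError(f"non-finite temperature at cube {bad}")
    return out


def simulate(grid: VoxelGrid, materials: Mapping[str, Material],
             config: SimulationConfig) -> SimulationResult:
    """Forward-simulate cooling; returns probe curves and optional snapshots.

    Initial condition: body-material cubes at ``t_body0_C``, everything else
    at the ambient schedule value at t=0.  Probe temperatures are recorded
    every configured ``dt_s``.  Deterministic.
    """
    solver = _Solver(grid, materials)
    for site, idx in config.probes.items():
        if grid.material[tuple(idx)] not in TISSUE_MATERIALS:
            raise ValueError(
                f"probe {site!r} at {tuple(idx)} sits on "
                f"{grid.material[tuple(idx)]!r}, not tissue")

    limit = stability_limit(materials, grid.dx, labels=solver.used_labels)
    n_sub = max(1, math.ceil(config.dt_s / limit)) if math.isfinite(limit) else 1
    if n_sub > MAX_SUBSTEPS:
        raise NumericalError(
            f"stability bound {limit:.3g} s requires {n_sub} sub-steps per "
            f"{config.dt_s} s step (cap {MAX_SUBSTEPS}); refine dt or dx")
    dt_sub = config.dt_s / n_sub
    n_steps = int(round(config.duration_h * 3600.0 / config.dt_s))
    log.info("simulate: %d cubes (%d active), stability %.1f s, %d sub-steps, "
             "%d steps", grid.material.size, int(solver.active.sum()), limit,
             n_sub, n_steps)

    ambient = config.ambient
    T = np.full(grid.dims, ambient.air(0.0), dtype=float)
    T[solver.body] = config.t_body0_C

    probe_idx = {site: tuple(idx) for site, idx in config.probes.items()}
    times = np.arange(n_steps + 1) * config.dt_s / 3600.0
    traces = {site: np.empty(n_steps + 1) for site in probe_idx}
    for site, idx in probe_idx.items():
        traces[site][0] = T[idx]
    snap_steps = {int(round(t * 3600.0 / config.dt_s)): t
                  for t in config.snapshot_times_h}
    snapshots = {}
    if 0 in snap_steps:
        snapshots[snap_steps[0]] = T.copy()

    t_now = 0.0
    for step in range(1, n_steps + 1):
        for _ in range(n_sub):
            t_mid = t_now + 0.5 * dt_sub / 3600.0
            T = solver.step(T, ambient.air(t_mid), ambient.radiative(t_mid),
                            dt_sub)
            t_now += dt_sub / 3600.0
        if not np.isfinite(T).all():
            bad = tuple(int(v) for v in np.argwhere(~np.isfinite(T))[0])
            raise NumericalError(
                f"non-finite temperature at cube {bad}, step {step}")
        for site, idx in probe_idx.items():
            traces[site][step] = T[idx]
        if step in snap_steps:
            snapshots[snap_steps[step]] = T.copy()

    curves = [CoolingCurve(site, probe_idx[site], times, traces[site])
              for site in probe_idx]
    return SimulationResult(curves, snapshots, limit, n_sub)


def thermal_energy(grid: VoxelGrid, materials: Mapping[str, Material],
                   T: np.ndarray, labels=TISSUE_MATERIALS) -> float:
    """Sum of rho c V T over cubes with the given labels (J, deg C datum)."""
    total = 0.0
    v = grid.dx ** 3
    for label in labels:
        m = materials[label]
        sel = grid.material == label
        total += float((m.rho * m.c * v * T[sel]).sum())
    return total


def save_curves(curves, path) -> None:
    pd.concat([c.to_frame() for c in curves], ignore_index=True).to_csv(
        path, index=False)


def load_curves(path) -> dict:
    df = pd.read_csv(path)
    out = {}
    for site, sub in df.groupby("site", sort=False):
        out[str(site)] = CoolingCurve(str(site), (), sub["time_h"].to_numpy(),
                                      sub["temp_C"].to_numpy())
    return out
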