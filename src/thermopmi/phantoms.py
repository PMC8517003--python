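"""Synthetic phantoms: posed body meshes, logger series, thermal rasters.

Real cadaver and crime-scene data are protected, so every other module is
exercised on synthetic stand-ins: a capsule/sphere union body mesh in one
of three posture presets (straight, bent_arm, fetal), forward-simulated
skin-temperature "logger" series with additive Gaussian sensor noise, and
synthetic thermal rasters showing cool logger discs over warmer skin
patches.  Capsule unions deliberately produce non-convex geometry with
only partial substrate contact — the hard case the individualised grid
representation exists for.

All randomness flows through one seeded NumPy generator, so a fixed seed
gives byte-identical outputs.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh

from . import geometry
from ._inside import winding_number_inside
from .geometry import (BODY_SITES, MarkerObservation, TriangleMesh, VoxelGrid,
                       register_marker)
from .pmi import MeasurementRecord
from .thermo import (CoolingCurve, Material, SimulationConfig, SimulationResult,
                     default_materials, simulate)
from .thermometry import RingROI, ThermalMap

log = logging.getLogger(__name__)

POSTURES = ("straight", "bent_arm", "fetal")
#: Arbitrary but fixed death clock used to stamp synthetic measurements.
DEFAULT_DEATH_CLOCK = pd.Timestamp("2021-03-01T00:00:00")


@dataclass(frozen=True)
class Primitive:
    """One body-segment primitive: capsule between two points or a sphere."""

    kind: str                  # "capsule" | "sphere" | "box"
    p0: tuple                  # capsule start / sphere centre / box centre
    p1: tuple = None           # capsule end
    radius: float = 0.0
    extents: tuple = None      # box only


@dataclass
class PhantomSpec:
    """Recipe for a synthetic posed body."""

    primitives: list
    markers: dict              # site -> surface anchor point (3-vector)
    posture: str = "straight"
    floor_height: float = 0.0
    seed: int = 0
    label: str = "phantom"


def _capsule_between(p0, p1, radius, sections=24) -> trimesh.Trimesh:
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    vec = p1 - p0
    height = float(np.linalg.norm(vec))
    cap = trimesh.creation.capsule(radius=radius, height=height,
                                   count=(sections, sections))
    # trimesh capsules are centred on the origin along +z.
    transform = trimesh.geometry.align_vectors([0.0, 0.0, 1.0], vec / height)
    transform[:3, 3] = (p0 + p1) / 2.0
    cap.apply_transform(transform)
    return cap


def _primitive_mesh(p: Primitive) -> trimesh.Trimesh:
    if p.kind == "capsule":
        return _capsule_between(p.p0, p.p1, p.radius)
    if p.kind == "sphere":
        m = trimesh.creation.icosphere(subdivisions=3, radius=p.radius)
        m.apply_translation(np.asarray(p.p0, dtype=float))
        return m
    if p.kind == "box":
        m = trimesh.creation.box(extents=p.extents)
        m.apply_translation(np.asarray(p.p0, dtype=float))
        return m
    raise ValueError(f"unknown primitive kind {p.kind!r}")


def _primitives_connected(meshes) -> bool:
    """Overlap graph connectivity, tested by mutual vertex containment."""
    n = len(meshes)
    if n <= 1:
        return True
    adj = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            vi = np.asarray(meshes[i].vertices)
            inside = winding_number_inside(vi[:: max(1, len(vi) // 64)],
                                           np.asarray(meshes[j].vertices),
                                           np.asarray(meshes[j].faces))
            if inside.any():
                adj[i, j] = adj[j, i] = True
                continue
            vj = np.asarray(meshes[j].vertices)
            inside = winding_number_inside(vj[:: max(1, len(vj) // 64)],
                                           np.asarray(meshes[i].vertices),
                                           np.asarray(meshes[i].faces))
            if inside.any():
                adj[i, j] = adj[j, i] = True
    seen = {0}
    frontier = [0]
    while frontier:
        cur = frontier.pop()
        for other in np.flatnonzero(adj[cur]):
            if other not in seen:
                seen.add(int(other))
                frontier.append(int(other))
    return len(seen) == n


def body_spec(posture: str = "straight", stature_m: float = 1.70,
              seed: int = 0) -> PhantomSpec:
    """Capsule-union body phantom lying on the floor plane z=0.

    The body axis runs along +x (feet towards -x, head towards +x); the
    stature scales axial positions and segment lengths while radii stay
    anthropometric.  ``bent_arm`` raises the right forearm so that its
    elbow-to-hand segment arches above the floor; ``fetal`` folds the
    shanks back under the thighs.
    """
    if posture not in POSTURES:
        raise ValueError(f"posture must be one of {POSTURES}")
    r_torso, r_head, r_leg, r_arm = 0.13, 0.09, 0.06, 0.045
    # Head-to-toe span is 1.40*s + 0.15 m (the radii do not scale axially).
    s = (stature_m - 0.15) / 1.40

    def ax(x):  # axial scaling
        return x * s

    torso = Primitive("capsule", (ax(0.60), 0.0, r_torso),
                      (ax(1.10), 0.0, r_torso), r_torso)
    head = Primitive("sphere", (ax(1.28), 0.0, r_head), radius=r_head)
    legs = [Primitive("capsule", (ax(-0.12), y, r_leg), (ax(0.63), y, r_leg),
                      r_leg) for y in (-0.07, 0.07)]
    y_arm = 0.14
    arms = [Primitive("capsule", (ax(0.58), -y_arm, r_arm),
                      (ax(1.08), -y_arm, r_arm), r_arm)]
    if posture == "bent_arm":
        elbow = np.array([ax(0.80), y_arm, r_arm])
        hand = elbow + np.array([ax(0.28) * np.cos(np.deg2rad(55)), 0.0,
                                 ax(0.28) * np.sin(np.deg2rad(55))])
        arms += [Primitive("capsule", (ax(0.58), y_arm, r_arm),
                           tuple(elbow), r_arm),
                 Primitive("capsule", tuple(elbow), tuple(hand), r_arm)]
    else:
        arms += [Primitive("capsule", (ax(0.58), y_arm, r_arm),
                           (ax(1.08), y_arm, r_arm), r_arm)]
    if posture == "fetal":
        # Fold the lower legs back: thigh along +x, shank doubling back.
        legs = []
        for y in (-0.07, 0.07):
            knee = (ax(0.25), y, r_leg)
            legs += [Primitive("capsule", knee, (ax(0.63), y, r_leg), r_leg),
                     Primitive("capsule", knee,
                               (ax(0.60), y + np.sign(y) * 0.02, 3 * r_leg),
                               r_leg)]

    primitives = [torso, head] + legs + arms
    markers = {
        "forehead": (ax(1.28), 0.0, 2 * r_head),
        "chest": (ax(1.05), 0.0, 2 * r_torso),
        "abdomen": (ax(0.72), 0.0, 2 * r_torso),
        "thigh": (ax(0.45), 0.07, 2 * r_leg),
        "upper_arm": (ax(0.70), -y_arm, 2 * r_arm),
    }
    return PhantomSpec(primitives=primitives, markers=markers,
                       posture=posture, floor_height=0.0, seed=seed,
                       label=f"body-{posture}")


def arch_spec(radius: float = 0.05, span: float = 0.5,
              apex_height: float = 0.25) -> PhantomSpec:
    """Two capsules joined at an apex arching above the floor (bent limb)."""
    apex = (span / 2.0, 0.0, apex_height)
    prims = [Primitive("capsule", (0.0, 0.0, radius), apex, radius),
             Primitive("capsule", apex, (span, 0.0, radius), radius)]
    markers = {"upper_arm": (span / 2.0, 0.0, apex_height + radius)}
    return PhantomSpec(primitives=prims, markers=markers, posture="bent_arm",
                       floor_height=0.0, label="arch")


def make_phantom(spec: PhantomSpec):
    """Build the phantom mesh and its marker observations.

    Returns (TriangleMesh, list[MarkerObservation]).  The mesh is a
    concatenation of closed primitive surfaces (free-edge fraction 0); the
    voxelizer treats the union of their interiors as the body.
    """
    meshes = [_primitive_mesh(p) for p in spec.primitives]
    if not _primitives_connected(meshes):
        raise ValueError(f"phantom {spec.label!r}: primitives do not overlap "
                         "into one connected body")
    merged = trimesh.util.concatenate(meshes)
    mesh = TriangleMesh.from_trimesh(merged, label=spec.label)
    markers = [MarkerObservation(i + 1, tuple(pos), site)
               for i, (site, pos) in enumerate(sorted(spec.markers.items()))]
    return mesh, markers


def voxelize_phantom(spec: PhantomSpec, dx: float = 0.01, padding: int = 5,
                     adipose_shell_m: float = 0.02):
    """Mesh -> padded grid with substrate and adipose shell + probe indices."""
    mesh, markers = make_phantom(spec)
    grid = geometry.voxelize(mesh, dx=dx, padding=padding)
    grid = geometry.assign_substrate(grid, spec.floor_height)
    grid = geometry.assign_adipose_shell(grid, adipose_shell_m)
    probes = {m.site: register_marker(grid, m)
              for m in markers if m.site in BODY_SITES}
    return mesh, markers, grid, probes


@dataclass
class SyntheticCase:
    """A fully synthetic case: inputs plus ground truth for recovery tests."""

    spec: PhantomSpec
    mesh: TriangleMesh
    markers: list
    grid: VoxelGrid
    result: SimulationResult
    records: list                     # MeasurementRecord per sample
    truth: pd.DataFrame               # site, true_pmi_h, clean_temp_C, ...
    death_clock: pd.Timestamp


def synthesize_measurements(spec: PhantomSpec, materials=None,
                            config: SimulationConfig | None = None,
                            noise_sd_C: float = 0.2,
                            sample_times_h=None, seed: int | None = None,
                            dx: float = 0.01,
                            death_clock=DEFAULT_DEATH_CLOCK) -> SyntheticCase:
    """Forward-simulate the phantom and sample noisy logger measurements.

    Records are the simulated probe temperatures at ``sample_times_h``
    (hours since death) plus independent N(0, noise_sd) sensor noise, with
    the ambient column taken from the schedule and clock times stamped
    relative to ``death_clock``.  Ground truth PMIs are attached for
    parameter-recovery tests.
    """
    if materials is None:
        materials = default_materials()
    if config is None:
        config = SimulationConfig(duration_h=36.0)
    if sample_times_h is None:
        sample_times_h = np.linspace(2.0, 35.0, 20)
    sample_times_h = np.asarray(sample_times_h, dtype=float)
    if sample_times_h.max() > config.duration_h:
        raise ValueError("sample times exceed the simulated span")
    rng = np.random.default_rng(spec.seed if seed is None else seed)

    mesh, markers, grid, probes = voxelize_phantom(spec, dx=dx)
    config.probes = probes
    result = simulate(grid, materials, config)
    curves = result.curves_by_site()

    death_clock = pd.Timestamp(death_clock)
    records, rows = [], []
    for site in sorted(curves):
        curve = curves[site]
        clean = curve(sample_times_h)
        noise = rng.normal(0.0, noise_sd_C, size=len(sample_times_h))
        for t, temp_clean, eps in zip(sample_times_h, clean, noise):
            ambient = config.ambient.air(t)
            records.append(MeasurementRecord(
                site=site,
                clock_time=death_clock + pd.Timedelta(hours=float(t)),
                skin_temp_C=float(temp_clean + eps),
                ambient_temp_C=float(ambient)))
            rows.append({"site": site, "true_pmi_h": float(t),
                         "clean_temp_C": float(temp_clean),
                         "noisy_temp_C": float(temp_clean + eps),
                         "ambient_C": float(ambient)})
    truth = pd.DataFrame(rows)
    return SyntheticCase(spec, mesh, markers, grid, result, records, truth,
                         death_clock)


class OverlapError(ValueError):
    """Synthetic logger discs overlap in the raster."""


def synthesize_thermal_map(site_temps_C: dict, layout: dict,
                           logger_radius_px: float = 5.0,
                           background_C: float = 20.0,
                           noise_sd_C: float = 0.0, seed: int = 0,
                           shape=(120, 160), logger_offset_C: float = -5.0,
                           patch_radius_px: float | None = None):
    """Render a synthetic thermal raster with logger discs on skin patches.

    Each site gets a circular skin patch at its configured temperature with
    a cooler logger disc at its centre (loggers read below skin-surface
    temperature in the image because they obscure the skin); Gaussian
    pixel noise is added on top.  Returns (ThermalMap, {site: RingROI})
    with rings placed just outside the logger discs.
    """
    if patch_radius_px is None:
        patch_radius_px = logger_radius_px + 6.0
    rng = np.random.default_rng(seed)
    n_rows, n_cols = shape
    values = np.full(shape, float(background_C))
    rows_g, cols_g = np.mgrid[0:n_rows, 0:n_cols]

    centres = {site: np.asarray(c, dtype=float) for site, c in layout.items()}
    sites = sorted(site_temps_C)
    for i, a in enumerate(sites):
        for b in sites[i + 1:]:
            if np.linalg.norm(centres[a] - centres[b]) < 2 * patch_radius_px:
                raise OverlapError(f"logger patches {a!r} and {b!r} overlap")

    rois = {}
    for site in sites:
        cx, cy = centres[site]
        if (cx - patch_radius_px < -0.5 or cy - patch_radius_px < -0.5
                or cx + patch_radius_px > n_cols - 0.5
                or cy + patch_radius_px > n_rows - 0.5):
            raise ValueError(f"patch for {site!r} exceeds the raster")
        dist = np.hypot(cols_g - cx, rows_g - cy)
        values[dist < patch_radius_px] = site_temps_C[site]
        values[dist < logger_radius_px] = site_temps_C[site] + logger_offset_C
        rois[site] = RingROI(cx, cy, logger_radius_px + 1.0,
                             logger_radius_px + 4.0)
    if noise_sd_C > 0:
        values = values + rng.normal(0.0, noise_sd_C, size=shape)
    return ThermalMap(values), rois


def write_fixture_directory(path, spec: PhantomSpec | None = None,
                            noise_sd_C: float = 0.2, seed: int = 0,
                            duration_h: float = 36.0, ambient_C: float = 20.0,
                            sample_times_h=None, dx: float = 0.01) -> dict:
    """Write a complete synthetic case directory (mesh, CSVs, ground truth).

    Files: body.ply, markers.csv, measurements.csv, ambient.csv,
    thermal_map.csv, rois.csv, truth.json, case.yaml (ready for run-case).
    """
    import json
    from pathlib import Path

    import yaml

    from .pmi import save_measurements
    from .thermo import AmbientSchedule

    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    if spec is None:
        spec = body_spec("straight", seed=seed)
    config = SimulationConfig(duration_h=duration_h,
                              ambient=AmbientSchedule.constant(ambient_C))
    case = synthesize_measurements(spec, config=config, noise_sd_C=noise_sd_C,
                                   sample_times_h=sample_times_h, seed=seed,
                                   dx=dx)
    geometry.save_mesh(case.mesh, out / "body.ply")
    geometry.save_markers(case.markers, out / "markers.csv")
    save_measurements(case.records, out / "measurements.csv")
    pd.DataFrame({"time_h": [0.0, duration_h],
                  "temp_C": [ambient_C, ambient_C]}).to_csv(
        out / "ambient.csv", index=False)

    curves = case.result.curves_by_site()
    last_t = case.truth["true_pmi_h"].max()
    site_temps = {s: float(curves[s](last_t)) for s in curves}
    n_sites = len(site_temps)
    layout = {s: (20 + 30 * i, 60) for i, s in enumerate(sorted(site_temps))}
    tmap, rois = synthesize_thermal_map(site_temps, layout,
                                        noise_sd_C=noise_sd_C, seed=seed)
    np.savetxt(out / "thermal_map.csv", tmap.values_C, delimiter=",",
               fmt="%.4f")
    marker_ids = {m.site: m.marker_id for m in case.markers}
    pd.DataFrame([{"marker_id": marker_ids[s], "cx": r.cx, "cy": r.cy,
                   "r_inner": r.r_inner, "r_outer": r.r_outer}
                  for s, r in sorted(rois.items())]).to_csv(
        out / "rois.csv", index=False)

    truth = {
        "posture": spec.posture,
        "death_clock": case.death_clock.isoformat(),
        "noise_sd_C": noise_sd_C,
        "seed": seed,
        "samples": case.truth.to_dict(orient="records"),
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1))

    case_cfg = {
        "mesh": "body.ply", "markers": "markers.csv",
        "measurements": "measurements.csv", "ambient": "ambient.csv",
        "floor_height": spec.floor_height, "dx": dx,
        "adipose_shell_m": 0.02,
        "solver": {"dt_s": 60.0, "duration_h": duration_h,
                   "t_body0_C": 37.0},
        "output_dir": "results",
    }
    (out / "case.yaml").write_text(yaml.safe_dump(case_cfg, sort_keys=False))
    log.info("wrote fixture case (%d sites, %d records) to %s", n_sites,
             len(case.records), out)
    return {"spec": spec, "case": case, "path": out}
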