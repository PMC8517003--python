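"""Shared fixtures: small analytic solids and one forward-simulated case.

Expensive forward simulations are session-scoped; everything is generated
programmatically (no stored binary fixtures).
"""
from __future__ import annotations

import numpy as np
import pytest
import trimesh
from hypothesis import HealthCheck, settings

from thermopmi import phantoms
from thermopmi.geometry import TriangleMesh, voxelize
from thermopmi.phantoms import PhantomSpec, Primitive
from thermopmi.thermo import (AmbientSchedule, SimulationConfig,
                              default_materials, simulate)

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def sphere_mesh(radius=0.05, subdivisions=3) -> TriangleMesh:
    return TriangleMesh.from_trimesh(
        trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius),
        label=f"sphere-r{radius}")


def small_sphere_spec(seed: int = 0) -> PhantomSpec:
    """Single-sphere phantom resting on the floor, one forehead marker."""
    r = 0.06
    return PhantomSpec(
        primitives=[Primitive("sphere", (0.0, 0.0, r), radius=r)],
        markers={"forehead": (0.0, 0.0, 2 * r)},
        floor_height=0.0, seed=seed, label="small-sphere")


@pytest.fixture(scope="session")
def sphere_grid():
    """Voxelized free-floating r=0.05 m sphere at dx=1 cm."""
    return voxelize(sphere_mesh(), dx=0.01)


@pytest.fixture(scope="session")
def sphere_case():
    """Small sphere phantom on the floor, simulated 12 h, one probe."""
    spec = small_sphere_spec()
    _, _, grid, probes = phantoms.voxelize_phantom(spec)
    config = SimulationConfig(duration_h=12.0, probes=probes,
                              ambient=AmbientSchedule.constant(20.0))
    result = simulate(grid, default_materials(), config)
    return {"spec": spec, "grid": grid, "probes": probes, "result": result,
            "curve": result.curve("forehead")}


@pytest.fixture(scope="session")
def recovery_case():
    """Capsule-body phantom, 36 h forward run, 5 sites x 20 noisy samples.

    The study conditions of the parameter-recovery experiment: ambient
    20 deg C, 60 s steps, 0.2 deg C sensor noise, true PMIs spanning
    2-35 h.
    """
    return phantoms.synthesize_measurements(
        phantoms.body_spec("straight", seed=1), noise_sd_C=0.2, seed=1)
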