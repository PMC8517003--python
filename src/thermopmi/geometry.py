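"""Surface meshes, cubic-grid voxelization, and marker registration.

A scaled triangle surface mesh of a body (typically exported from a
photogrammetry pipeline, in metres) is translated into a volumetric
representation on a cubic grid: every cube whose centre lies inside the
closed surface becomes tissue, cubes below the floor plane become
substrate, and everything else is ambient air.  Labelled marker positions
(thermometry sites on the skin) are snapped to the nearest air-facing
tissue cube so that measured and simulated skin temperatures refer to the
same grid location.

All coordinates are SI metres.  Grid indices are 0-based, with the centre
of cube (i, j, k) at ``origin + (i + 1/2, j + 1/2, k + 1/2) * dx``.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import trimesh
from scipy import ndimage

from ._inside import component_occupancy

log = logging.getLogger(__name__)

#: Material labels used on the cubic grid.
MAT_AIR = "air"
MAT_TISSUE_CORE = "tissue_core"
MAT_TISSUE_ADIPOSE = "tissue_adipose"
MAT_SUBSTRATE = "substrate"
TISSUE_MATERIALS = (MAT_TISSUE_CORE, MAT_TISSUE_ADIPOSE)

#: The five skin-thermometry sites, plus auxiliary marker roles.
BODY_SITES = ("forehead", "chest", "abdomen", "thigh", "upper_arm")
AUX_SITES = ("ambient", "scale")
ALL_SITES = BODY_SITES + AUX_SITES

#: Meshes with a larger fraction of free (single-face) edges are refused.
DEFAULT_FREE_EDGE_THRESHOLD = 0.02
#: Markers farther than this many cube edges from the skin fail to register.
DEFAULT_SNAP_RADIUS_CUBES = 3.0
DEFAULT_PADDING_CUBES = 5
DEFAULT_DX = 0.01


class MeshError(ValueError):
    """Unusable surface mesh (parse failure, open surface, bad indices)."""


class RegistrationError(ValueError):
    """A marker could not be associated with a surface tissue cube."""


@dataclass
class TriangleMesh:
    """Closed triangle surface mesh in metres."""

    vertices: np.ndarray
    faces: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshError("faces must be an (m, 3) array")
        if len(self.faces) == 0:
            raise MeshError(f"mesh {self.label!r} has zero faces")
        if not np.isfinite(self.vertices).all():
            bad = np.argwhere(~np.isfinite(self.vertices))[0]
            raise MeshError(
                f"mesh {self.label!r}: non-finite coordinate at vertex "
                f"{bad[0]} component {bad[1]}")
        if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
            bad = int(np.argwhere(
                (self.faces < 0) | (self.faces >= len(self.vertices)))[0, 0])
            raise MeshError(
                f"mesh {self.label!r}: face {bad} references vertex "
                f"{int(self.faces[bad].max())} of {len(self.vertices)}")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def free_edge_fraction(self) -> float:
        """Fraction of unique edges that belong to exactly one face."""
        edges = np.sort(self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2),
                        axis=1)
        _, counts = np.unique(edges, axis=0, return_counts=True)
        return float((counts == 1).sum() / len(counts))

    def bounds(self) -> np.ndarray:
        return np.array([self.vertices.min(axis=0),
                         self.vertices.max(axis=0)])

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces,
                               process=False)

    @classmethod
    def from_trimesh(cls, mesh: trimesh.Trimesh, label: str = "") -> "TriangleMesh":
        return cls(np.asarray(mesh.vertices, dtype=float),
                   np.asarray(mesh.faces, dtype=np.int64), label)

    def translated(self, offset) -> "TriangleMesh":
        return TriangleMesh(self.vertices + np.asarray(offset, dtype=float),
                            self.faces.copy(), self.label)


@dataclass(frozen=True)
class MarkerObservation:
    """A labelled 3D marker (coded imaging target) position."""

    marker_id: int
    position: tuple
    site: str

    def __post_init__(self):
        if self.site not in ALL_SITES:
            raise ValueError(f"unknown marker site {self.site!r}; "
                             f"expected one of {ALL_SITES}")
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.isfinite(pos).all():
            raise ValueError(f"marker {self.marker_id}: position must be a "
                             "finite 3-vector")
        object.__setattr__(self, "position", tuple(pos))

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.position, dtype=float)


GridIndex = tuple  # (i, j, k) 0-based cube indices


@dataclass
class VoxelGrid:
    """Cubic discretisation with a material label per cube."""

    origin: np.ndarray
    dx: float
    material: np.ndarray  # (nx, ny, nz) array of label strings

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        if self.dx <= 0:
            raise ValueError("dx must be positive")
        if self.material.ndim != 3 or min(self.material.shape) < 1:
            raise ValueError("material must be a non-empty 3D array")

    @property
    def dims(self) -> tuple:
        return self.material.shape

    def centre(self, index) -> np.ndarray:
        return self.origin + (np.asarray(index, dtype=float) + 0.5) * self.dx

    def centres_z(self) -> np.ndarray:
        return self.origin[2] + (np.arange(self.dims[2]) + 0.5) * self.dx

    @property
    def tissue_mask(self) -> np.ndarray:
        return np.isin(self.material, TISSUE_MATERIALS)

    def count(self, label: str) -> int:
        return int((self.material == label).sum())

    def surface_tissue_mask(self, *, facing=("air",)) -> np.ndarray:
        """Tissue cubes sharing at least one face with a cube in `facing`."""
        tissue = self.tissue_mask
        exposed = np.zeros(self.dims, dtype=bool)
        neighbour = np.isin(self.material, facing)
        for axis in range(3):
            lo = [slice(None)] * 3
            hi = [slice(None)] * 3
            lo[axis] = slice(None, -1)
            hi[axis] = slice(1, None)
            lo, hi = tuple(lo), tuple(hi)
            exposed[lo] |= tissue[lo] & neighbour[hi]
            exposed[hi] |= tissue[hi] & neighbour[lo]
        return exposed

    def copy(self) -> "VoxelGrid":
        return VoxelGrid(self.origin.copy(), self.dx, self.material.copy())


def load_surface_mesh(path, fmt: str = "auto") -> TriangleMesh:
    """Load a PLY/OBJ/STL surface mesh (metres) into a :class:`TriangleMesh`."""
    kwargs = {} if fmt == "auto" else {"file_type": fmt}
    try:
        loaded = trimesh.load(str(path), force="mesh", process=False, **kwargs)
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise MeshError(f"could not parse mesh file {path}: {exc}") from exc
    if loaded is None or not hasattr(loaded, "faces"):
        raise MeshError(f"no mesh found in {path}")
    mesh = TriangleMesh(np.asarray(loaded.vertices, dtype=float),
                        np.asarray(loaded.faces, dtype=np.int64),
                        label=str(path))
    log.info("loaded %s: %d vertices, %d faces", path, mesh.n_vertices,
             mesh.n_faces)
    return mesh


def save_mesh(mesh: TriangleMesh, path) -> None:
    mesh.to_trimesh().export(str(path))


def voxelize(mesh: TriangleMesh, dx: float = DEFAULT_DX,
             padding: int = DEFAULT_PADDING_CUBES, *,
             free_edge_threshold: float = DEFAULT_FREE_EDGE_THRESHOLD) -> VoxelGrid:
    """Fill the closed surface with tissue cubes on a padded cubic grid.

    A cube is tissue iff its centre is inside the mesh (union of the mesh's
    closed connected components, so overlapping primitive unions are
    handled).  The grid covers the mesh bounding box expanded by `padding`
    cubes of air on every side.
    """
    if dx <= 0:
        raise ValueError("dx must be positive")
    fef = mesh.free_edge_fraction()
    if fef > free_edge_threshold:
        raise MeshError(
            f"mesh {mesh.label!r} is not closed: free-edge fraction "
            f"{fef:.3f} exceeds {free_edge_threshold}; repair the surface "
            "(fill holes / remove dangling faces) before voxelizing")
    lo, hi = mesh.bounds()
    extent = hi - lo
    if np.any(extent < dx):
        raise MeshError(f"dx={dx} exceeds mesh extent {extent}")
    n_core = np.maximum(np.ceil(extent / dx - 1e-9).astype(int), 1)
    dims = tuple(int(n) for n in n_core + 2 * padding)
    origin = lo - padding * dx

    occupancy = np.zeros(dims, dtype=bool)
    parts = mesh.to_trimesh().split(only_watertight=False)
    if len(parts) == 0:
        parts = [mesh.to_trimesh()]
    for part in parts:
        occupancy |= component_occupancy(
            np.asarray(part.vertices, dtype=float),
            np.asarray(part.faces, dtype=np.int64), origin, dx, dims)

    material = np.full(dims, MAT_AIR, dtype="U14")
    material[occupancy] = MAT_TISSUE_CORE
    grid = VoxelGrid(origin, dx, material)

    labels, n_comp = ndimage.label(occupancy)
    if n_comp > 1:
        log.warning("voxelized body splits into %d face-connected components",
                    n_comp)
    log.info("voxelized %s: dims=%s, %d tissue cubes", mesh.label, dims,
             int(occupancy.sum()))
    return grid


def assign_substrate(grid: VoxelGrid, floor_height: float,
                     substrate_material: str = MAT_SUBSTRATE) -> VoxelGrid:
    """Convert non-tissue cubes with centres below the floor plane to substrate."""
    out = grid.copy()
    z = out.centres_z()
    if floor_height <= z[0] - 0.5 * grid.dx:
        log.warning("floor height %.3f m lies below the grid; no substrate "
                    "assigned", floor_height)
        return out
    below = np.zeros(out.dims, dtype=bool)
    below[:, :, z < floor_height] = True
    if np.any(below & out.tissue_mask):
        raise ValueError(
            f"floor plane z={floor_height} intersects tissue cubes; the mesh "
            "and floor height are inconsistent")
    out.material[below & (out.material == MAT_AIR)] = substrate_material
    return out


def assign_adipose_shell(grid: VoxelGrid, shell_thickness: float) -> VoxelGrid:
    """Relabel tissue within `shell_thickness` of the skin as adipose.

    The body is modelled as two tissue types: a sub-surface adipose shell
    (cube-centre Euclidean distance to the nearest air/substrate-adjacent
    tissue cube strictly below the thickness) over a non-adipose core.
    """
    if shell_thickness < 0:
        raise ValueError("shell_thickness must be >= 0")
    out = grid.copy()
    tissue = out.tissue_mask
    out.material[tissue] = MAT_TISSUE_CORE
    if shell_thickness == 0 or not tissue.any():
        return out
    surface = out.surface_tissue_mask(facing=(MAT_AIR, MAT_SUBSTRATE))
    if not surface.any():
        return out
    dist = ndimage.distance_transform_edt(~surface) * grid.dx
    out.material[tissue & (dist < shell_thickness)] = MAT_TISSUE_ADIPOSE
    return out


def register_marker(grid: VoxelGrid, marker: MarkerObservation,
                    snap_radius: float | None = None) -> GridIndex:
    """Snap a body-site marker to the nearest air-facing tissue cube.

    Ties are broken towards the lowest (i, j, k) in lexicographic order.
    """
    if marker.site not in BODY_SITES:
        raise RegistrationError(
            f"marker {marker.marker_id} has site {marker.site!r}; only body "
            f"sites {BODY_SITES} can be registered on the grid")
    if snap_radius is None:
        snap_radius = DEFAULT_SNAP_RADIUS_CUBES * grid.dx
    surface = grid.surface_tissue_mask(facing=(MAT_AIR,))
    idx = np.argwhere(surface)
    if len(idx) == 0:
        raise RegistrationError("grid contains no air-facing tissue cubes")
    centres = grid.origin + (idx + 0.5) * grid.dx
    d2 = np.einsum("ij,ij->i", centres - marker.xyz, centres - marker.xyz)
    dmin = d2.min()
    if dmin > snap_radius ** 2:
        raise RegistrationError(
            f"marker {marker.marker_id} ({marker.site}) is "
            f"{np.sqrt(dmin):.3f} m from the nearest surface tissue cube, "
            f"beyond the snap radius {snap_radius:.3f} m")
    ties = idx[d2 <= dmin + 1e-18]
    order = np.lexsort((ties[:, 2], ties[:, 1], ties[:, 0]))
    return tuple(int(v) for v in ties[order[0]])


@dataclass
class ScaleValidation:
    """Manual vs virtual distance comparison for scaled 3D models."""

    table: pd.DataFrame  # columns: label, manual_m, virtual_m, difference_m
    mean_difference_m: float
    sd_difference_m: float


def validate_scale(manual, markers) -> ScaleValidation:
    """Compare manually measured distances against marker-pair distances.

    `manual` is a sequence of (label, distance_m) where each label names a
    marker pair as "idA-idB".  The virtual distance is the Euclidean
    distance between the two marker positions in the scaled model.
    """
    by_id = {m.marker_id: m for m in markers}
    rows, unresolved = [], []
    for label, dist in manual:
        try:
            a_id, b_id = (int(s) for s in str(label).split("-"))
            a, b = by_id[a_id], by_id[b_id]
        except (ValueError, KeyError):
            unresolved.append(str(label))
            continue
        virtual = float(np.linalg.norm(a.xyz - b.xyz))
        rows.append((str(label), float(dist), virtual, float(dist) - virtual))
    if unresolved:
        raise KeyError(f"unresolved marker-pair labels: {unresolved}")
    table = pd.DataFrame(rows, columns=["label", "manual_m", "virtual_m",
                                        "difference_m"])
    diffs = table["difference_m"].to_numpy()
    sd = float(np.std(diffs, ddof=1)) if len(diffs) > 1 else 0.0
    return ScaleValidation(table, float(diffs.mean()), sd)


def load_markers(path) -> list:
    """Read markers from CSV with columns marker_id, x, y, z, site."""
    df = pd.read_csv(path)
    return [MarkerObservation(int(r.marker_id), (r.x, r.y, r.z), str(r.site))
            for r in df.itertuples()]


def save_markers(markers, path) -> None:
    pd.DataFrame(
        [{"marker_id": m.marker_id, "x": m.position[0], "y": m.position[1],
          "z": m.position[2], "site": m.site} for m in markers]
    ).to_csv(path, index=False)
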