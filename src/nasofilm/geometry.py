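"""Labelled triangulated surfaces for deposition and wall-film modelling.

Two surrogate geometries are provided:

* a flat square plate emulating the mucosa coupon of the ex vivo
  retention assay, tilted by pointing the gravity vector rather than
  rotating the vertices; and
* an idealised unilateral infant nasal passage: a curved circular duct
  whose per-region lateral areas are calibrated to the measured airway
  dimensions of a 10-day-old nose.  The duct ascends through the
  vestibule and valve, runs posteriorly through the turbinate region,
  and bends down through the nasopharynx, pharynx and larynx, ending in
  an open outlet through which film runoff leaves the domain.

Coordinates are millimetres throughout.  Gravity is encoded as a unit
vector on the mesh; body orientation only rotates that vector.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path

import numpy as np

from . import datasets

__all__ = [
    "REGIONS",
    "Orientation",
    "SurfaceMesh",
    "build_plate_mesh",
    "build_nasal_surrogate",
    "holding_capacity",
    "save_mesh",
    "load_mesh",
]

G_M_S2 = 9.81

REGIONS = (
    "vestibule",
    "valve",
    "turbinate",
    "nasopharynx",
    "pharynx",
    "larynx",
    "plate",
)

#: Duct-axis elevation (degrees above the posterior horizontal) of the
#: three anatomical segments of the surrogate centreline.  The anterior
#: segment climbs, the turbinate runs level, and the distal segment
#: descends steeply while still drifting posteriorly so that the duct
#: drains toward the laryngeal outlet in both supine and back-tilt
#: postures.
_SEGMENT_ELEVATION_DEG = {"anterior": 35.0, "turbinate": 0.0, "distal": -70.0}


@dataclass(frozen=True)
class Orientation:
    """Body position; 0 = supine, 45 = 45-degree back tilt, 90 = upright."""

    back_tilt_angle: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.back_tilt_angle <= 90.0:
            raise ValueError("back_tilt_angle must lie in [0, 90] degrees")

    @property
    def gravity_vector(self) -> np.ndarray:
        """Unit gravity direction in the body frame.

        Body frame: +x posterior, +y lateral (left), +z superior.  In
        the supine position gravity points posteriorly (+x); tilting the
        back up by ``beta`` rotates gravity about the lateral axis
        toward the inferior direction (-z).
        """
        b = np.radians(self.back_tilt_angle)
        return np.array([np.cos(b), 0.0, -np.sin(b)])


class _FaceConnectivity:
    """Precomputed edge/adjacency arrays for finite-volume operators."""

    def __init__(self, mesh: "SurfaceMesh"):
        verts = mesh.vertices
        faces = mesh.faces
        m = len(faces)

        # half-edges: (v0, v1) per face corner, keyed by sorted pair
        edge_map: dict[tuple[int, int], list[tuple[int, int]]] = {}
        for f in range(m):
            tri = faces[f]
            for k in range(3):
                a, b = int(tri[k]), int(tri[(k + 1) % 3])
                edge_map.setdefault((min(a, b), max(a, b)), []).append((f, k))

        adj, bnd = [], []
        for key, owners in edge_map.items():
            if len(owners) == 2:
                adj.append((owners[0][0], owners[1][0], key[0], key[1]))
            else:
                bnd.append((owners[0][0], key[0], key[1]))

        self.adj = np.array([(i, j) for i, j, _, _ in adj], dtype=np.int64).reshape(-1, 2)
        adj_v = np.array([(a, b) for _, _, a, b in adj], dtype=np.int64).reshape(-1, 2)
        self.bnd_face = np.array([f for f, _, _ in bnd], dtype=np.int64)
        bnd_v = np.array([(a, b) for _, a, b in bnd], dtype=np.int64).reshape(-1, 2)
        self.bnd_edges = bnd_v

        normals = mesh.face_normal
        centroids = mesh.face_centroid

        def edge_geo(face_idx, ev):
            p0 = verts[ev[:, 0]]
            p1 = verts[ev[:, 1]]
            vec = p1 - p0
            length = np.linalg.norm(vec, axis=1)
            mid = 0.5 * (p0 + p1)
            # in-plane outward normal of the owning face
            n = normals[face_idx]
            t = np.cross(vec, n)
            t /= np.maximum(np.linalg.norm(t, axis=1), 1e-300)[:, None]
            # orient away from the face centroid
            flip = np.einsum("ij,ij->i", t, mid - centroids[face_idx]) < 0
            t[flip] *= -1.0
            return length, t, mid

        if len(self.adj):
            self.adj_len, self.adj_tang_i, self.adj_mid = edge_geo(self.adj[:, 0], adj_v)
            _, tang_j, _ = edge_geo(self.adj[:, 1], adj_v)
            self.adj_tang_j = tang_j
        else:  # pragma: no cover - degenerate meshes
            self.adj_len = np.zeros(0)
            self.adj_tang_i = np.zeros((0, 3))
            self.adj_tang_j = np.zeros((0, 3))
            self.adj_mid = np.zeros((0, 3))

        if len(self.bnd_face):
            self.bnd_len, self.bnd_tang, _ = edge_geo(self.bnd_face, bnd_v)
        else:
            self.bnd_len = np.zeros(0)
            self.bnd_tang = np.zeros((0, 3))

        outlet = {tuple(sorted(e)) for e in np.asarray(mesh.outlet_edges).reshape(-1, 2)}
        self.bnd_is_outlet = np.array(
            [tuple(sorted(e)) in outlet for e in bnd_v], dtype=bool
        )

        # CSR neighbour lists (used by the overflow router)
        nbr = [[] for _ in range(m)]
        for i, j in self.adj:
            nbr[i].append(j)
            nbr[j].append(i)
        counts = np.array([len(x) for x in nbr], dtype=np.int64)
        self.nbr_ptr = np.concatenate([[0], np.cumsum(counts)])
        self.nbr_idx = np.array(
            [j for lst in nbr for j in lst], dtype=np.int64
        )
        # faces owning at least one outlet boundary edge
        self.outlet_faces = np.unique(self.bnd_face[self.bnd_is_outlet]) if len(
            self.bnd_face
        ) else np.zeros(0, dtype=np.int64)


@dataclass
class SurfaceMesh:
    """Triangulated labelled surface carrying all deposition/film fields.

    Attributes
    ----------
    vertices : (n, 3) float array, mm
    faces : (m, 3) int array of vertex triplets
    face_region : (m,) array of region names (see :data:`REGIONS`)
    gravity_vector : (3,) unit vector set by body orientation
    outlet_edges : (k, 2) vertex-index pairs of boundary edges through
        which film mass exits the domain
    """

    vertices: np.ndarray
    faces: np.ndarray
    face_region: np.ndarray
    gravity_vector: np.ndarray
    outlet_edges: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        self.face_region = np.asarray(self.face_region)
        g = np.asarray(self.gravity_vector, dtype=float)
        self.gravity_vector = g / np.linalg.norm(g)
        self.outlet_edges = np.asarray(self.outlet_edges, dtype=np.int64).reshape(-1, 2)

    # -- derived quantities -------------------------------------------------

    @cached_property
    def _cross(self) -> np.ndarray:
        tri = self.vertices[self.faces]
        return np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])

    @cached_property
    def face_area(self) -> np.ndarray:
        """Triangle areas, mm^2."""
        return 0.5 * np.linalg.norm(self._cross, axis=1)

    @cached_property
    def face_normal(self) -> np.ndarray:
        """Unit normals on the gas side of the film."""
        return self._cross / (2.0 * self.face_area)[:, None]

    @cached_property
    def face_centroid(self) -> np.ndarray:
        return self.vertices[self.faces].mean(axis=1)

    @cached_property
    def connectivity(self) -> _FaceConnectivity:
        return _FaceConnectivity(self)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def region_areas(self) -> dict[str, float]:
        """Summed face area per region, mm^2."""
        out: dict[str, float] = {}
        for r in np.unique(self.face_region):
            out[str(r)] = float(self.face_area[self.face_region == r].sum())
        return out

    def with_orientation(self, orientation: Orientation) -> "SurfaceMesh":
        """Same geometry with the gravity vector reset from a body position."""
        return SurfaceMesh(
            vertices=self.vertices,
            faces=self.faces,
            face_region=self.face_region,
            gravity_vector=orientation.gravity_vector,
            outlet_edges=self.outlet_edges,
            metadata=dict(self.metadata, back_tilt_angle=orientation.back_tilt_angle),
        )


# ---------------------------------------------------------------------------
# Plate
# ---------------------------------------------------------------------------


def build_plate_mesh(
    side_length: float, resolution: int, tilt_angle: float
) -> SurfaceMesh:
    """Square mucosa-coupon plate of ``side_length`` mm.

    The plate lies in the z = 0 plane with its lower edge along y = 0;
    tilting is represented by the gravity vector, whose tangential
    component points toward that lower edge, which is marked as the
    outlet edge chain.  ``resolution`` is the number of cells per side.
    """
    if side_length <= 0:
        raise ValueError("side_length must be positive")
    if resolution < 2:
        raise ValueError("resolution must be at least 2")
    if not 0.0 <= tilt_angle <= 180.0:
        raise ValueError("tilt_angle must lie in [0, 180] degrees")

    n = int(resolution)
    xs = np.linspace(0.0, side_length, n + 1)
    xx, yy = np.meshgrid(xs, xs, indexing="ij")
    verts = np.column_stack([xx.ravel(), yy.ravel(), np.zeros((n + 1) ** 2)])

    def vid(i, j):
        return i * (n + 1) + j

    faces = []
    for i in range(n):
        for j in range(n):
            a, b, c, d = vid(i, j), vid(i + 1, j), vid(i + 1, j + 1), vid(i, j + 1)
            faces.append((a, b, c))  # CCW from +z
            faces.append((a, c, d))
    faces = np.array(faces, dtype=np.int64)

    outlet = np.array([(vid(i, 0), vid(i + 1, 0)) for i in range(n)], dtype=np.int64)

    th = np.radians(tilt_angle)
    gravity = np.array([0.0, -np.sin(th), -np.cos(th)])

    return SurfaceMesh(
        vertices=verts,
        faces=faces,
        face_region=np.array(["plate"] * len(faces)),
        gravity_vector=gravity,
        outlet_edges=outlet,
        metadata={"kind": "plate", "tilt_angle": float(tilt_angle)},
    )


# ---------------------------------------------------------------------------
# Nasal surrogate duct
# ---------------------------------------------------------------------------

_DUCT_ORDER = ("vestibule", "valve", "turbinate", "nasopharynx", "pharynx", "larynx")


def _smoothstep(x):
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _duct_profile(dims: dict, lengths: dict, blend_mm: float = 6.0):
    """Return callables psi(s) [axis angle, rad] and r(s) [radius, mm]."""
    regions = [r for r in _DUCT_ORDER if r in dims]
    radii = np.array(
        [10.0 * 2.0 * dims[r]["volume_cm3"] / dims[r]["area_cm2"] for r in regions]
    )  # mm, from effective diameter 4V/A
    L = np.array([lengths[r] for r in regions])
    s_end = np.cumsum(L)
    s_start = s_end - L

    elev = []
    for r in regions:
        if r in ("vestibule", "valve"):
            elev.append(_SEGMENT_ELEVATION_DEG["anterior"])
        elif r == "turbinate":
            elev.append(_SEGMENT_ELEVATION_DEG["turbinate"])
        else:
            elev.append(_SEGMENT_ELEVATION_DEG["distal"])
    elev = np.radians(np.array(elev))

    def piecewise(s, values):
        s = np.atleast_1d(np.asarray(s, dtype=float))
        out = np.empty_like(s)
        out[:] = values[0]
        for k in range(len(regions)):
            mask = (s >= s_start[k]) & (s <= s_end[k] + 1e-12)
            out[mask] = values[k]
        # blend across boundaries
        for k in range(len(regions) - 1):
            sb = s_end[k]
            w = min(blend_mm, 0.5 * L[k], 0.5 * L[k + 1])
            if w <= 0:
                continue
            mask = (s > sb - w) & (s < sb + w)
            t = _smoothstep((s[mask] - (sb - w)) / (2 * w))
            out[mask] = (1 - t) * values[k] + t * values[k + 1]
        return out

    total = float(s_end[-1])

    def psi(s):
        return piecewise(s, elev)

    def radius(s):
        return piecewise(s, radii)

    def region_at(s):
        idx = np.clip(np.searchsorted(s_end, s, side="right"), 0, len(regions) - 1)
        return np.array([regions[i] for i in np.atleast_1d(idx)])

    return psi, radius, region_at, total


def _mesh_duct(dims, lengths, edge_mm):
    psi, radius, region_at, total = _duct_profile(dims, lengths)

    # rings aligned with region boundaries so every ring interval has a
    # single region and region areas vary continuously with the lengths
    regions = [r for r in _DUCT_ORDER if r in dims]
    bounds = np.concatenate([[0.0], np.cumsum([lengths[r] for r in regions])])
    s_parts, interval_region = [0.0], []
    for k, r in enumerate(regions):
        nk = max(2, int(round((bounds[k + 1] - bounds[k]) / edge_mm)))
        seg = np.linspace(bounds[k], bounds[k + 1], nk + 1)[1:]
        s_parts.extend(seg.tolist())
        interval_region.extend([r] * nk)
    s = np.asarray(s_parts)
    n_rings = len(s)
    ds = np.diff(s)

    # centreline by integrating the axis direction (all in the xz-plane)
    ang = psi(s)
    d = np.column_stack([np.cos(ang), np.zeros_like(ang), np.sin(ang)])
    c = np.vstack(
        [[0.0, 0.0, 0.0], np.cumsum(0.5 * (d[1:] + d[:-1]) * ds[:, None], axis=0)]
    )

    r = radius(s)
    n_theta = max(10, int(np.ceil(2 * np.pi * r.max() / edge_mm)))
    theta = 2 * np.pi * np.arange(n_theta) / n_theta

    # frame: e2 = lateral y; e1 = in-plane normal of the axis
    e1 = np.column_stack([np.sin(ang), np.zeros_like(ang), -np.cos(ang)])
    e2 = np.array([0.0, 1.0, 0.0])

    verts = (
        c[:, None, :]
        + r[:, None, None] * np.cos(theta)[None, :, None] * e1[:, None, :]
        + r[:, None, None] * np.sin(theta)[None, :, None] * e2[None, None, :]
    ).reshape(-1, 3)

    def vid(k, i):
        return k * n_theta + (i % n_theta)

    faces, ring_of_face = [], []
    for k in range(n_rings - 1):
        for i in range(n_theta):
            a, b = vid(k, i), vid(k, i + 1)
            cc, dd = vid(k + 1, i + 1), vid(k + 1, i)
            # wind so normals point toward the duct axis (gas side)
            faces.append((a, cc, b))
            faces.append((a, dd, cc))
            ring_of_face.extend([k, k])
    faces = np.array(faces, dtype=np.int64)

    ring_region = np.array(interval_region)
    face_region = ring_region[np.array(ring_of_face)]

    outlet = np.array(
        [(vid(n_rings - 1, i), vid(n_rings - 1, i + 1)) for i in range(n_theta)],
        dtype=np.int64,
    )
    meta = {
        "kind": "nasal_surrogate",
        "inlet_center": c[0].tolist(),
        "inlet_axis": d[0].tolist(),
        "duct_length_mm": total,
    }
    return verts, faces, face_region, outlet, meta


def build_nasal_surrogate(
    dims: dict | None = None,
    orientation: Orientation = Orientation(0.0),
    resolution: float = 1.6,
) -> SurfaceMesh:
    """Idealised unilateral nasal passage calibrated to per-region areas.

    Parameters
    ----------
    dims : mapping region -> {"area_cm2", "volume_cm3"}; defaults to the
        measured 10-day-old airway with anterior regions halved for a
        single passage (:func:`nasofilm.datasets.unilateral_dims`).
    orientation : body position setting the gravity vector.
    resolution : target edge length in mm.

    Each region is a circular-duct segment whose radius comes from its
    effective diameter (4V/A) and whose length is iteratively calibrated
    so that the meshed lateral area matches the target area within 2%.
    """
    if dims is None:
        dims = datasets.unilateral_dims()
    for r, d in dims.items():
        if "area_cm2" not in d or "volume_cm3" not in d:
            raise ValueError(f"region '{r}' must provide area_cm2 and volume_cm3")
        if d["area_cm2"] <= 0 or d["volume_cm3"] <= 0:
            raise ValueError(f"region '{r}' dimensions must be positive")

    regions = [r for r in _DUCT_ORDER if r in dims]
    if not regions:
        raise ValueError("dims must contain at least one known region")

    # initial lengths from the cylinder relation A = 2*pi*r*L
    lengths = {}
    for r in regions:
        rad_mm = 10.0 * 2.0 * dims[r]["volume_cm3"] / dims[r]["area_cm2"]
        lengths[r] = 100.0 * dims[r]["area_cm2"] / (2 * np.pi * rad_mm)

    # fixed-point calibration of lengths against the meshed region areas
    out = None
    for _ in range(4):
        verts, faces, face_region, outlet, meta = _mesh_duct(dims, lengths, resolution)
        mesh = SurfaceMesh(
            vertices=verts,
            faces=faces,
            face_region=face_region,
            gravity_vector=orientation.gravity_vector,
            outlet_edges=outlet,
            metadata=meta,
        )
        areas = mesh.region_areas()
        worst = 0.0
        for r in regions:
            target = 100.0 * dims[r]["area_cm2"]
            got = areas.get(r, 0.0)
            if got <= 0:
                raise RuntimeError(f"region '{r}' vanished during meshing")
            lengths[r] *= target / got
            worst = max(worst, abs(got - target) / target)
        out = mesh
        if worst < 0.005:
            break
    out.metadata["back_tilt_angle"] = orientation.back_tilt_angle
    out.metadata["region_area_targets_cm2"] = {
        r: dims[r]["area_cm2"] for r in regions
    }
    return out


# ---------------------------------------------------------------------------
# Holding capacity
# ---------------------------------------------------------------------------


def holding_capacity(
    mesh: SurfaceMesh, h_max: float, regions=None
) -> float:
    """Liquid volume (mL) the selected regions hold at film height ``h_max`` mm.

    The capacity is the sum of face_area * h_max; an empty region
    selection returns zero.
    """
    if h_max < 0:
        raise ValueError("h_max must be non-negative")
    if regions is None:
        mask = np.ones(mesh.n_faces, dtype=bool)
    else:
        regions = set(regions)
        mask = np.isin(mesh.face_region, list(regions))
    return float(mesh.face_area[mask].sum() * h_max / 1000.0)  # mm^3 -> mL


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def save_mesh(mesh: SurfaceMesh, path: str | Path) -> None:
    """Write geometry as OBJ/STL with a JSON sidecar for labels and edges."""
    import trimesh

    path = Path(path)
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    tm.export(path)
    sidecar = {
        "face_region": {
            str(r): np.flatnonzero(mesh.face_region == r).tolist()
            for r in np.unique(mesh.face_region)
        },
        "outlet_edges": mesh.outlet_edges.tolist(),
        "gravity_vector": mesh.gravity_vector.tolist(),
        "metadata": mesh.metadata,
    }
    path.with_suffix(path.suffix + ".labels.json").write_text(json.dumps(sidecar))


def load_mesh(path: str | Path) -> SurfaceMesh:
    import trimesh

    path = Path(path)
    tm = trimesh.load(path, process=False)
    sidecar = json.loads(path.with_suffix(path.suffix + ".labels.json").read_text())
    region = np.empty(len(tm.faces), dtype=object)
    for r, idx in sidecar["face_region"].items():
        region[np.asarray(idx, dtype=int)] = r
    return SurfaceMesh(
        vertices=np.asarray(tm.vertices, dtype=float),
        faces=np.asarray(tm.faces, dtype=np.int64),
        face_region=region.astype(str),
        gravity_vector=np.asarray(sidecar["gravity_vector"], dtype=float),
        outlet_edges=np.asarray(sidecar["outlet_edges"], dtype=np.int64),
        metadata=sidecar.get("metadata", {}),
    )
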