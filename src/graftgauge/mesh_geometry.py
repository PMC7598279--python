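"""Triangle-surface geometry of vascular lumens.

The quantities computed here drive the reference-cylinder shape analysis:
for a lumen surface of axial height ``h`` and lateral (side) surface ``A``,
the *reference cylinder* is the right circular cylinder of the same height
whose lateral surface equals ``A``, i.e. with diameter ``d = A / (pi * h)``.
The shape factor of an object is the ratio of the reference cylinder's
volume to the object's enclosed volume; it equals 1 for a right cylinder
and grows as the lumen departs from a straight tube (bulging sac,
bifurcated limbs).

All lengths are millimetres; areas mm^2; volumes mm^3.
"""

from __future__ import annotations

import logging
import struct
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import numpy as np
import trimesh

__all__ = [
    "MeshFormatError",
    "MeshGeometryError",
    "TriSurfaceMesh",
    "ReferenceCylinder",
    "ShapeFactorDirection",
    "ShapeFactorReport",
    "read_stl",
    "write_stl",
    "axial_height",
    "side_surface_area",
    "strip_caps",
    "enclosed_volume",
    "build_reference_cylinder",
    "shape_factor_vs_cylinder",
    "shape_factor_pair",
]

logger = logging.getLogger(__name__)

#: vertices closer than this (mm) are merged at load time
VERTEX_MERGE_TOL = 1e-6
#: faces with area below this (mm^2) are dropped as degenerate
DEGENERATE_AREA_TOL = 1e-12


class MeshGeometryError(ValueError):
    """Raised when a mesh violates a precondition of a geometric operation."""


class MeshFormatError(MeshGeometryError):
    """Raised when an STL file cannot be parsed."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class TriSurfaceMesh:
    """Indexed triangle surface of a lumen (units mm).

    Parameters
    ----------
    vertices : (n, 3) float array
        Vertex coordinates in mm.
    faces : (m, 3) int array
        Vertex-index triplets; counter-clockwise winding seen from outside.
    axis : (3,) float array
        Unit vector of the axial (cranio-caudal) direction, default +z.
    """

    vertices: np.ndarray
    faces: np.ndarray
    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        self.axis = np.asarray(self.axis, dtype=np.float64).reshape(3)
        norm = np.linalg.norm(self.axis)
        if not norm > 0:
            raise MeshGeometryError("axis must be a non-zero vector")
        self.axis = self.axis / norm
        if not np.all(np.isfinite(self.vertices)):
            raise MeshGeometryError("vertex coordinates must be finite")
        if len(self.faces) and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise MeshGeometryError("face indices out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def is_empty(self) -> bool:
        return self.n_faces == 0

    def triangles(self) -> np.ndarray:
        """(m, 3, 3) array of triangle vertex coordinates."""
        return self.vertices[self.faces]

    def scaled(self, factor: float) -> "TriSurfaceMesh":
        if factor <= 0:
            raise MeshGeometryError("scale factor must be positive")
        return replace(self, vertices=self.vertices * factor)

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.faces, process=False
        )


@dataclass(frozen=True)
class ReferenceCylinder:
    """Equivalent right cylinder: same axial height, same side surface.

    Invariants: ``side_surface == pi * diameter * height`` and
    ``volume == pi * diameter**2 / 4 * height``.
    """

    height: float
    diameter: float
    side_surface: float
    volume: float

    def __post_init__(self) -> None:
        for name in ("height", "diameter", "side_surface", "volume"):
            if not getattr(self, name) > 0:
                raise MeshGeometryError(f"reference cylinder {name} must be > 0")

    @classmethod
    def from_height_and_side_surface(
        cls, height: float, side_surface: float
    ) -> "ReferenceCylinder":
        if not height > 0:
            raise MeshGeometryError("reference cylinder height must be > 0")
        if not side_surface > 0:
            raise MeshGeometryError("reference cylinder side surface must be > 0")
        diameter = side_surface / (np.pi * height)
        volume = np.pi * diameter**2 / 4.0 * height
        return cls(
            height=height,
            diameter=diameter,
            side_surface=side_surface,
            volume=volume,
        )


class ShapeFactorDirection(str, Enum):
    ANEURYSM_OVER_GRAFT = "aneurysm_over_graft"
    GRAFT_OVER_ANEURYSM = "graft_over_aneurysm"


@dataclass(frozen=True)
class ShapeFactorReport:
    """Shape factors of an aneurysm/stent-graft pair.

    ``phi_ref_aaa`` and ``phi_ref_graft`` compare each object against its own
    reference cylinder (both built with the aneurysm height, so the pair
    shares a common height). ``phi_AS`` is the ratio of the two reference
    side surfaces, orientation given by ``direction``.
    """

    phi_ref_aaa: float
    phi_ref_graft: float
    phi_AS: float
    direction: ShapeFactorDirection
    height: float
    aaa_cylinder: ReferenceCylinder
    graft_cylinder: ReferenceCylinder


# ---------------------------------------------------------------------------
# STL input / output
# ---------------------------------------------------------------------------

def _clean(vertices: np.ndarray, faces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge near-duplicate vertices and drop degenerate faces."""
    vertices = np.asarray(vertices, dtype=np.float64).reshape(-1, 3)
    faces = np.asarray(faces, dtype=np.int64).reshape(-1, 3)
    if len(vertices) == 0:
        return vertices, faces
    # quantize onto a VERTEX_MERGE_TOL grid; identical cells merge
    keys = np.round(vertices / VERTEX_MERGE_TOL).astype(np.int64)
    _, first, inverse = np.unique(
        keys, axis=0, return_index=True, return_inverse=True
    )
    vertices = vertices[first]
    faces = inverse[faces]
    # drop faces with repeated indices or vanishing area
    distinct = (
        (faces[:, 0] != faces[:, 1])
        & (faces[:, 1] != faces[:, 2])
        & (faces[:, 0] != faces[:, 2])
    )
    faces = faces[distinct]
    if len(faces):
        tri = vertices[faces]
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        area2 = np.linalg.norm(cross, axis=1)
        faces = faces[area2 > 2.0 * DEGENERATE_AREA_TOL]
    # drop unreferenced vertices
    used = np.unique(faces)
    remap = -np.ones(len(vertices), dtype=np.int64)
    remap[used] = np.arange(len(used))
    return vertices[used], remap[faces]


def read_stl(path: str | Path, axis=(0.0, 0.0, 1.0)) -> TriSurfaceMesh:
    """Read a binary or ASCII STL file into a cleaned :class:`TriSurfaceMesh`.

    Duplicate vertices within 1e-6 mm are merged; zero-area faces dropped.
    """
    path = Path(path)
    if not path.exists():
        raise MeshFormatError(f"no such STL file: {path}")
    try:
        raw = trimesh.load_mesh(str(path), file_type="stl", process=False)
    except Exception as exc:  # trimesh raises assorted types on corrupt input
        raise MeshFormatError(f"cannot parse STL file {path}: {exc}") from exc
    if raw.faces.shape[0] == 0:
        raise MeshFormatError(f"STL file {path} contains no triangles")
    vertices, faces = _clean(raw.vertices, raw.faces)
    if len(faces) == 0:
        raise MeshFormatError(f"STL file {path}: all triangles degenerate")
    return TriSurfaceMesh(vertices=vertices, faces=faces, axis=np.asarray(axis))


def write_stl(mesh: TriSurfaceMesh, path: str | Path) -> None:
    """Write a binary STL file (80-byte header, 50 bytes per triangle).

    The output is byte-deterministic for identical input meshes.
    """
    if mesh.is_empty():
        raise MeshGeometryError("cannot write an empty mesh")
    tri = mesh.triangles().astype(np.float32)
    normals = np.cross(
        tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]
    ).astype(np.float64)
    lengths = np.linalg.norm(normals, axis=1)
    lengths[lengths == 0] = 1.0
    normals = (normals / lengths[:, None]).astype(np.float32)
    record = np.zeros(
        len(tri),
        dtype=np.dtype(
            [("normal", "<f4", (3,)), ("v", "<f4", (3, 3)), ("attr", "<u2")]
        ),
    )
    record["normal"] = normals
    record["v"] = tri
    header = b"graftgauge binary STL".ljust(80, b"\0")
    path = Path(path)
    try:
        with open(path, "wb") as fh:
            fh.write(header)
            fh.write(struct.pack("<I", len(tri)))
            fh.write(record.tobytes())
    except OSError as exc:
        raise IOError(f"cannot write STL file {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# scalar geometry
# ---------------------------------------------------------------------------

def _require_non_empty(mesh: TriSurfaceMesh) -> None:
    if mesh.is_empty():
        raise MeshGeometryError("operation requires a non-empty mesh")


def axial_height(mesh: TriSurfaceMesh) -> float:
    """Axial extent of the mesh: max minus min vertex projection onto ``axis``.

    Sign-invariant in the axis direction.
    """
    _require_non_empty(mesh)
    proj = mesh.vertices @ mesh.axis
    return float(proj.max() - proj.min())


def side_surface_area(mesh: TriSurfaceMesh) -> float:
    """Total triangle area (mm^2). The mesh is assumed open-ended (no caps)."""
    _require_non_empty(mesh)
    tri = mesh.triangles()
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    return float(0.5 * np.linalg.norm(cross, axis=1).sum())


def strip_caps(mesh: TriSurfaceMesh, tol_deg: float = 15.0) -> TriSurfaceMesh:
    """Remove planar end caps so a capped tube conforms to the open-ended
    side-surface convention.

    A face is a cap face when its normal lies within ``tol_deg`` of the
    (signed) axis *and* its centroid sits within 1% of the axial extremes.
    """
    if not 0 < tol_deg <= 45:
        raise MeshGeometryError("tol_deg must be in (0, 45]")
    _require_non_empty(mesh)
    tri = mesh.triangles()
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    norms = np.linalg.norm(cross, axis=1)
    norms[norms == 0] = 1.0
    cos_axis = np.abs((cross / norms[:, None]) @ mesh.axis)
    axial = cos_axis >= np.cos(np.deg2rad(tol_deg))
    proj = mesh.vertices @ mesh.axis
    lo, hi = proj.min(), proj.max()
    margin = 0.01 * (hi - lo)
    centroid_proj = tri.mean(axis=1) @ mesh.axis
    at_ends = (centroid_proj <= lo + margin) | (centroid_proj >= hi - margin)
    keep = ~(axial & at_ends)
    if not keep.any():
        raise MeshGeometryError("mesh is all caps")
    vertices, faces = _clean(mesh.vertices, mesh.faces[keep])
    return TriSurfaceMesh(vertices=vertices, faces=faces, axis=mesh.axis)


def _boundary_loops(faces: np.ndarray) -> list[np.ndarray]:
    """Vertex loops of boundary (single-incidence) edges, following winding."""
    edges = np.concatenate(
        [faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]], axis=0
    )
    und = np.sort(edges, axis=1)
    _, inverse, counts = np.unique(
        und, axis=0, return_inverse=True, return_counts=True
    )
    boundary = edges[counts[inverse] == 1]
    succ: dict[int, int] = {}
    for a, b in boundary:
        if int(a) in succ:
            raise MeshGeometryError(
                "non-manifold boundary: cannot chain boundary edges into loops"
            )
        succ[int(a)] = int(b)
    loops = []
    remaining = dict(succ)
    while remaining:
        start, nxt = next(iter(remaining.items()))
        loop = [start]
        del remaining[start]
        while nxt != start:
            loop.append(nxt)
            try:
                nxt2 = remaining.pop(nxt)
            except KeyError as exc:
                raise MeshGeometryError(
                    "open boundary chain: surface cannot be capped"
                ) from exc
            nxt = nxt2
        loops.append(np.asarray(loop, dtype=np.int64))
    return loops


def _capped(mesh: TriSurfaceMesh) -> tuple[np.ndarray, np.ndarray]:
    """Vertices/faces with each boundary loop closed by a centroid fan.

    Cap triangles are wound opposite to the boundary loop, which preserves a
    globally consistent orientation of each closed component.
    """
    loops = _boundary_loops(mesh.faces)
    if not loops:
        return mesh.vertices, mesh.faces
    vertices = [mesh.vertices]
    new_faces = [mesh.faces]
    next_index = len(mesh.vertices)
    for loop in loops:
        centroid = mesh.vertices[loop].mean(axis=0)
        vertices.append(centroid[None, :])
        a = loop
        b = np.roll(loop, -1)
        fan = np.column_stack([b, a, np.full(len(loop), next_index)])
        new_faces.append(fan)
        next_index += 1
    return np.concatenate(vertices, axis=0), np.concatenate(new_faces, axis=0)


def _signed_volume(vertices: np.ndarray, faces: np.ndarray) -> float:
    tri = vertices[faces]
    return float(np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum() / 6.0)


def enclosed_volume(mesh: TriSurfaceMesh) -> float:
    """Volume (mm^3) enclosed by the surface after virtually capping open ends.

    Open boundary loops (tube ends) are closed with planar centroid fans and
    the signed-tetrahedron (divergence theorem) sum is taken; the result is
    orientation-normalised per closed component.
    """
    _require_non_empty(mesh)
    try:
        vertices, faces = _capped(mesh)
        closed = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
        if closed.is_winding_consistent:
            if closed.body_count > 1:
                # abs per component so a flipped component cannot cancel
                return float(
                    sum(abs(part.volume) for part in closed.split(only_watertight=False))
                )
            return abs(_signed_volume(vertices, faces))
        trimesh.repair.fix_normals(closed)
        return float(sum(abs(p.volume) for p in closed.split(only_watertight=False)))
    except MeshGeometryError:
        # fall back to trimesh repair for surfaces our fan-capping rejects
        tm = mesh.as_trimesh()
        trimesh.repair.fill_holes(tm)
        trimesh.repair.fix_normals(tm)
        if not tm.is_winding_consistent:
            raise MeshGeometryError(
                "non-manifold surface: cannot cap and compute enclosed volume"
            )
        return abs(float(tm.volume))


def build_reference_cylinder(
    mesh: TriSurfaceMesh, height_override: float | None = None
) -> ReferenceCylinder:
    """Reference cylinder of a lumen: same height, same side surface.

    ``height_override`` forces a common height on an aneurysm/stent-graft
    pair (both objects are compared at the aneurysm height).
    """
    _require_non_empty(mesh)
    height = height_override if height_override is not None else axial_height(mesh)
    if not height > 0:
        raise MeshGeometryError("reference cylinder height must be > 0")
    return ReferenceCylinder.from_height_and_side_surface(
        height, side_surface_area(mesh)
    )


def shape_factor_vs_cylinder(
    mesh: TriSurfaceMesh, height_override: float | None = None
) -> float:
    """Dimensionless shape factor of a lumen against its reference cylinder.

    Defined as ``V_reference_cylinder / V_object``: 1 for a right cylinder,
    above 1 when the lumen encloses less volume than a cylinder with its side
    surface (bulged sacs, bifurcated limbs). This volume-based convention is
    one design choice among possible area/diameter variants; it is the one
    consistent with factors above unity for aneurysmal geometry.
    """
    ref = build_reference_cylinder(mesh, height_override)
    volume = enclosed_volume(mesh)
    if not volume > 0:
        raise MeshGeometryError("mesh encloses zero volume")
    return ref.volume / volume


def shape_factor_pair(
    aaa: TriSurfaceMesh,
    graft: TriSurfaceMesh,
    direction: ShapeFactorDirection | str = ShapeFactorDirection.ANEURYSM_OVER_GRAFT,
) -> ShapeFactorReport:
    """Shape factors of an aneurysm/stent-graft pair at a common height.

    Both reference cylinders use the aneurysm's axial height, enforcing the
    equal-height convention of the pairwise comparison. ``phi_AS`` is the
    ratio of reference side surfaces in the requested ``direction``.
    """
    direction = ShapeFactorDirection(direction)
    _require_non_empty(aaa)
    _require_non_empty(graft)
    h_aaa = axial_height(aaa)
    h_graft = axial_height(graft)
    if h_graft > h_aaa * 1.01:
        logger.warning(
            "stent-graft height %.3f mm exceeds aneurysm height %.3f mm; "
            "using the aneurysm height",
            h_graft,
            h_aaa,
        )
    ref_aaa = build_reference_cylinder(aaa, height_override=h_aaa)
    ref_graft = build_reference_cylinder(graft, height_override=h_aaa)
    ratio = ref_aaa.side_surface / ref_graft.side_surface
    if direction is ShapeFactorDirection.GRAFT_OVER_ANEURYSM:
        ratio = 1.0 / ratio
    return ShapeFactorReport(
        phi_ref_aaa=shape_factor_vs_cylinder(aaa, height_override=h_aaa),
        phi_ref_graft=shape_factor_vs_cylinder(graft, height_override=h_aaa),
        phi_AS=ratio,
        direction=direction,
        height=h_aaa,
        aaa_cylinder=ref_aaa,
        graft_cylinder=ref_graft,
    )
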