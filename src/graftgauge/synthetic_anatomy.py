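"""Parametric generator of AAA and stent-graft lumen surfaces.

Stands in for a patient AngioCT cohort: fusiform abdominal aortic aneurysm
lumens (surface of revolution with a smooth sac bulge) and bifurcated
stent-graft lumens in two spatial configurations, long body and short body,
which differ only in the fraction of the height occupied by the single
trunk before the bifurcation. All three surfaces of a patient share the
same axial height by construction, the convention the pairwise
reference-cylinder comparison requires.

Geometries are open-ended tubes aligned with +z (cranio-caudal), units mm.
Generation is deterministic: a cohort is reproducible from its seed, with
one random stream per patient so records do not depend on ordering.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace

import numpy as np

from .mesh_geometry import MeshGeometryError, TriSurfaceMesh

__all__ = [
    "AnatomyParams",
    "CohortSpec",
    "PatientGeometry",
    "make_cylinder_mesh",
    "make_aaa_mesh",
    "make_stentgraft_mesh",
    "make_cohort",
    "DEFAULT_ANATOMY",
]


@dataclass(frozen=True)
class AnatomyParams:
    """Dimensions of one synthetic patient (mm, degrees, counts).

    Defaults reflect surgical-scale anatomy: aortic neck diameter 20 mm, sac
    diameter 55 mm (the repair-threshold size), total height 130 mm, iliac
    limb diameter 12 mm.
    """

    neck_radius: float = 10.0
    sac_radius: float = 27.5
    height: float = 130.0
    sac_center_frac: float = 0.5
    sac_length_frac: float = 0.5
    graft_body_frac_long: float = 0.6
    graft_body_frac_short: float = 0.25
    limb_radius: float = 6.0
    bifurcation_angle: float = 30.0
    circumferential_segments: int = 96
    axial_segments: int = 128

    def validate(self) -> None:
        errors = []
        if not self.sac_radius > self.neck_radius > self.limb_radius > 0:
            errors.append(
                "requires sac_radius > neck_radius > limb_radius > 0 "
                f"(got {self.sac_radius}, {self.neck_radius}, {self.limb_radius})"
            )
        if not 0 < self.graft_body_frac_short < self.graft_body_frac_long < 1:
            errors.append(
                "requires 0 < graft_body_frac_short < graft_body_frac_long < 1 "
                f"(got {self.graft_body_frac_short}, {self.graft_body_frac_long})"
            )
        if not self.height > 0:
            errors.append(f"height must be > 0 (got {self.height})")
        if not 0 < self.sac_center_frac < 1:
            errors.append(f"sac_center_frac must be in (0,1) (got {self.sac_center_frac})")
        if not 0 < self.sac_length_frac <= 1:
            errors.append(f"sac_length_frac must be in (0,1] (got {self.sac_length_frac})")
        if self.circumferential_segments < 16 or self.axial_segments < 16:
            errors.append("segment counts must be >= 16")
        if not 0 <= self.bifurcation_angle < 90:
            errors.append(
                f"bifurcation_angle must be in [0, 90) degrees (got {self.bifurcation_angle})"
            )
        if errors:
            raise MeshGeometryError("invalid anatomy parameters: " + "; ".join(errors))


DEFAULT_ANATOMY = AnatomyParams()


@dataclass(frozen=True)
class CohortSpec:
    """Size, seed and per-patient parameter spread of a synthetic cohort."""

    n_patients: int = 20
    seed: int = 1
    param_jitter: float = 0.1

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not 0 <= self.param_jitter < 0.5:
            raise ValueError("param_jitter must be in [0, 0.5)")


@dataclass
class PatientGeometry:
    """One synthetic patient: AAA lumen plus both stent-graft configurations."""

    patient_id: int
    params: AnatomyParams
    aaa: TriSurfaceMesh
    graft_long: TriSurfaceMesh
    graft_short: TriSurfaceMesh

    def meshes(self) -> dict[str, TriSurfaceMesh]:
        return {"AAA": self.aaa, "SL": self.graft_long, "SS": self.graft_short}


# ---------------------------------------------------------------------------
# primitive surfaces
# ---------------------------------------------------------------------------

def _tube_from_profile(
    z: np.ndarray,
    radius: np.ndarray,
    center_x: np.ndarray,
    segments: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Open tube: circular horizontal rings of given radius/center vs z.

    Winding is counter-clockwise seen from outside (normals point away from
    the local ring centre).
    """
    theta = np.linspace(0.0, 2.0 * np.pi, segments, endpoint=False)
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    nz, ns = len(z), segments
    x = center_x[:, None] + radius[:, None] * cos_t[None, :]
    y = radius[:, None] * sin_t[None, :]
    zz = np.broadcast_to(z[:, None], (nz, ns))
    vertices = np.stack([x, y, zz], axis=-1).reshape(-1, 3)

    ring = np.arange(ns)
    ring_next = np.roll(ring, -1)
    faces = []
    for j in range(nz - 1):
        a = j * ns + ring
        b = j * ns + ring_next
        c = (j + 1) * ns + ring
        d = (j + 1) * ns + ring_next
        faces.append(np.column_stack([a, b, d]))
        faces.append(np.column_stack([a, d, c]))
    return vertices, np.concatenate(faces, axis=0)


def make_cylinder_mesh(
    radius: float, height: float, segments: tuple[int, int] = (96, 64)
) -> TriSurfaceMesh:
    """Open-ended right cylinder aligned with +z, base at z=0.

    ``segments`` is (circumferential, axial); lateral area converges to
    2*pi*r*h as the circumferential count grows.
    """
    circ, axial = segments
    if circ < 3 or axial < 1:
        raise MeshGeometryError("cylinder needs >= 3 circumferential and >= 1 axial segments")
    if not (radius > 0 and height > 0):
        raise MeshGeometryError("cylinder radius and height must be > 0")
    z = np.linspace(0.0, height, axial + 1)
    vertices, faces = _tube_from_profile(
        z, np.full(len(z), float(radius)), np.zeros(len(z)), circ
    )
    return TriSurfaceMesh(vertices=vertices, faces=faces)


def _bump(z_frac: np.ndarray, center: float, width: float) -> np.ndarray:
    """C^1 cosine-tapered window on [center - width/2, center + width/2]."""
    s = (z_frac - center) / width
    out = np.zeros_like(z_frac)
    inside = np.abs(s) < 0.5
    out[inside] = 0.5 * (1.0 + np.cos(2.0 * np.pi * s[inside]))
    return out


def make_aaa_mesh(params: AnatomyParams) -> TriSurfaceMesh:
    """Fusiform AAA lumen: surface of revolution with a smooth sac bulge.

    The radius profile is ``neck_radius + (sac_radius - neck_radius) * bump``
    with a cosine-tapered window centred at ``sac_center_frac`` of the
    height, of width ``sac_length_frac``. Open ends; the maximal diameter
    equals 2*sac_radius at the window centre.
    """
    params.validate()
    z = np.linspace(0.0, params.height, params.axial_segments + 1)
    z_frac = z / params.height
    radius = params.neck_radius + (
        params.sac_radius - params.neck_radius
    ) * _bump(z_frac, params.sac_center_frac, params.sac_length_frac)
    vertices, faces = _tube_from_profile(
        z, radius, np.zeros(len(z)), params.circumferential_segments
    )
    return TriSurfaceMesh(vertices=vertices, faces=faces)


def make_stentgraft_mesh(params: AnatomyParams, body: str = "long") -> TriSurfaceMesh:
    """Bifurcated stent-graft lumen, configuration ``"long"`` or ``"short"``.

    A single trunk of radius ``neck_radius`` spans ``body_frac * height``
    from the inlet (z=0); two limbs of radius ``limb_radius`` then diverge
    symmetrically at ``bifurcation_angle`` (total opening angle) down to the
    full height, so both configurations share the AAA's axial extent
    exactly. Limbs are sheared tubes: ring cross-sections stay horizontal
    circles while ring centres follow the tilted limb axis, which keeps the
    total height exact and horizontal cross-section areas circular.
    """
    if body not in ("long", "short"):
        raise MeshGeometryError(f"body must be 'long' or 'short', got {body!r}")
    params.validate()
    body_frac = (
        params.graft_body_frac_long if body == "long" else params.graft_body_frac_short
    )
    h = params.height
    z_bif = body_frac * h
    circ = params.circumferential_segments
    n_axial_trunk = max(16, int(round(params.axial_segments * body_frac)))
    n_axial_limb = max(16, params.axial_segments - n_axial_trunk)

    # trunk
    z_trunk = np.linspace(0.0, z_bif, n_axial_trunk + 1)
    v_trunk, f_trunk = _tube_from_profile(
        z_trunk, np.full(len(z_trunk), params.neck_radius), np.zeros(len(z_trunk)), circ
    )

    # limbs: start tangent to each other on the trunk axis, diverge at
    # half the opening angle each
    slope = np.tan(np.deg2rad(params.bifurcation_angle / 2.0))
    z_limb = np.linspace(z_bif, h, n_axial_limb + 1)
    limb_span = z_limb - z_bif
    half_sep = params.limb_radius + slope * limb_span  # centre offset from axis
    if 2.0 * half_sep.min() < 2.0 * params.limb_radius * (1.0 - 1e-9):
        raise MeshGeometryError(
            "limbs intersect at the chosen geometry; use a smaller bifurcation_angle"
        )
    parts = [(v_trunk, f_trunk)]
    radius_limb = np.full(len(z_limb), params.limb_radius)
    for sign in (+1.0, -1.0):
        v, f = _tube_from_profile(z_limb, radius_limb, sign * half_sep, circ)
        parts.append((v, f))

    offset = 0
    vertices, faces = [], []
    for v, f in parts:
        vertices.append(v)
        faces.append(f + offset)
        offset += len(v)
    return TriSurfaceMesh(
        vertices=np.concatenate(vertices, axis=0),
        faces=np.concatenate(faces, axis=0),
    )


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

_JITTERED_LENGTHS = ("neck_radius", "sac_radius", "height", "limb_radius")
_JITTERED_FRACS = (
    "sac_center_frac",
    "sac_length_frac",
    "graft_body_frac_long",
    "graft_body_frac_short",
)


def _jitter_params(
    base: AnatomyParams, rng: np.random.Generator, sigma: float
) -> AnatomyParams:
    """Multiplicative log-normal jitter; fractions clipped to stay valid."""
    if sigma == 0:
        return base
    values = {}
    for name in _JITTERED_LENGTHS:
        values[name] = getattr(base, name) * float(np.exp(rng.normal(0.0, sigma)))
    for name in _JITTERED_FRACS:
        jittered = getattr(base, name) * float(np.exp(rng.normal(0.0, sigma / 2.0)))
        values[name] = float(np.clip(jittered, 0.05, 0.95))
    # keep the radius ordering invariant under independent jitter
    values["sac_radius"] = max(values["sac_radius"], 1.5 * values["neck_radius"])
    values["limb_radius"] = min(values["limb_radius"], 0.8 * values["neck_radius"])
    if values["graft_body_frac_short"] >= values["graft_body_frac_long"]:
        values["graft_body_frac_short"] = 0.5 * values["graft_body_frac_long"]
    out = replace(base, **values)
    out.validate()
    return out


def make_cohort(
    spec: CohortSpec, base: AnatomyParams = DEFAULT_ANATOMY
) -> list[PatientGeometry]:
    """Generate ``n_patients`` (AAA, long graft, short graft) triples.

    Per-patient parameters are drawn from a stream seeded by
    ``(spec.seed, patient_id)``, so a patient's geometry is independent of
    cohort size and ordering. Heights within a triple are identical by
    construction.
    """
    spec.validate()
    base.validate()
    patients = []
    for pid in range(1, spec.n_patients + 1):
        rng = np.random.default_rng([spec.seed, pid])
        params = _jitter_params(base, rng, spec.param_jitter)
        patients.append(
            PatientGeometry(
                patient_id=pid,
                params=params,
                aaa=make_aaa_mesh(params),
                graft_long=make_stentgraft_mesh(params, "long"),
                graft_short=make_stentgraft_mesh(params, "short"),
            )
        )
    return patients


def params_as_dict(params: AnatomyParams) -> dict:
    """Flat dict of anatomy parameters (for manifests and configs)."""
    return asdict(params)
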