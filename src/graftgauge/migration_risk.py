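"""Migration-risk decision layer.

Combines the reference-cylinder geometry factors with the cycle-aggregated
wall shear stress into per-patient quantities:

* the WSS factor phi_WSS = WSS_aneurysm / WSS_stent-graft,
* the drag (pushing) force on each stent-graft configuration,
* a verdict: for the same patient, the configuration (long vs short body)
  with the strictly lower cycle-mean drag force across the requested
  hemodynamic conditions presents the lower migration risk; relative
  differences under 1% are reported as indeterminate rather than decided
  by numerical noise.

A cohort of such records feeds the regression of the geometry ratio
(graft volume / aneurysm volume) on the WSS ratio (graft WSS / aneurysm
WSS), fitted per graft type and per hemodynamic condition.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from . import hemodynamics as hd
from . import mesh_geometry as mg
from . import stats_report as sr
from .mesh_geometry import TriSurfaceMesh
from .synthetic_anatomy import PatientGeometry

__all__ = [
    "RiskError",
    "Verdict",
    "ObjectMetrics",
    "GraftHemodynamics",
    "CohortRecord",
    "RiskReport",
    "wss_factor",
    "evaluate_patient",
    "evaluate_cohort",
    "shape_wss_regression",
    "build_risk_report",
    "INDIFFERENCE_BAND",
]

#: relative drag-force difference below which no configuration is preferred
INDIFFERENCE_BAND = 0.01

GRAFT_KEYS = ("SL", "SS")


class RiskError(ValueError):
    pass


class Verdict(str, Enum):
    LONG_LOWER_RISK = "long_lower_risk"
    SHORT_LOWER_RISK = "short_lower_risk"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class ObjectMetrics:
    """Geometry of one object (AAA, SL or SS) and its reference cylinder."""

    height: float  # mm
    side_surface: float  # mm^2
    volume: float  # mm^3
    ref_diameter: float  # mm
    phi_ref: float  # dimensionless, vs reference cylinder


@dataclass(frozen=True)
class GraftHemodynamics:
    """Cycle-aggregated hemodynamics of one graft under one waveform."""

    wss_total: float  # Pa
    phi_wss: float  # WSS_aneurysm / WSS_graft
    wss_ratio: float  # WSS_graft / WSS_aneurysm (regression abscissa)
    drag_force: float  # N


@dataclass
class CohortRecord:
    """Per-patient bundle of geometry factors, WSS aggregates and verdict."""

    patient_id: int
    objects: dict[str, ObjectMetrics]  # keys AAA, SL, SS
    phi_AS: dict[str, float]  # Eq-style A_aneurysm / A_graft, per graft
    volume_ratio: dict[str, float]  # V_graft / V_AAA, per graft
    wss_aaa: dict[str, float]  # per waveform kind, Pa
    hemodynamics: dict[tuple[str, str], GraftHemodynamics]  # (graft, kind)
    verdict: Verdict
    waveform_kinds: tuple[str, ...] = ()

    def mean_drag(self, graft: str) -> float:
        forces = [
            self.hemodynamics[(graft, kind)].drag_force
            for kind in self.waveform_kinds
        ]
        return float(np.mean(forces))


def wss_factor(wss_aneurysm: float, wss_graft: float) -> float:
    """WSS factor phi_WSS = WSS_aneurysm / WSS_stent-graft (dimensionless)."""
    if not wss_aneurysm > 0:
        raise RiskError("wss_aneurysm must be > 0")
    if not wss_graft > 0:
        raise RiskError("wss_graft must be > 0 (zero denominator)")
    return wss_aneurysm / wss_graft


def _verdict_from_drags(drag_long: float, drag_short: float) -> Verdict:
    scale = max(abs(drag_long), abs(drag_short))
    if scale == 0 or abs(drag_long - drag_short) / scale < INDIFFERENCE_BAND:
        return Verdict.INDETERMINATE
    return (
        Verdict.LONG_LOWER_RISK if drag_long < drag_short else Verdict.SHORT_LOWER_RISK
    )


def evaluate_patient(
    aaa: TriSurfaceMesh,
    graft_long: TriSurfaceMesh,
    graft_short: TriSurfaceMesh,
    waveforms: list[hd.VelocityWaveform],
    rheo: hd.RheologyParams | None = None,
    patient_id: int = 0,
    n_stations: int = 40,
) -> CohortRecord:
    """Full per-patient evaluation across the given hemodynamic conditions.

    All three meshes must share the axial height within 1% (the common
    reference-cylinder height convention). The verdict compares the mean
    drag force of the two configurations across all waveforms.
    """
    if not waveforms:
        raise RiskError("at least one waveform is required")
    meshes = {"AAA": aaa, "SL": graft_long, "SS": graft_short}
    heights = {k: mg.axial_height(m) for k, m in meshes.items()}
    h_ref = heights["AAA"]
    for key, h in heights.items():
        if abs(h - h_ref) > 0.01 * h_ref:
            raise RiskError(
                f"patient {patient_id}: {key} height {h:.3f} mm deviates more "
                f"than 1% from the AAA height {h_ref:.3f} mm"
            )

    objects: dict[str, ObjectMetrics] = {}
    for key, mesh in meshes.items():
        try:
            ref = mg.build_reference_cylinder(mesh, height_override=h_ref)
            volume = mg.enclosed_volume(mesh)
            objects[key] = ObjectMetrics(
                height=heights[key],
                side_surface=ref.side_surface,
                volume=volume,
                ref_diameter=ref.diameter,
                phi_ref=ref.volume / volume,
            )
        except mg.MeshGeometryError as exc:
            raise RiskError(f"patient {patient_id}, object {key}: {exc}") from exc

    phi_AS = {
        g: objects["AAA"].side_surface / objects[g].side_surface for g in GRAFT_KEYS
    }
    volume_ratio = {
        g: objects[g].volume / objects["AAA"].volume for g in GRAFT_KEYS
    }

    tubes = {}
    for key, mesh in meshes.items():
        try:
            tubes[key] = hd.tube_from_mesh(mesh, n_stations=n_stations)
        except hd.HemodynamicsError as exc:
            raise RiskError(f"patient {patient_id}, object {key}: {exc}") from exc

    wss_aaa: dict[str, float] = {}
    records: dict[tuple[str, str], GraftHemodynamics] = {}
    kinds = tuple(w.kind for w in waveforms)
    if len(set(kinds)) != len(kinds):
        raise RiskError("waveform kinds must be distinct")
    for waveform in waveforms:
        try:
            totals = {
                key: hd.wss_total(hd.wss_series(tubes[key], waveform, rheo))
                for key in meshes
            }
        except hd.HemodynamicsError as exc:
            raise RiskError(
                f"patient {patient_id}, waveform {waveform.kind}: {exc}"
            ) from exc
        wss_aaa[waveform.kind] = totals["AAA"]
        for g in GRAFT_KEYS:
            series_total = totals[g]
            records[(g, waveform.kind)] = GraftHemodynamics(
                wss_total=series_total,
                phi_wss=wss_factor(totals["AAA"], series_total),
                wss_ratio=series_total / totals["AAA"],
                drag_force=series_total * objects[g].side_surface * hd.MM2_TO_M2,
            )

    drag_long = float(np.mean([records[("SL", k)].drag_force for k in kinds]))
    drag_short = float(np.mean([records[("SS", k)].drag_force for k in kinds]))
    return CohortRecord(
        patient_id=patient_id,
        objects=objects,
        phi_AS=phi_AS,
        volume_ratio=volume_ratio,
        wss_aaa=wss_aaa,
        hemodynamics=records,
        verdict=_verdict_from_drags(drag_long, drag_short),
        waveform_kinds=kinds,
    )


def evaluate_cohort(
    patients: list[PatientGeometry],
    waveforms: list[hd.VelocityWaveform],
    rheo: hd.RheologyParams | None = None,
    n_stations: int = 40,
) -> list[CohortRecord]:
    """Evaluate every patient of a synthetic cohort."""
    return [
        evaluate_patient(
            p.aaa,
            p.graft_long,
            p.graft_short,
            waveforms,
            rheo=rheo,
            patient_id=p.patient_id,
            n_stations=n_stations,
        )
        for p in patients
    ]


def shape_wss_regression(
    records: list[CohortRecord], graft_type: str, waveform_kind: str
) -> sr.LinearFitResult:
    """OLS of the geometry ratio on the WSS ratio for one graft/condition.

    y = volume ratio (graft/AAA), x = cycle WSS ratio (graft/AAA); returns
    slope and intercept with their standard errors. Requires >= 3 records.
    """
    if graft_type not in GRAFT_KEYS:
        raise RiskError(f"graft_type must be one of {GRAFT_KEYS}")
    if len(records) < 3:
        raise RiskError("regression requires at least 3 cohort records")
    try:
        x = np.array(
            [r.hemodynamics[(graft_type, waveform_kind)].wss_ratio for r in records]
        )
    except KeyError as exc:
        raise RiskError(
            f"waveform kind {waveform_kind!r} missing from cohort records"
        ) from exc
    y = np.array([r.volume_ratio[graft_type] for r in records])
    return sr.linear_fit(sr.PairedSample(x=x, y=y, labels=("wss_ratio", "volume_ratio")))


@dataclass
class RiskReport:
    """Cohort-level report: records, mean ± SEM summaries, regression rows."""

    records: list[CohortRecord]
    summaries: dict[str, tuple[float, float]]  # quantity -> (mean, SEM)
    regressions: list[dict]  # one row per graft type x waveform kind
    verdict_counts: dict[str, int]

    @property
    def n_patients(self) -> int:
        return len(self.records)


def build_risk_report(records: list[CohortRecord]) -> RiskReport:
    """Aggregate per-patient records into cohort summaries and regressions.

    Summaries are mean ± SEM over patients for every shape factor, WSS
    aggregate, WSS factor and drag force; regression rows cover every
    graft type x hemodynamic condition combination.
    """
    if not records:
        raise RiskError("cannot build a report from an empty cohort")
    kinds = records[0].waveform_kinds
    summaries: dict[str, tuple[float, float]] = {}

    def add(name: str, values) -> None:
        values = np.asarray(list(values), dtype=float)
        if values.size >= 2:
            summaries[name] = sr.mean_sem(values)
        else:
            summaries[name] = (float(values[0]), 0.0)

    for obj in ("AAA", "SL", "SS"):
        add(f"phi_ref_{obj}", (r.objects[obj].phi_ref for r in records))
        add(f"volume_mm3_{obj}", (r.objects[obj].volume for r in records))
        add(f"side_surface_mm2_{obj}", (r.objects[obj].side_surface for r in records))
    for g in GRAFT_KEYS:
        add(f"phi_AS_{g}", (r.phi_AS[g] for r in records))
        add(f"volume_ratio_{g}", (r.volume_ratio[g] for r in records))
    for kind in kinds:
        add(f"wss_Pa_AAA_{kind}", (r.wss_aaa[kind] for r in records))
        for g in GRAFT_KEYS:
            add(
                f"wss_Pa_{g}_{kind}",
                (r.hemodynamics[(g, kind)].wss_total for r in records),
            )
            add(
                f"phi_wss_{g}_{kind}",
                (r.hemodynamics[(g, kind)].phi_wss for r in records),
            )
            add(
                f"wss_ratio_{g}_{kind}",
                (r.hemodynamics[(g, kind)].wss_ratio for r in records),
            )
            add(
                f"drag_N_{g}_{kind}",
                (r.hemodynamics[(g, kind)].drag_force for r in records),
            )

    regressions = []
    if len(records) >= 3:
        for g in GRAFT_KEYS:
            for kind in kinds:
                fit = shape_wss_regression(records, g, kind)
                regressions.append(
                    {
                        "graft": g,
                        "waveform": kind,
                        "slope": fit.slope,
                        "slope_se": fit.slope_se,
                        "intercept": fit.intercept,
                        "intercept_se": fit.intercept_se,
                        "p_slope": fit.p_slope,
                        "r_value": fit.r_value,
                        "n": fit.n,
                    }
                )

    counts = {v.value: 0 for v in Verdict}
    for r in records:
        counts[r.verdict.value] += 1
    return RiskReport(
        records=records,
        summaries=summaries,
        regressions=regressions,
        verdict_counts=counts,
    )
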