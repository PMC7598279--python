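"""End-to-end orchestration: cohort -> geometry -> hemodynamics -> report.

``run_pipeline`` takes a :class:`~graftgauge.config.RunConfig`, generates
(or loads) the cohort, evaluates every patient under every requested
hemodynamic condition, and writes the full report set:

* ``manifest.csv``   — per-patient anatomy parameters (and STL paths when
  geometry was written to disk),
* ``geometry.csv``   — per patient x object: height, side surface, volume,
  reference-cylinder diameter, shape factors,
* ``risk.csv``       — per patient x graft x waveform: WSS aggregates, WSS
  factor, drag force, verdict,
* ``regressions.csv``— geometry-ratio vs WSS-ratio OLS rows (one per graft
  type per condition),
* ``summary.json``   — cohort mean ± SEM summaries and verdict counts.

All outputs are deterministic (byte-identical) for a fixed seed.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import hemodynamics as hd
from . import mesh_geometry as mg
from . import migration_risk as mr
from .config import RunConfig
from .synthetic_anatomy import (
    AnatomyParams,
    PatientGeometry,
    make_cohort,
    params_as_dict,
)

__all__ = [
    "run_pipeline",
    "write_cohort_stl",
    "load_cohort_from_manifest",
    "report_frames",
]

logger = logging.getLogger("graftgauge.pipeline")

_OBJECT_FILES = {"AAA": "aaa", "SL": "graft_long", "SS": "graft_short"}


def _configure_logging(verbosity: str) -> None:
    level = {"quiet": logging.WARNING, "info": logging.INFO, "debug": logging.DEBUG}[
        verbosity
    ]
    logging.getLogger("graftgauge").setLevel(level)
    if not logging.getLogger().handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(
            logging.Formatter("%(levelname)s %(name)s: %(message)s")
        )
        logging.getLogger().addHandler(handler)


def write_cohort_stl(
    patients: list[PatientGeometry], directory: str | Path
) -> pd.DataFrame:
    """Write one STL per object (``P{id}_{AAA|SL|SS}.stl``) plus a manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for p in patients:
        row: dict = {"patient_id": p.patient_id, **params_as_dict(p.params)}
        for key, mesh in p.meshes().items():
            name = f"P{p.patient_id:03d}_{key}.stl"
            mg.write_stl(mesh, directory / name)
            row[f"stl_{key}"] = name
        rows.append(row)
    manifest = pd.DataFrame(rows)
    manifest.to_csv(directory / "manifest.csv", index=False)
    return manifest


def load_cohort_from_manifest(manifest_path: str | Path) -> list[PatientGeometry]:
    """Rebuild a cohort by reading the STL files referenced in a manifest."""
    manifest_path = Path(manifest_path)
    directory = manifest_path.parent
    table = pd.read_csv(manifest_path)
    param_fields = set(AnatomyParams.__dataclass_fields__)
    patients = []
    for _, row in table.iterrows():
        params = AnatomyParams(
            **{
                k: (int(row[k]) if k.endswith("segments") else float(row[k]))
                for k in param_fields
                if k in row
            }
        )
        meshes = {
            key: mg.read_stl(directory / row[f"stl_{key}"])
            for key in _OBJECT_FILES
        }
        patients.append(
            PatientGeometry(
                patient_id=int(row["patient_id"]),
                params=params,
                aaa=meshes["AAA"],
                graft_long=meshes["SL"],
                graft_short=meshes["SS"],
            )
        )
    return patients


def report_frames(
    report: mr.RiskReport,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """(geometry, risk, regressions) DataFrames of a RiskReport."""
    geometry_rows = []
    risk_rows = []
    for rec in report.records:
        for obj, m in rec.objects.items():
            geometry_rows.append(
                {
                    "patient_id": rec.patient_id,
                    "object": obj,
                    "height_mm": m.height,
                    "side_surface_mm2": m.side_surface,
                    "volume_mm3": m.volume,
                    "ref_diameter_mm": m.ref_diameter,
                    "phi_ref": m.phi_ref,
                    "phi_AS": rec.phi_AS.get(obj, np.nan),
                    "volume_ratio": rec.volume_ratio.get(obj, np.nan),
                }
            )
        for (graft, kind), h in rec.hemodynamics.items():
            risk_rows.append(
                {
                    "patient_id": rec.patient_id,
                    "graft": graft,
                    "waveform": kind,
                    "wss_Pa_aaa": rec.wss_aaa[kind],
                    "wss_Pa_graft": h.wss_total,
                    "phi_wss": h.phi_wss,
                    "wss_ratio": h.wss_ratio,
                    "drag_N": h.drag_force,
                    "verdict": rec.verdict.value,
                }
            )
    geometry = pd.DataFrame(geometry_rows).sort_values(
        ["patient_id", "object"], ignore_index=True
    )
    risk = pd.DataFrame(risk_rows).sort_values(
        ["patient_id", "graft", "waveform"], ignore_index=True
    )
    regressions = pd.DataFrame(report.regressions)
    return geometry, risk, regressions


def run_pipeline(config: RunConfig) -> mr.RiskReport:
    """Run the whole workflow described by ``config`` and write the report."""
    config.validate()
    _configure_logging(config.verbosity)
    t0 = time.perf_counter()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.cohort is not None:
        logger.info(
            "stage=generate n_patients=%d seed=%d jitter=%.3f",
            config.cohort.n_patients,
            config.cohort.seed,
            config.cohort.param_jitter,
        )
        patients = make_cohort(config.cohort, config.anatomy)
        manifest = pd.DataFrame(
            [
                {"patient_id": p.patient_id, "seed": config.cohort.seed,
                 **params_as_dict(p.params)}
                for p in patients
            ]
        )
        manifest.to_csv(outdir / "manifest.csv", index=False)
    else:
        logger.info("stage=load manifest=%s", config.manifest)
        patients = load_cohort_from_manifest(config.manifest)

    waveforms = [
        hd.make_waveform(
            kind,
            peak_velocity=config.peak_velocity,
            period=config.period,
            n_samples=config.n_time_steps,
        )
        for kind in config.waveform_kinds
    ]

    records = []
    for p in patients:
        t_p = time.perf_counter()
        record = mr.evaluate_patient(
            p.aaa,
            p.graft_long,
            p.graft_short,
            waveforms,
            rheo=config.rheology,
            patient_id=p.patient_id,
            n_stations=config.n_stations,
        )
        records.append(record)
        logger.info(
            "stage=evaluate patient_id=%d verdict=%s elapsed=%.2fs",
            p.patient_id,
            record.verdict.value,
            time.perf_counter() - t_p,
        )
    report = mr.build_risk_report(records)

    geometry, risk, regressions = report_frames(report)
    geometry.to_csv(outdir / "geometry.csv", index=False)
    risk.to_csv(outdir / "risk.csv", index=False)
    regressions.to_csv(outdir / "regressions.csv", index=False)
    summary = {
        "n_patients": report.n_patients,
        "waveform_kinds": list(config.waveform_kinds),
        "summaries": {
            k: {"mean": v[0], "sem": v[1]} for k, v in sorted(report.summaries.items())
        },
        "verdict_counts": report.verdict_counts,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    logger.info(
        "stage=report outdir=%s elapsed=%.2fs", outdir, time.perf_counter() - t0
    )
    return report
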