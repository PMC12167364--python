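"""Cohort directory I/O.

A cohort directory holds, per patient, the three registered phase volumes
and the liver/tumor masks as NIfTI, plus cohort-level CSV tables:

    images/{patient}/{A|V|D}.nii.gz
    masks/{patient}/{liver|tumor}.nii.gz
    clinical.csv
    outcomes.csv            (patient_id, os_time, os_event, pfs_time, pfs_event)
    ground_truth.json       (optional; written by the synthetic generator)

CSV dialect: UTF-8, comma-separated, header required, missing values as
empty cells.  Loading validates vocabularies and cross-table id alignment
and reports every problem (with its row) rather than the first.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .datatypes import ClinicalRecord, SurvivalLabel, TriphasicScan, PHASES
from .synthetic import GroundTruth

__all__ = ["write_cohort", "read_cohort", "CohortLoadError"]


class CohortLoadError(ValueError):
    """Itemized validation failures while loading a cohort directory."""

    def __init__(self, problems: list):
        self.problems = list(problems)
        super().__init__("cohort load failed:\n  " + "\n  ".join(self.problems))


def _save_nii(path: Path, data: np.ndarray, affine: np.ndarray) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    # store as (x, y, z) per NIfTI convention; in-memory axis order is (z, y, x)
    nib.save(nib.Nifti1Image(np.ascontiguousarray(data.T), affine), str(path))


def _load_nii(path: Path) -> tuple:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj).T  # back to (z, y, x)
    zooms = img.header.get_zooms()[:3]
    return data, tuple(float(z) for z in zooms[::-1]), img.affine


def write_cohort(directory, scans: Sequence[TriphasicScan],
                 clinical: Sequence[ClinicalRecord],
                 os_labels: Sequence[SurvivalLabel],
                 pfs_labels: Sequence[SurvivalLabel],
                 truth: GroundTruth | None = None) -> Path:
    """Write a cohort directory in the standard layout; returns its path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for scan in scans:
        for ph in PHASES:
            _save_nii(directory / "images" / scan.patient_id / f"{ph}.nii.gz",
                      scan.phases[ph].astype(np.float32), scan.affine)
        _save_nii(directory / "masks" / scan.patient_id / "liver.nii.gz",
                  scan.liver_mask.astype(np.uint8), scan.affine)
        _save_nii(directory / "masks" / scan.patient_id / "tumor.nii.gz",
                  scan.tumor_mask.astype(np.uint8), scan.affine)

    pd.DataFrame([rec.to_dict() for rec in clinical]).to_csv(
        directory / "clinical.csv", index=False)
    pd.DataFrame({
        "patient_id": [r.patient_id for r in clinical],
        "os_time": [l.time for l in os_labels],
        "os_event": [l.event for l in os_labels],
        "pfs_time": [l.time for l in pfs_labels],
        "pfs_event": [l.event for l in pfs_labels],
    }).to_csv(directory / "outcomes.csv", index=False)

    if truth is not None:
        payload = {
            "coefficients": truth.coefficients,
            "lp": truth.lp.tolist(),
            "true_os": truth.true_os.tolist(),
            "true_pfs": truth.true_pfs.tolist(),
            "censor_times": [c if np.isfinite(c) else None
                             for c in truth.censor_times],
            "covariates": truth.covariates.to_dict(orient="list"),
        }
        (directory / "ground_truth.json").write_text(json.dumps(payload, indent=1))
    return directory


def read_cohort(directory) -> tuple:
    """Load (scans, clinical, os_labels, pfs_labels) from a cohort directory.

    Raises :class:`CohortLoadError` listing every malformed row, unknown
    vocabulary value, missing phase file, or id present in only one table.
    """
    directory = Path(directory)
    problems: list = []
    clinical_path = directory / "clinical.csv"
    outcomes_path = directory / "outcomes.csv"
    for p in (clinical_path, outcomes_path):
        if not p.exists():
            raise CohortLoadError([f"missing table {p.name}"])
    cdf = pd.read_csv(clinical_path)
    odf = pd.read_csv(outcomes_path)

    cids, oids = list(cdf["patient_id"]), list(odf["patient_id"])
    for pid in sorted(set(cids) - set(oids)):
        problems.append(f"id {pid} present in clinical.csv only")
    for pid in sorted(set(oids) - set(cids)):
        problems.append(f"id {pid} present in outcomes.csv only")

    records = {}
    for row_num, row in cdf.iterrows():
        try:
            rec = ClinicalRecord(**row.to_dict())
            rec.validate()
            records[rec.patient_id] = rec
        except (TypeError, ValueError) as err:
            problems.append(f"clinical.csv row {row_num}: {err}")

    outcomes = {}
    for row_num, row in odf.iterrows():
        try:
            if row["os_time"] <= 0 or row["pfs_time"] <= 0:
                raise ValueError(
                    f"non-positive survival time "
                    f"(os={row['os_time']}, pfs={row['pfs_time']})"
                )
            outcomes[row["patient_id"]] = (
                SurvivalLabel(float(row["os_time"]), int(row["os_event"]), "OS"),
                SurvivalLabel(float(row["pfs_time"]), int(row["pfs_event"]), "PFS"),
            )
        except (TypeError, ValueError, KeyError) as err:
            problems.append(f"outcomes.csv row {row_num}: {err}")

    ids = [pid for pid in cids if pid in records and pid in outcomes]
    scans = []
    for pid in ids:
        try:
            phases, spacings = {}, set()
            for ph in PHASES:
                path = directory / "images" / pid / f"{ph}.nii.gz"
                if not path.exists():
                    raise FileNotFoundError(f"missing phase file {path.name}")
                vol, spacing, affine = _load_nii(path)
                phases[ph] = vol.astype(np.float32)
                spacings.add(spacing)
            liver, _, _ = _load_nii(directory / "masks" / pid / "liver.nii.gz")
            tumor, _, _ = _load_nii(directory / "masks" / pid / "tumor.nii.gz")
            scan = TriphasicScan(
                patient_id=pid, phases=phases, spacing=next(iter(spacings)),
                liver_mask=liver.astype(np.uint8), tumor_mask=tumor.astype(np.uint8),
                affine=affine,
            )
            scan.validate()
            scans.append(scan)
        except (FileNotFoundError, ValueError) as err:
            problems.append(f"patient {pid}: {err}")

    if problems:
        raise CohortLoadError(problems)
    clinical = [records[pid] for pid in ids]
    os_labels = [outcomes[pid][0] for pid in ids]
    pfs_labels = [outcomes[pid][1] for pid in ids]
    return scans, clinical, os_labels, pfs_labels
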