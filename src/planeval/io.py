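"""Reading and writing the plain-text DVH exchange format.

One CSV per patient, UTF-8, header row required, with columns::

    structure, bin_lo_gy, bin_hi_gy, volume_fraction, absolute_volume_cm3

Each row is one differential-DVH bin; ``absolute_volume_cm3`` repeats per
structure. A cohort directory holds one such CSV per patient plus a
``manifest.json`` recording the arm, the prescription, the patient ids and —
for generated cohorts — the generator settings.

A minimal adapter to DICOM RT-structure / RT-dose pairs is provided behind
the optional ``dicom`` extra; nothing else in the package depends on it.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .dvh import DoseVolumeHistogram, PlanContext, to_differential
from .exceptions import ValidationError
from .metrics import PatientRecord
from .synthetic import SyntheticCohortSpec, spec_to_manifest

__all__ = [
    "write_patient_csv",
    "read_patient_csv",
    "write_cohort",
    "read_cohort",
    "dicom_to_patient",
]

logger = logging.getLogger(__name__)

CSV_COLUMNS = ["structure", "bin_lo_gy", "bin_hi_gy", "volume_fraction", "absolute_volume_cm3"]


def write_patient_csv(patient: PatientRecord, path: str | Path) -> None:
    """Write every structure's differential DVH to one exchange CSV."""
    frames = []
    for role in sorted(patient.structures):
        dvh = patient.structures[role]
        if dvh.form == "cumulative":
            dvh = to_differential(dvh)
        frames.append(
            pd.DataFrame(
                {
                    "structure": role,
                    "bin_lo_gy": dvh.bin_edges[:-1],
                    "bin_hi_gy": dvh.bin_edges[1:],
                    "volume_fraction": dvh.volume_fraction,
                    "absolute_volume_cm3": dvh.absolute_volume,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


def read_patient_csv(
    path: str | Path, patient_id: str, arm: str, plan: PlanContext
) -> PatientRecord:
    """Parse one exchange CSV back into a :class:`PatientRecord`."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    structures = {}
    for role, group in df.groupby("structure", sort=True):
        lo = group["bin_lo_gy"].to_numpy(dtype=float)
        hi = group["bin_hi_gy"].to_numpy(dtype=float)
        order = np.argsort(lo)
        lo, hi = lo[order], hi[order]
        if not np.allclose(lo[1:], hi[:-1], atol=1e-9):
            raise ValidationError(f"{path}: bins of structure {role!r} are not contiguous")
        volumes = group["absolute_volume_cm3"].to_numpy(dtype=float)
        structures[str(role)] = DoseVolumeHistogram(
            structure_name=str(role),
            bin_edges=np.concatenate([lo, hi[-1:]]),
            volume_fraction=group["volume_fraction"].to_numpy(dtype=float)[order],
            absolute_volume=float(volumes[0]),
        )
    return PatientRecord(patient_id=patient_id, arm=arm, plan=plan, structures=structures)


def write_cohort(
    patients: list[PatientRecord],
    directory: str | Path,
    spec: SyntheticCohortSpec | None = None,
) -> Path:
    """Write one CSV per patient plus ``manifest.json``; returns the directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if not patients:
        raise ValidationError("cannot write an empty cohort")
    arms = {p.arm for p in patients}
    if len(arms) != 1:
        raise ValidationError(f"cohort mixes arms {sorted(arms)}")
    plan = patients[0].plan
    for p in patients:
        write_patient_csv(p, directory / f"{p.patient_id}.csv")
    manifest = {
        "arm": patients[0].arm,
        "plan": {"total_dose": plan.total_dose, "n_fractions": plan.n_fractions},
        "patients": [p.patient_id for p in patients],
    }
    if spec is not None:
        manifest["generator"] = spec_to_manifest(spec)
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return directory


def read_cohort(directory: str | Path, skip_bad: bool = True) -> list[PatientRecord]:
    """Load a cohort directory written by :func:`write_cohort`.

    Unreadable patient files are logged and skipped when ``skip_bad`` is set
    (the pipeline's error contract); pass ``skip_bad=False`` to raise instead.
    """
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    plan = PlanContext(**manifest["plan"])
    arm = manifest["arm"]
    patients = []
    for pid in manifest["patients"]:
        path = directory / f"{pid}.csv"
        try:
            patients.append(read_patient_csv(path, pid, arm, plan))
        except Exception as exc:
            if not skip_bad:
                raise
            logger.warning("skipping unreadable patient file %s: %s", path, exc)
    if not patients:
        raise ValidationError(f"no readable patients in {directory}")
    return patients


def dicom_to_patient(
    rtstruct_path: str | Path,
    rtdose_path: str | Path,
    patient_id: str,
    arm: str,
    plan: PlanContext,
    structure_roles: dict[str, str],
) -> PatientRecord:
    """Extract per-structure DVHs from a DICOM RT-structure / RT-dose pair.

    Delegates DVH extraction to ``dicompyler-core`` (install the ``dicom``
    extra); ``structure_roles`` maps DICOM ROI names to this package's
    structure roles (``"PTV"``, ``"heart"``, ...). The returned record feeds
    the same pipeline as CSV input.
    """
    try:
        from dicompylercore import dicomparser, dvhcalc
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "DICOM ingestion requires the optional 'dicom' extra "
            "(pip install planeval[dicom])"
        ) from exc
    parser = dicomparser.DicomParser(str(rtstruct_path))
    rois = {s["name"]: key for key, s in parser.GetStructures().items()}
    structures = {}
    for roi_name, role in structure_roles.items():
        if roi_name not in rois:
            logger.warning("ROI %r not found in %s", roi_name, rtstruct_path)
            continue
        calc = dvhcalc.get_dvh(str(rtstruct_path), str(rtdose_path), rois[roi_name])
        diff = calc.relative_volume.differential  # fractions per bin, dose in Gy
        edges = np.append(diff.bincenters - diff.binsize / 2.0, diff.bincenters[-1] + diff.binsize / 2.0)
        frac = diff.counts / 100.0
        structures[role] = DoseVolumeHistogram(
            structure_name=role,
            bin_edges=edges,
            volume_fraction=frac / frac.sum(),
            absolute_volume=float(calc.volume),
        )
    return PatientRecord(patient_id=patient_id, arm=arm, plan=plan, structures=structures)
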