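"""Synthetic two-arm breast-plan cohorts.

Generates per-patient, per-structure differential DVHs with the statistical
structure the analysis assumes, so the full pipeline is testable without
patient DICOM data. Each structure's voxel doses are drawn from a truncated
Gaussian (or a bimodal cold-spot mixture) around a structure-specific
fraction of the prescription; structure volumes are Gaussian in cm^3.

The arm defaults emulate the study conditions: a conventionally fractionated
(CF) arm of 19 patients at 50 Gy / 25 fractions and a hypofractionated (HF)
arm of 9 patients at 42.56 Gy / 16 fractions, with structure-volume means and
SDs matching the clinical cohorts (heart 490 +/- 79 cm^3 CF, PTV 673 +/- 206
cm^3 CF, ...). PTV and chest-wall mean dose sits a few percent above
prescription with ~1 Gy voxel spread; the ipsilateral lung receives a far
higher dose fraction (0.25) than the contralateral lung (0.03) or heart
(0.05), reproducing the anatomical ordering of organ exposure. The OAR dose
fractions and the between-patient jitter are tuning constants of the
generator, not clinical measurements.

Randomness is driven by ``numpy`` ``SeedSequence`` substreams keyed on
``(seed, patient_index)``, so any patient can be regenerated independently
and cohorts are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .dvh import DoseVolumeHistogram, PlanContext
from .exceptions import ValidationError
from .metrics import PatientRecord

__all__ = [
    "StructureDoseModel",
    "StructureVolumeModel",
    "SyntheticCohortSpec",
    "default_cf_spec",
    "default_hf_spec",
    "generate_patient",
    "generate_cohort",
]

CF_PLAN = PlanContext(total_dose=50.0, n_fractions=25)
HF_PLAN = PlanContext(total_dose=42.56, n_fractions=16)

DOSE_SHAPES = ("gaussian_truncated", "bimodal_cold_spot")


@dataclass(frozen=True)
class StructureDoseModel:
    """Voxel-dose law of one structure.

    ``mean_dose_fraction`` scales the prescription; ``dose_sd_gy`` is the
    within-structure (voxel-to-voxel) spread; ``patient_sd_gy`` jitters the
    structure's mean dose between patients, producing the between-patient
    variance the arm-level t-tests operate on. The ``bimodal_cold_spot``
    shape moves ``cold_fraction`` of the voxels down by ``cold_drop_fraction``
    of the mean, exercising the cold-spot sensitivity of negative-exponent
    EUD.
    """

    mean_dose_fraction: float
    dose_sd_gy: float = 1.0
    patient_sd_gy: float = 0.2
    shape: str = "gaussian_truncated"
    cold_fraction: float = 0.05
    cold_drop_fraction: float = 0.15

    def __post_init__(self) -> None:
        if self.mean_dose_fraction < 0:
            raise ValidationError("mean_dose_fraction must be >= 0")
        if self.dose_sd_gy < 0 or self.patient_sd_gy < 0:
            raise ValidationError("dose SDs must be >= 0")
        if self.shape not in DOSE_SHAPES:
            raise ValidationError(f"shape must be one of {DOSE_SHAPES}, got {self.shape!r}")
        if not 0 <= self.cold_fraction < 1:
            raise ValidationError("cold_fraction must lie in [0, 1)")


@dataclass(frozen=True)
class StructureVolumeModel:
    """Gaussian structure volume in cm^3, truncated away from zero."""

    mean_cm3: float
    sd_cm3: float

    def __post_init__(self) -> None:
        if self.mean_cm3 <= 0 or self.sd_cm3 < 0:
            raise ValidationError("volume mean must be > 0 and SD >= 0")


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Everything needed to generate one arm's cohort deterministically."""

    arm: str
    plan: PlanContext
    n_patients: int
    dose_models: dict[str, StructureDoseModel]
    volume_models: dict[str, StructureVolumeModel]
    bin_width: float = 0.1
    n_voxels: int = 4000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.arm not in ("CF", "HF"):
            raise ValidationError(f"arm must be 'CF' or 'HF', got {self.arm!r}")
        if self.n_patients < 1:
            raise ValidationError("n_patients must be >= 1")
        if self.bin_width <= 0 or self.n_voxels < 1:
            raise ValidationError("bin_width must be > 0 and n_voxels >= 1")
        if "PTV" not in self.dose_models:
            raise ValidationError("dose_models must include the PTV")
        if set(self.dose_models) != set(self.volume_models):
            raise ValidationError("dose_models and volume_models must cover the same structures")


# -- arm defaults --------------------------------------------------------

# Between-patient jitter (Gy) per structure; tuning constants sized so the
# arm-level SDs of EUD/TCP/NTCP sit in realistic clinical ranges.
_PATIENT_SD = {
    "PTV": 0.25,
    "chest_wall": 0.6,
    "ipsilateral_lung": 1.0,
    "contralateral_lung": 0.3,
    "heart": 0.5,
}

# Within-structure voxel SD in Gy for the CF prescription; HF scales by
# prescription ratio except for the target structures, whose ~1 Gy spread is
# what yields HI ~ 0.08-0.10 in both arms.
_VOXEL_SD_CF = {
    "PTV": 1.0,
    "chest_wall": 1.2,
    "ipsilateral_lung": 6.0,
    "contralateral_lung": 1.2,
    "heart": 2.0,
}

_MEAN_FRACTION = {
    "CF": {
        "PTV": 1.036,
        "chest_wall": 1.035,
        "ipsilateral_lung": 0.25,
        "contralateral_lung": 0.03,
        "heart": 0.05,
    },
    "HF": {
        "PTV": 1.028,
        "chest_wall": 1.027,
        "ipsilateral_lung": 0.25,
        "contralateral_lung": 0.03,
        "heart": 0.05,
    },
}

_VOLUMES = {
    "CF": {
        "heart": (490.0, 79.0),
        "ipsilateral_lung": (928.0, 192.0),
        "contralateral_lung": (1000.0, 268.0),
        "chest_wall": (515.0, 187.0),
        "PTV": (673.0, 206.0),
    },
    "HF": {
        "heart": (569.0, 129.0),
        "ipsilateral_lung": (931.0, 234.0),
        "contralateral_lung": (1080.0, 220.0),
        "chest_wall": (541.0, 164.0),
        "PTV": (706.0, 184.0),
    },
}


def _default_spec(arm: str, plan: PlanContext, n_patients: int, seed: int) -> SyntheticCohortSpec:
    sd_scale = 1.0 if arm == "CF" else plan.total_dose / CF_PLAN.total_dose
    dose_models = {}
    for role, frac in _MEAN_FRACTION[arm].items():
        voxel_sd = _VOXEL_SD_CF[role]
        if role not in ("PTV", "chest_wall"):
            voxel_sd *= sd_scale
        dose_models[role] = StructureDoseModel(
            mean_dose_fraction=frac,
            dose_sd_gy=voxel_sd,
            patient_sd_gy=_PATIENT_SD[role],
        )
    volume_models = {
        role: StructureVolumeModel(mean_cm3=m, sd_cm3=s) for role, (m, s) in _VOLUMES[arm].items()
    }
    return SyntheticCohortSpec(
        arm=arm,
        plan=plan,
        n_patients=n_patients,
        dose_models=dose_models,
        volume_models=volume_models,
        seed=seed,
    )


def default_cf_spec(n_patients: int = 19, seed: int = 0) -> SyntheticCohortSpec:
    """Conventional-fractionation arm: 50 Gy / 25 fx, 19 patients."""
    return _default_spec("CF", CF_PLAN, n_patients, seed)


def default_hf_spec(n_patients: int = 9, seed: int = 0) -> SyntheticCohortSpec:
    """Hypofractionation arm: 42.56 Gy / 16 fx, 9 patients."""
    return _default_spec("HF", HF_PLAN, n_patients, seed)


# -- generation ----------------------------------------------------------


def _sample_structure(
    rng: np.random.Generator,
    role: str,
    dose_model: StructureDoseModel,
    volume_model: StructureVolumeModel,
    plan: PlanContext,
    bin_width: float,
    n_voxels: int,
) -> DoseVolumeHistogram:
    volume = max(float(rng.normal(volume_model.mean_cm3, volume_model.sd_cm3)), 1.0)
    mean = dose_model.mean_dose_fraction * plan.total_dose
    mean += float(rng.normal(0.0, dose_model.patient_sd_gy)) if dose_model.patient_sd_gy else 0.0
    mean = max(mean, 0.0)
    if dose_model.dose_sd_gy == 0:
        return DoseVolumeHistogram.uniform(mean, role, volume, bin_width)
    doses = rng.normal(mean, dose_model.dose_sd_gy, size=n_voxels)
    if dose_model.shape == "bimodal_cold_spot":
        n_cold = int(round(dose_model.cold_fraction * n_voxels))
        doses[:n_cold] -= dose_model.cold_drop_fraction * mean
    np.clip(doses, 0.0, None, out=doses)
    return DoseVolumeHistogram.from_doses(doses, role, volume, bin_width)


def generate_patient(spec: SyntheticCohortSpec, patient_index: int) -> PatientRecord:
    """Deterministic patient: same ``(seed, patient_index)`` -> same record."""
    if not 0 <= patient_index < spec.n_patients:
        raise ValidationError(
            f"patient_index must lie in [0, {spec.n_patients}), got {patient_index}"
        )
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(patient_index,)))
    structures = {
        role: _sample_structure(
            rng, role, spec.dose_models[role], spec.volume_models[role],
            spec.plan, spec.bin_width, spec.n_voxels,
        )
        for role in sorted(spec.dose_models)
    }
    return PatientRecord(
        patient_id=f"{spec.arm}-{patient_index:03d}",
        arm=spec.arm,
        plan=spec.plan,
        structures=structures,
    )


def generate_cohort(spec: SyntheticCohortSpec) -> list[PatientRecord]:
    """All ``n_patients`` records; patients are independent substreams."""
    return [generate_patient(spec, i) for i in range(spec.n_patients)]


def spec_to_manifest(spec: SyntheticCohortSpec) -> dict:
    """JSON-serializable echo of a cohort spec (written beside generated CSVs)."""
    d = asdict(spec)
    d["plan"] = {"total_dose": spec.plan.total_dose, "n_fractions": spec.plan.n_fractions}
    return d
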