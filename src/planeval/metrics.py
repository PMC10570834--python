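"""Plan-quality indices: homogeneity index (HI) and conformity index (CI).

HI = (D2% - D98%) / prescription measures dose spread inside the target: 0 is
a perfectly flat target dose, ~0.1 means the hottest and coldest regions of
the PTV differ by 10% of the prescription.

CI = (V_RI,PTV)^2 / (100 * sum_structures V_RI) measures how tightly the
reference isodose (default 95% of prescription) conforms to the target. The
sum runs over every contoured structure *including* the PTV, each V expressed
as a percentage of that structure's own volume; the ideal plan — full target
coverage, no other structure reaching the reference isodose — scores exactly
1, and CI never exceeds 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .dvh import DoseVolumeHistogram, PlanContext, dose_at_volume_fraction, volume_at_dose_percent
from .exceptions import DegeneratePlanError, MissingStructureError, ValidationError

__all__ = [
    "PatientRecord",
    "homogeneity_index",
    "conformity_index",
    "DEFAULT_RI_FRACTION",
]

DEFAULT_RI_FRACTION = 0.95

#: Canonical structure roles of a breast plan.
KNOWN_ROLES = (
    "PTV",
    "heart",
    "ipsilateral_lung",
    "contralateral_lung",
    "chest_wall",
    "spinal_cord",
    "contralateral_breast",
)


@dataclass
class PatientRecord:
    """One patient's plan: arm label, prescription and per-structure DVHs."""

    patient_id: str
    arm: str
    plan: PlanContext
    structures: dict[str, DoseVolumeHistogram] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.arm not in ("CF", "HF"):
            raise ValidationError(f"arm must be 'CF' or 'HF', got {self.arm!r}")
        if "PTV" not in self.structures:
            raise MissingStructureError(f"patient {self.patient_id}: no PTV structure")

    def structure(self, role: str) -> DoseVolumeHistogram:
        try:
            return self.structures[role]
        except KeyError:
            raise MissingStructureError(
                f"patient {self.patient_id}: no structure {role!r}"
            ) from None


def homogeneity_index(
    ptv: DoseVolumeHistogram,
    plan: PlanContext,
    upper_percent: float = 2.0,
    lower_percent: float = 98.0,
) -> float:
    """(D2% - D98%) / prescription dose; 0 for a perfectly uniform target dose."""
    d_hot = dose_at_volume_fraction(ptv, upper_percent)
    d_cold = dose_at_volume_fraction(ptv, lower_percent)
    return (d_hot - d_cold) / plan.total_dose


def conformity_index(
    patient: PatientRecord,
    reference_isodose: float | None = None,
    ri_fraction: float = DEFAULT_RI_FRACTION,
) -> float:
    """Squared PTV coverage at the reference isodose over the total relative
    volume at that isodose, summed across all contoured structures.

    ``reference_isodose`` is in Gy; when omitted it defaults to
    ``ri_fraction`` times the prescription (47.5 Gy for 50 Gy / 25 fx,
    40.43 Gy for 42.56 Gy / 16 fx at the default 0.95).
    """
    ri = reference_isodose if reference_isodose is not None else ri_fraction * patient.plan.total_dose
    v_ptv = volume_at_dose_percent(patient.structure("PTV"), ri)
    total = sum(volume_at_dose_percent(dvh, ri) for dvh in patient.structures.values())
    if total == 0:
        raise DegeneratePlanError(
            f"patient {patient.patient_id}: no structure receives {ri:g} Gy; CI undefined"
        )
    return v_ptv**2 / (100.0 * total)
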