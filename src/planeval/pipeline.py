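"""End-to-end orchestration: ingest cohorts, compute per-patient metrics,
compare arms, write reports.

Outputs of :func:`run_pipeline` (all plain text, byte-reproducible for fixed
inputs):

* ``per_patient_metrics.csv`` — one row per patient with CI, HI,
  Dmin/Dmax/Dmean of the PTV, EUD and TCP of the PTV, NTCP of heart and both
  lungs (in %), and V95/V100/V107 of PTV and chest wall.
* ``comparison.csv`` / ``comparison.txt`` — the two-arm report: per-quantity
  mean +/- SD for each arm, pooled t statistic and two-sided p-value.

EUD and TCP are evaluated for the PTV only; LKB NTCP for the heart and the
two lungs only. Other ingested structures (spinal cord, contralateral
breast, ...) contribute their volumes and V-metrics but receive no
radiobiological endpoint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .compare import comparisons_to_frame, compare_cohorts, format_report, standard_quantities
from .dvh import PlanContext, summary_stats
from .exceptions import ValidationError
from .io import read_cohort
from .metrics import DEFAULT_RI_FRACTION, PatientRecord, conformity_index, homogeneity_index
from .radbio import (
    TissueParameters,
    default_tissue_parameters,
    eud,
    load_tissue_parameters,
    ntcp_lkb,
    tcp_poisson_lq,
    tissue_for_structure,
)
from .dvh import volume_at_dose_percent

__all__ = ["RunConfig", "patient_metrics", "patients_to_frame", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Inputs and knobs of one full pipeline run."""

    cf_dir: str | Path
    hf_dir: str | Path
    out_dir: str | Path
    tissue_file: str | Path | None = None
    ri_fraction: float = DEFAULT_RI_FRACTION
    equal_var: bool = True

    def __post_init__(self) -> None:
        if Path(self.cf_dir).resolve() == Path(self.hf_dir).resolve():
            raise ValidationError("CF and HF cohort directories must be disjoint")
        if not 0 < self.ri_fraction:
            raise ValidationError("ri_fraction must be positive")


def patient_metrics(
    patient: PatientRecord,
    tissue: dict[str, TissueParameters] | None = None,
    ri_fraction: float = DEFAULT_RI_FRACTION,
) -> dict[str, float | str]:
    """All per-patient quantities as one flat record (NaN where undefined)."""
    reg = tissue if tissue is not None else default_tissue_parameters()
    ptv = patient.structure("PTV")
    stats = summary_stats(ptv)
    row: dict[str, float | str] = {
        "patient_id": patient.patient_id,
        "arm": patient.arm,
        "CI": conformity_index(patient, ri_fraction=ri_fraction),
        "HI": homogeneity_index(ptv, patient.plan),
        "Dmin_PTV_gy": stats["d_min"],
        "Dmax_PTV_gy": stats["d_max"],
        "Dmean_PTV_gy": stats["d_mean"],
        "EUD_PTV_gy": eud(ptv, patient.plan, tissue_for_structure("PTV", reg)),
        "TCP_PTV_pct": 100.0 * tcp_poisson_lq(ptv, patient.plan, tissue_for_structure("PTV", reg)),
    }
    for role in ("heart", "ipsilateral_lung", "contralateral_lung"):
        try:
            row[f"NTCP_{role}_pct"] = 100.0 * ntcp_lkb(
                patient.structure(role), patient.plan, tissue_for_structure(role, reg)
            )
        except KeyError:
            logger.warning("patient %s: no %s structure; NTCP omitted", patient.patient_id, role)
            row[f"NTCP_{role}_pct"] = float("nan")
    for role in ("PTV", "chest_wall"):
        for pct in (95, 100, 107):
            try:
                row[f"V{pct}_{role}_pct"] = volume_at_dose_percent(
                    patient.structure(role), pct / 100.0 * patient.plan.total_dose
                )
            except KeyError:
                row[f"V{pct}_{role}_pct"] = float("nan")
    return row


def patients_to_frame(
    patients: list[PatientRecord],
    tissue: dict[str, TissueParameters] | None = None,
    ri_fraction: float = DEFAULT_RI_FRACTION,
) -> pd.DataFrame:
    rows = [patient_metrics(p, tissue, ri_fraction) for p in patients]
    return pd.DataFrame(rows).sort_values(["arm", "patient_id"]).reset_index(drop=True)


def run_pipeline(config: RunConfig):
    """Full run: read both cohorts, compute metrics, compare, write reports.

    Returns ``(per_patient_frame, comparison_rows)``.
    """
    tissue = (
        load_tissue_parameters(config.tissue_file)
        if config.tissue_file
        else default_tissue_parameters()
    )
    cf = read_cohort(config.cf_dir)
    hf = read_cohort(config.hf_dir)
    if len(cf) < 2 or len(hf) < 2:
        raise ValidationError("each arm needs at least two readable patients")
    logger.info("loaded %d CF and %d HF patients", len(cf), len(hf))

    per_patient = patients_to_frame(cf + hf, tissue, config.ri_fraction)
    rows = compare_cohorts(
        cf, hf,
        quantities=standard_quantities(tissue, config.ri_fraction),
        equal_var=config.equal_var,
    )

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    per_patient.to_csv(out / "per_patient_metrics.csv", index=False, float_format="%.10g")
    comparisons_to_frame(rows).to_csv(out / "comparison.csv", index=False, float_format="%.10g")
    (out / "comparison.txt").write_text(format_report(rows) + "\n")
    return per_patient, rows
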