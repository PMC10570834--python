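"""Two-arm cohort comparison: per-quantity mean +/- SD and independent-sample
t-tests between the conventionally fractionated (CF) and hypofractionated
(HF) arms.

The default test is the classical pooled-variance (Student) two-sided t-test;
Welch's unequal-variance form is available behind ``equal_var=False``. The t
sign convention is ``(mean_CF - mean_HF) / SE``. No multiple-testing
correction is applied; each quantity is tested marginally at alpha = 0.05.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InsufficientDataError
from .metrics import (
    DEFAULT_RI_FRACTION,
    PatientRecord,
    conformity_index,
    homogeneity_index,
)
from .radbio import (
    TissueParameters,
    default_tissue_parameters,
    eud,
    ntcp_lkb,
    tcp_poisson_lq,
    tissue_for_structure,
)
from .dvh import volume_at_dose_percent

__all__ = [
    "ArmSummary",
    "CohortComparison",
    "summarize_arm",
    "independent_t_test",
    "standard_quantities",
    "compare_cohorts",
    "comparisons_to_frame",
    "format_report",
]

logger = logging.getLogger(__name__)

ALPHA = 0.05


@dataclass(frozen=True)
class ArmSummary:
    mean: float
    sd: float
    n: int


@dataclass(frozen=True)
class CohortComparison:
    """One report row: a quantity's per-arm summary plus the t-test."""

    quantity_name: str
    cf_mean: float
    cf_sd: float
    cf_n: int
    hf_mean: float
    hf_sd: float
    hf_n: int
    t_value: float
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def summarize_arm(values: Sequence[float]) -> ArmSummary:
    """Arithmetic mean and sample SD (n-1 denominator) of one arm's values."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise InsufficientDataError(f"need >= 2 observations, got {arr.size}")
    return ArmSummary(mean=float(arr.mean()), sd=float(arr.std(ddof=1)), n=int(arr.size))


def independent_t_test(
    group_a: Sequence[float], group_b: Sequence[float], equal_var: bool = True
) -> tuple[float, float]:
    """Two-sided independent-sample t-test; returns ``(t, p)``.

    Sign convention: ``t = (mean_a - mean_b) / SE``. Degenerate zero-variance
    inputs are resolved explicitly: equal means give ``(0, 1)``, unequal means
    ``(+/-inf, 0)``.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each group needs >= 2 observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
    with warnings.catch_warnings():
        # near-constant groups (e.g. V95 ~ 100% for every patient) trigger a
        # scipy precision warning; exact zero variance is already handled above
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


# -- quantity extraction -------------------------------------------------

Extractor = Callable[[PatientRecord], float]


def standard_quantities(
    tissue: dict[str, TissueParameters] | None = None,
    ri_fraction: float = DEFAULT_RI_FRACTION,
) -> list[tuple[str, Extractor]]:
    """The report's quantity list, in fixed row order.

    Covers structure volumes; CI and HI; EUD and TCP of the PTV; LKB NTCP of
    the heart and both lungs (reported in %); and the PTV / chest-wall volume
    percentages at 95, 100 and 107% of the prescription.
    """
    reg = tissue if tissue is not None else default_tissue_parameters()

    def vol(role: str) -> Extractor:
        return lambda p: p.structure(role).absolute_volume

    def v_at(role: str, frac: float) -> Extractor:
        return lambda p: volume_at_dose_percent(p.structure(role), frac * p.plan.total_dose)

    def ntcp_pct(role: str) -> Extractor:
        return lambda p: 100.0 * ntcp_lkb(p.structure(role), p.plan, tissue_for_structure(role, reg))

    quantities: list[tuple[str, Extractor]] = [
        ("volume_heart_cm3", vol("heart")),
        ("volume_ipsilateral_lung_cm3", vol("ipsilateral_lung")),
        ("volume_contralateral_lung_cm3", vol("contralateral_lung")),
        ("volume_chest_wall_cm3", vol("chest_wall")),
        ("volume_PTV_cm3", vol("PTV")),
        ("CI", lambda p: conformity_index(p, ri_fraction=ri_fraction)),
        ("HI", lambda p: homogeneity_index(p.structure("PTV"), p.plan)),
        ("EUD_PTV_gy", lambda p: eud(p.structure("PTV"), p.plan, tissue_for_structure("PTV", reg))),
        (
            "TCP_PTV_pct",
            lambda p: 100.0 * tcp_poisson_lq(p.structure("PTV"), p.plan, tissue_for_structure("PTV", reg)),
        ),
        ("NTCP_heart_pct", ntcp_pct("heart")),
        ("NTCP_ipsilateral_lung_pct", ntcp_pct("ipsilateral_lung")),
        ("NTCP_contralateral_lung_pct", ntcp_pct("contralateral_lung")),
        ("V95_PTV_pct", v_at("PTV", 0.95)),
        ("V100_PTV_pct", v_at("PTV", 1.00)),
        ("V107_PTV_pct", v_at("PTV", 1.07)),
        ("V95_chest_wall_pct", v_at("chest_wall", 0.95)),
        ("V100_chest_wall_pct", v_at("chest_wall", 1.00)),
        ("V107_chest_wall_pct", v_at("chest_wall", 1.07)),
    ]
    return quantities


def _extract(patients: Sequence[PatientRecord], name: str, fn: Extractor) -> list[float]:
    out = []
    for p in patients:
        try:
            out.append(fn(p))
        except KeyError as exc:  # MissingStructureError
            logger.warning("patient %s excluded from %s: %s", p.patient_id, name, exc)
    return out


def compare_cohorts(
    cf_patients: Sequence[PatientRecord],
    hf_patients: Sequence[PatientRecord],
    quantities: Sequence[tuple[str, Extractor]] | None = None,
    equal_var: bool = True,
) -> list[CohortComparison]:
    """One :class:`CohortComparison` per quantity, CF vs HF, in list order."""
    if quantities is None:
        quantities = standard_quantities()
    rows = []
    for name, fn in quantities:
        cf_vals = _extract(cf_patients, name, fn)
        hf_vals = _extract(hf_patients, name, fn)
        cf, hf = summarize_arm(cf_vals), summarize_arm(hf_vals)
        t, p = independent_t_test(cf_vals, hf_vals, equal_var=equal_var)
        rows.append(
            CohortComparison(
                quantity_name=name,
                cf_mean=cf.mean, cf_sd=cf.sd, cf_n=cf.n,
                hf_mean=hf.mean, hf_sd=hf.sd, hf_n=hf.n,
                t_value=t, p_value=p,
            )
        )
    return rows


def comparisons_to_frame(rows: Sequence[CohortComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "quantity": [r.quantity_name for r in rows],
            "cf_mean": [r.cf_mean for r in rows],
            "cf_sd": [r.cf_sd for r in rows],
            "cf_n": [r.cf_n for r in rows],
            "hf_mean": [r.hf_mean for r in rows],
            "hf_sd": [r.hf_sd for r in rows],
            "hf_n": [r.hf_n for r in rows],
            "t_value": [r.t_value for r in rows],
            "p_value": [r.p_value for r in rows],
            "significant": [r.significant for r in rows],
        }
    )


def format_report(rows: Sequence[CohortComparison]) -> str:
    """Human-readable table: quantity, CF mean+/-SD, HF mean+/-SD, t, p."""
    lines = [
        f"{'quantity':<30} {'CF (mean ± SD)':>20} {'HF (mean ± SD)':>20} {'t':>8} {'p':>8}",
        "-" * 90,
    ]
    for r in rows:
        star = " *" if r.significant else ""
        lines.append(
            f"{r.quantity_name:<30} {r.cf_mean:>12.4g} ± {r.cf_sd:<6.3g} "
            f"{r.hf_mean:>12.4g} ± {r.hf_sd:<6.3g} {r.t_value:>8.2f} {r.p_value:>8.3g}{star}"
        )
    lines.append("-" * 90)
    lines.append("* p < 0.05 (two-sided, no multiple-testing correction)")
    return "\n".join(lines)
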