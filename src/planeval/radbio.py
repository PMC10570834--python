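"""Radiobiological endpoints: EQD2 conversion, Niemierko EUD, Poisson-LQ TCP
and Lyman-Kutcher-Burman NTCP.

All endpoint functions consume a *differential* DVH together with the plan's
prescription (total dose and fraction number). Each bin's total dose ``D_i``
is assumed delivered over all ``n_f`` fractions at ``D_i / n_f`` per fraction,
and is first converted to its 2-Gy-per-fraction equivalent

    EQD_i = D_i * (alpha/beta + D_i / n_f) / (alpha/beta + 2),

the standard linear-quadratic isoeffect transform (EQD equals the physical
dose exactly when the plan delivers 2 Gy per fraction). The per-bin EQDs and
the fractional volumes are then reduced to a scalar endpoint:

* EUD: generalized mean with tissue exponent ``a`` (negative for tumors, so
  cold spots dominate).
* TCP: Poisson linear-quadratic response with slope ``gamma`` and ``D50``,
  multiplied voxel-wise (log-additive in fractional volume).
* NTCP: LKB probit of the Kutcher-Burman effective dose
  ``D_eff = (sum v_i EQD_i^(1/n))^n`` via ``t = (D_eff - D50)/(m D50)``.

Tissue constants (alpha/beta = 4 Gy for breast, heart and lung; breast target
a = -7.2, gamma = 1.3, D50 = 30.89 Gy; heart D50 = 48 Gy, m = 0.1, n = 0.35;
lung D50 = 37.6 Gy, m = 0.35, n = 0.87) ship as a YAML registry and every
value can be overridden per run.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml
from scipy.special import logsumexp, ndtr

from .dvh import DoseVolumeHistogram, PlanContext
from .exceptions import DomainError, ParameterError

__all__ = [
    "TissueParameters",
    "default_tissue_parameters",
    "load_tissue_parameters",
    "tissue_for_structure",
    "eqd",
    "eud",
    "tcp_poisson_lq",
    "effective_dose",
    "ntcp_lkb",
]


@dataclass(frozen=True)
class TissueParameters:
    """Radiobiological constants of one organ/endpoint.

    Target tissues define ``a_exponent``, ``gamma`` and ``d50`` (EUD and TCP);
    organs at risk define ``d50``, ``m_slope`` and ``n_volume`` (LKB NTCP).
    ``alpha_beta`` is required by every endpoint.
    """

    organ: str
    alpha_beta: float
    a_exponent: float | None = None
    gamma: float | None = None
    d50: float | None = None
    m_slope: float | None = None
    n_volume: float | None = None

    def __post_init__(self) -> None:
        if not self.alpha_beta > 0:
            raise ParameterError(f"alpha_beta must be > 0, got {self.alpha_beta}")
        if self.d50 is not None and not self.d50 > 0:
            raise ParameterError(f"d50 must be > 0, got {self.d50}")
        if self.m_slope is not None and not self.m_slope > 0:
            raise ParameterError(f"m must be > 0, got {self.m_slope}")
        if self.n_volume is not None and not 0 < self.n_volume <= 1:
            raise ParameterError(f"n must lie in (0, 1], got {self.n_volume}")


def _registry_from_mapping(raw: dict) -> dict[str, TissueParameters]:
    reg = {}
    for organ, vals in raw.items():
        reg[organ] = TissueParameters(
            organ=organ,
            alpha_beta=float(vals["alpha_beta"]),
            a_exponent=float(vals["a"]) if "a" in vals else None,
            gamma=float(vals["gamma"]) if "gamma" in vals else None,
            d50=float(vals["d50"]) if "d50" in vals else None,
            m_slope=float(vals["m"]) if "m" in vals else None,
            n_volume=float(vals["n"]) if "n" in vals else None,
        )
    return reg


def default_tissue_parameters() -> dict[str, TissueParameters]:
    """Registry of shipped defaults, keyed ``breast_ptv`` / ``heart`` / ``lung``."""
    text = resources.files("planeval").joinpath("data/tissue_defaults.yaml").read_text()
    return _registry_from_mapping(yaml.safe_load(text))


def load_tissue_parameters(path: str | Path) -> dict[str, TissueParameters]:
    """Load a user YAML registry; entries replace the shipped defaults."""
    reg = default_tissue_parameters()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    reg.update(_registry_from_mapping(raw))
    return reg


#: Structure-role -> registry-key mapping used by the pipeline.
STRUCTURE_TISSUE = {
    "PTV": "breast_ptv",
    "heart": "heart",
    "ipsilateral_lung": "lung",
    "contralateral_lung": "lung",
}


def tissue_for_structure(role: str, registry: dict[str, TissueParameters] | None = None) -> TissueParameters:
    registry = registry if registry is not None else default_tissue_parameters()
    try:
        return registry[STRUCTURE_TISSUE[role]]
    except KeyError as exc:
        raise ParameterError(f"no tissue parameters defined for structure role {role!r}") from exc


# -- EQD2 ----------------------------------------------------------------


def eqd(total_bin_dose, n_fractions: int, alpha_beta: float):
    """2-Gy-per-fraction equivalent of a total dose delivered in ``n_fractions``.

    Accepts scalars or arrays; strictly increasing in dose and equal to the
    physical dose at exactly 2 Gy per fraction.
    """
    d = np.asarray(total_bin_dose, dtype=float)
    if np.any(d < 0):
        raise DomainError("dose must be non-negative")
    if n_fractions < 1:
        raise DomainError(f"n_fractions must be >= 1, got {n_fractions}")
    if alpha_beta <= 0:
        raise ParameterError(f"alpha_beta must be > 0, got {alpha_beta}")
    out = d * (alpha_beta + d / n_fractions) / (alpha_beta + 2.0)
    return float(out) if np.isscalar(total_bin_dose) else out


def _bin_eqd(dvh: DoseVolumeHistogram, plan: PlanContext, alpha_beta: float):
    """Per-bin EQD and fractional volumes of a differential DVH (occupied bins)."""
    dvh.require_form("differential")
    occupied = dvh.volume_fraction > 0
    weights = dvh.volume_fraction[occupied]
    weights = weights / weights.sum()
    doses = dvh.bin_centers[occupied]
    return eqd(doses, plan.n_fractions, alpha_beta), weights


# -- Niemierko EUD -------------------------------------------------------


def eud(
    dvh: DoseVolumeHistogram,
    plan: PlanContext,
    params: TissueParameters,
    dose_floor: float = 0.0,
) -> float:
    """Equivalent uniform dose ``(sum_i v_i EQD_i^a)^(1/a)`` in Gy.

    For tumor exponents ``a < 0`` a single zero-dose bin drives the
    generalized mean to its mathematical limit 0; the function then returns
    0.0 with a warning. Passing ``dose_floor > 0`` (e.g. 1e-6 Gy) clamps
    per-bin EQD from below for users who want a cold-spot-robust EUD.
    """
    if params.a_exponent is None or params.a_exponent == 0:
        raise ParameterError(f"tissue {params.organ!r} defines no nonzero EUD exponent a")
    a = params.a_exponent
    eqd_i, w = _bin_eqd(dvh, plan, params.alpha_beta)
    if dose_floor > 0:
        eqd_i = np.maximum(eqd_i, dose_floor)
    if np.any(eqd_i <= 0):
        if a < 0:
            warnings.warn(
                "zero-dose bin with negative EUD exponent: EUD is 0 in the limit "
                "(set dose_floor > 0 for a cold-spot-robust value)",
                stacklevel=2,
            )
            return 0.0
        eqd_i, w = eqd_i[eqd_i > 0], w[eqd_i > 0]
    # log-space generalized mean: stable for |a| up to hundreds
    log_eud = logsumexp(np.log(w) + a * np.log(eqd_i)) / a
    return float(np.exp(log_eud))


# -- Poisson-LQ TCP ------------------------------------------------------

_LN_LN_2 = math.log(math.log(2.0))


def tcp_poisson_lq(
    dvh: DoseVolumeHistogram, plan: PlanContext, params: TissueParameters
) -> float:
    """Tumor control probability under the Poisson linear-quadratic model.

    Per unit volume at EQD ``E`` the response is
    ``exp(-exp(e*gamma - (E/D50) (e*gamma - ln ln 2)))`` (``e`` Euler's
    number); voxel responses multiply, weighted by fractional volume, so the
    product is evaluated log-additively. Uniform dose at ``EQD = D50`` gives
    exactly 0.5.
    """
    if params.gamma is None or params.d50 is None:
        raise ParameterError(f"tissue {params.organ!r} defines no (gamma, d50) for TCP")
    eqd_i, w = _bin_eqd(dvh, plan, params.alpha_beta)
    e_gamma = math.e * params.gamma
    inner = e_gamma - (eqd_i / params.d50) * (e_gamma - _LN_LN_2)
    log_tcp = np.sum(w * (-np.exp(inner)))
    return float(np.exp(log_tcp))


# -- LKB NTCP ------------------------------------------------------------


def effective_dose(
    dvh: DoseVolumeHistogram, plan: PlanContext, params: TissueParameters
) -> float:
    """Kutcher-Burman effective dose ``(sum_i v_i EQD_i^(1/n))^n`` in Gy.

    ``n = 1`` gives the mean EQD (parallel organ); ``n -> 0`` approaches the
    maximum (serial organ). Uniform dose returns that EQD for any ``n``.
    """
    if params.n_volume is None:
        raise ParameterError(f"tissue {params.organ!r} defines no LKB volume parameter n")
    n = params.n_volume
    eqd_i, w = _bin_eqd(dvh, plan, params.alpha_beta)
    positive = eqd_i > 0
    if not positive.any():
        return 0.0
    log_deff = n * logsumexp(np.log(w[positive]) + np.log(eqd_i[positive]) / n)
    return float(np.exp(log_deff))


def ntcp_lkb(
    dvh: DoseVolumeHistogram, plan: PlanContext, params: TissueParameters
) -> float:
    """LKB normal-tissue complication probability ``Phi((D_eff - D50)/(m D50))``."""
    if params.d50 is None or params.m_slope is None:
        raise ParameterError(f"tissue {params.organ!r} defines no (d50, m) for NTCP")
    d_eff = effective_dose(dvh, plan, params)
    t = (d_eff - params.d50) / (params.m_slope * params.d50)
    return float(ndtr(t))
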