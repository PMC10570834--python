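"""Dose-volume histograms and prescription context.

A dose-volume histogram (DVH) summarizes the dose a contoured structure
receives: in *differential* form, the fraction of the structure volume whose
dose falls in each dose bin; in *cumulative* form, the fraction of the volume
receiving at least a given dose.

Semantics used throughout this package:

* A differential DVH attributes each bin's volume fraction to the bin-center
  dose (point-mass reading). Dose statistics (``Dx%``, ``V_RI``, min/max/mean)
  are therefore exact finite sums over bin centers, with the plateau rule
  "highest dose attaining the requested volume fraction" for ``Dx%``.
* A cumulative DVH stores one value per bin *edge* (first value 1, last 0);
  queries interpolate linearly between edges, the de-facto standard of DVH
  tooling.

The two forms round-trip exactly: ``to_cumulative`` followed by
``to_differential`` reproduces the input bit-for-bit up to float addition.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .exceptions import DomainError, DVHFormError, ValidationError

__all__ = [
    "DoseVolumeHistogram",
    "PlanContext",
    "to_cumulative",
    "to_differential",
    "dose_at_volume_fraction",
    "volume_at_dose_percent",
    "summary_stats",
]

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class PlanContext:
    """Prescription of one treatment arm: total dose (Gy) over ``n_fractions``."""

    total_dose: float
    n_fractions: int

    def __post_init__(self) -> None:
        if not self.total_dose > 0:
            raise ValidationError(f"total_dose must be > 0, got {self.total_dose}")
        if int(self.n_fractions) != self.n_fractions or self.n_fractions < 1:
            raise ValidationError(f"n_fractions must be a positive integer, got {self.n_fractions}")

    @property
    def dose_per_fraction(self) -> float:
        return self.total_dose / self.n_fractions


@dataclass(frozen=True)
class DoseVolumeHistogram:
    """One structure's dose distribution.

    Parameters
    ----------
    structure_name:
        Label of the contoured structure (e.g. ``"PTV"``, ``"heart"``).
    bin_edges:
        Monotonically increasing dose values in Gy, length ``B + 1``. Bin
        centers must be non-negative; the first edge may dip slightly below
        zero so that a bin can be centered exactly at 0 Gy.
    volume_fraction:
        Differential form: per-bin volume fractions, length ``B``, summing
        to 1. Cumulative form: per-edge fractions receiving at least that
        dose, length ``B + 1``, non-increasing from 1 to 0.
    absolute_volume:
        Structure volume in cm^3.
    form:
        ``"differential"`` or ``"cumulative"``.
    """

    structure_name: str
    bin_edges: np.ndarray
    volume_fraction: np.ndarray
    absolute_volume: float
    form: str = "differential"

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        frac = np.asarray(self.volume_fraction, dtype=float)
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "volume_fraction", frac)
        if edges.ndim != 1 or edges.size < 2:
            raise ValidationError("bin_edges must be a 1-D array of at least two edges")
        if np.any(np.diff(edges) <= 0):
            raise ValidationError("bin_edges must be strictly increasing")
        centers = 0.5 * (edges[:-1] + edges[1:])
        if np.any(centers < 0):
            raise ValidationError("bin-center doses must be non-negative")
        if not self.absolute_volume > 0:
            raise ValidationError(f"absolute_volume must be > 0, got {self.absolute_volume}")
        if self.form == "differential":
            if frac.size != edges.size - 1:
                raise ValidationError(
                    f"differential DVH needs {edges.size - 1} fractions, got {frac.size}"
                )
            if np.any(frac < 0) or np.any(frac > 1):
                raise ValidationError("volume fractions must lie in [0, 1]")
            if abs(frac.sum() - 1.0) > _SUM_TOL:
                raise ValidationError(
                    f"differential volume fractions must sum to 1 (got {frac.sum():.12g})"
                )
        elif self.form == "cumulative":
            if frac.size != edges.size:
                raise ValidationError(
                    f"cumulative DVH needs {edges.size} per-edge values, got {frac.size}"
                )
            if np.any(np.diff(frac) > _SUM_TOL):
                raise ValidationError("cumulative values must be non-increasing in dose")
            if abs(frac[0] - 1.0) > _SUM_TOL:
                raise ValidationError("cumulative DVH must start at 1 (all volume receives >= 0 Gy)")
            if np.any(frac < -_SUM_TOL) or np.any(frac > 1 + _SUM_TOL):
                raise ValidationError("cumulative values must lie in [0, 1]")
        else:
            raise ValidationError(f"form must be 'differential' or 'cumulative', got {self.form!r}")

    # -- constructors ---------------------------------------------------

    @classmethod
    def uniform(
        cls,
        dose: float,
        structure_name: str = "structure",
        absolute_volume: float = 1.0,
        bin_width: float = 0.1,
    ) -> "DoseVolumeHistogram":
        """Single-bin DVH whose entire volume receives exactly ``dose`` Gy.

        The bin is centered on ``dose``; for ``dose`` below half a bin width
        (including 0 Gy) the first edge is negative, which is permitted so the
        bin-center dose is exact.
        """
        if dose < 0:
            raise DomainError(f"dose must be >= 0, got {dose}")
        half = bin_width / 2.0
        return cls(
            structure_name=structure_name,
            bin_edges=np.array([dose - half, dose + half]),
            volume_fraction=np.array([1.0]),
            absolute_volume=absolute_volume,
            form="differential",
        )

    @classmethod
    def from_doses(
        cls,
        doses: np.ndarray,
        structure_name: str = "structure",
        absolute_volume: float = 1.0,
        bin_width: float = 0.1,
        weights: np.ndarray | None = None,
    ) -> "DoseVolumeHistogram":
        """Histogram a voxel dose list onto a fixed-width grid starting at 0 Gy.

        Voxel doses within a bin are attributed to the bin center, so the
        resulting DVH quantizes each dose by at most ``bin_width / 2``.
        """
        doses = np.asarray(doses, dtype=float)
        if doses.size == 0:
            raise ValidationError("cannot build a DVH from an empty dose list")
        if np.any(doses < 0):
            raise DomainError("voxel doses must be non-negative")
        if bin_width <= 0:
            raise DomainError("bin_width must be positive")
        n_bins = max(1, int(np.ceil((doses.max() + 1e-12) / bin_width)))
        edges = np.linspace(0.0, n_bins * bin_width, n_bins + 1)
        counts, _ = np.histogram(doses, bins=edges, weights=weights)
        frac = counts / counts.sum()
        return cls(structure_name, edges, frac, absolute_volume, "differential")

    # -- derived views --------------------------------------------------

    @property
    def n_bins(self) -> int:
        return self.bin_edges.size - 1

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def require_form(self, form: str) -> None:
        if self.form != form:
            raise DVHFormError(f"expected a {form} DVH, got {self.form}")

    def rebin(self, factor: int = 2) -> "DoseVolumeHistogram":
        """Split every bin into ``factor`` equal sub-bins, assigning each
        bin's mass to the sub-bin containing its original center dose.

        For odd ``factor`` the center lies strictly inside the middle sub-bin
        and every dose statistic is exactly invariant; for even ``factor`` the
        center falls on a shared refined edge and is attributed upward,
        shifting statistics by at most half a refined bin width.
        """
        self.require_form("differential")
        if factor < 1 or int(factor) != factor:
            raise DomainError("factor must be a positive integer")
        new_edges = np.concatenate(
            [
                np.linspace(lo, hi, factor + 1)[:-1]
                for lo, hi in zip(self.bin_edges[:-1], self.bin_edges[1:])
            ]
            + [self.bin_edges[-1:]]
        )
        new_frac = np.zeros(new_edges.size - 1)
        # each original center falls in exactly one refined bin
        idx = np.searchsorted(new_edges, self.bin_centers, side="right") - 1
        np.add.at(new_frac, idx, self.volume_fraction)
        return replace(self, bin_edges=new_edges, volume_fraction=new_frac)


def to_cumulative(dvh: DoseVolumeHistogram) -> DoseVolumeHistogram:
    """Convert a differential DVH to cumulative form.

    The cumulative value at bin edge ``e`` is the total volume fraction in
    bins at or above ``e`` (every bin's mass lies at its center, above its
    lower edge), so the first value is 1 and the last 0.
    """
    dvh.require_form("differential")
    tail = np.concatenate([np.cumsum(dvh.volume_fraction[::-1])[::-1], [0.0]])
    return replace(dvh, volume_fraction=tail, form="cumulative")


def to_differential(dvh: DoseVolumeHistogram) -> DoseVolumeHistogram:
    """Inverse of :func:`to_cumulative`; exact round-trip."""
    dvh.require_form("cumulative")
    frac = dvh.volume_fraction[:-1] - dvh.volume_fraction[1:]
    return replace(dvh, volume_fraction=frac, form="differential")


def dose_at_volume_fraction(dvh: DoseVolumeHistogram, x_percent: float) -> float:
    """``Dx%``: the minimum dose received by the hottest ``x`` % of the volume.

    On a differential DVH this is an exact order-statistic of the point-mass
    distribution; on a cumulative DVH the curve is interpolated linearly
    between edges. Where the curve is flat the highest dose attaining the
    requested fraction is returned.
    """
    if not 0 < x_percent <= 100:
        raise DomainError(f"x_percent must lie in (0, 100], got {x_percent}")
    q = x_percent / 100.0
    if dvh.form == "differential":
        tail = np.cumsum(dvh.volume_fraction[::-1])[::-1]  # fraction at >= each center
        ok = np.nonzero(tail >= q - 1e-12)[0]
        return float(dvh.bin_centers[ok[-1]])
    values = dvh.volume_fraction
    edges = dvh.bin_edges
    ok = np.nonzero(values >= q - 1e-12)[0]
    i = ok[-1]
    if i == values.size - 1 or values[i] <= q + 1e-12:
        return float(edges[i])
    # strictly above q at edge i, strictly below at edge i+1: interpolate
    frac = (values[i] - q) / (values[i] - values[i + 1])
    return float(edges[i] + frac * (edges[i + 1] - edges[i]))


def volume_at_dose_percent(dvh: DoseVolumeHistogram, reference_dose: float) -> float:
    """``V_RI``: percentage of the structure volume receiving at least
    ``reference_dose`` Gy."""
    if reference_dose < 0:
        raise DomainError(f"reference_dose must be >= 0, got {reference_dose}")
    if dvh.form == "differential":
        mask = dvh.bin_centers >= reference_dose - 1e-12
        return float(100.0 * dvh.volume_fraction[mask].sum())
    edges = dvh.bin_edges
    if reference_dose <= edges[0]:
        return 100.0
    if reference_dose >= edges[-1]:
        return float(100.0 * dvh.volume_fraction[-1]) if reference_dose == edges[-1] else 0.0
    return float(100.0 * np.interp(reference_dose, edges, dvh.volume_fraction))


def summary_stats(dvh: DoseVolumeHistogram) -> dict[str, float]:
    """``D_min``, ``D_max`` and the volume-weighted ``D_mean`` in Gy.

    Min and max are the lowest and highest bin-center doses carrying nonzero
    volume; no near-min/near-max smoothing is applied.
    """
    d = dvh if dvh.form == "differential" else to_differential(dvh)
    occupied = d.volume_fraction > 0
    if not occupied.any():
        raise ValidationError("DVH carries no volume")
    centers = d.bin_centers[occupied]
    weights = d.volume_fraction[occupied]
    return {
        "d_min": float(centers.min()),
        "d_max": float(centers.max()),
        "d_mean": float(np.sum(weights * centers) / weights.sum()),
    }
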