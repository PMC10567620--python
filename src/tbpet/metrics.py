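"""Sensitivity and cost figures of merit.

Slice sensitivity
    ``S_i = R_i * L_mean / (d * A_mean)`` in cps/kBq, where ``R_i`` is the
    coincidence rate of axial slice ``i`` (width ``d``), ``L_mean`` the
    source length and ``A_mean`` the source activity.  The normalisation
    makes ``S_i`` the sensitivity to the activity contained in the slice.

Total-body sensitivity
    ``S_TB = sum_i R_i / (A_body * N)`` over the ``N`` slices covering the
    183 cm body range; slices outside a short scanner are empty but still
    counted, and ``A_body`` is the activity within the body range.

Cost figure of merit
    ``TB-FOM = S_TB / relative cost``, normalised to a reference design.
    Relative cost weights photosensor-covered area and (material-weighted)
    scintillator volume half and half.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil
from typing import Optional, Union

import numpy as np
import pandas as pd

from .emission import SourceSpec
from .geometry import ScannerDesign, pm_covered_area, scintillator_volume

#: Axial length of the body range over which S_TB averages (cm).
BODY_RANGE = 183.0


@dataclass(frozen=True)
class Slicing:
    """Contiguous uniform axial slices.

    The default grid (1 cm slices, edges on half-integers from -125.5 to
    125.5 cm) covers the 250 cm line source and aligns exactly with the
    183 cm body range.
    """

    d: float = 1.0
    z_min: float = -125.5
    z_max: float = 125.5

    def __post_init__(self) -> None:
        if self.d <= 0:
            raise ValueError("slice width d must be positive")
        if self.z_max <= self.z_min:
            raise ValueError("z_max must exceed z_min")

    @property
    def n_slices(self) -> int:
        return int(round((self.z_max - self.z_min) / self.d))

    @property
    def edges(self) -> np.ndarray:
        return self.z_min + self.d * np.arange(self.n_slices + 1)

    @property
    def centers(self) -> np.ndarray:
        return self.z_min + self.d * (np.arange(self.n_slices) + 0.5)


@dataclass(frozen=True)
class SensitivityProfile:
    """Binned axial sensitivity profile."""

    slice_centers: np.ndarray
    d: float
    R_i: np.ndarray  # cps per slice
    S_i: np.ndarray  # cps/kBq per slice

    @property
    def n_slices(self) -> int:
        return self.slice_centers.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "slice_center_cm": self.slice_centers,
                "R_cps": self.R_i,
                "S_cps_per_kBq": self.S_i,
            }
        )


@dataclass(frozen=True)
class TbResult:
    """Total-body sensitivity and its bookkeeping."""

    S_TB: float  # cps/kBq
    A_body: float  # kBq
    N: int  # body-range slice count


@dataclass(frozen=True)
class FomResult:
    """Cost-normalised comparison for one design."""

    relative_cost: float
    tb_fom: float


def slice_rates(
    records: Union[pd.DataFrame, np.ndarray],
    duration: float,
    slicing: Slicing = Slicing(),
) -> pd.Series:
    """Coincidence rate per axial slice (cps), binned by true annihilation z.

    Returns a Series indexed by slice centre; counts outside the slicing
    range are dropped (total in-range counts are conserved).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    z = records["z_true"].to_numpy() if isinstance(records, pd.DataFrame) else np.asarray(records, float)
    counts, _ = np.histogram(z, bins=slicing.edges)
    return pd.Series(counts / duration, index=slicing.centers, name="R_cps")


def sensitivity_profile(
    rates: pd.Series, source: SourceSpec, slicing: Slicing = Slicing()
) -> SensitivityProfile:
    """Apply the slice-sensitivity normalisation to a rate table."""
    if source.A_mean <= 0:
        raise ValueError("source activity must be positive")
    R = rates.to_numpy(dtype=float)
    S = R * source.L_mean / (slicing.d * source.A_mean)
    return SensitivityProfile(rates.index.to_numpy(dtype=float), slicing.d, R, S)


def total_body_sensitivity(
    profile: SensitivityProfile,
    A_body: Optional[float] = None,
    source: Optional[SourceSpec] = None,
    body_range: float = BODY_RANGE,
    body_center: float = 0.0,
) -> TbResult:
    """Average body-range rate per unit body activity (cps/kBq).

    ``A_body`` defaults to the activity of the source segment inside the
    body range, ``A_mean * body_range / L_mean``.  Slices inside the body
    range but outside the scanner contribute zero rate yet still count in
    the ``N``-slice average.
    """
    if A_body is None:
        if source is None:
            raise ValueError("provide A_body or a source to derive it from")
        A_body = source.A_mean * min(1.0, body_range / source.L_mean)
    if A_body <= 0:
        raise ValueError("A_body must be positive")
    N = ceil(body_range / profile.d)
    half = body_range / 2.0
    sel = np.abs(profile.slice_centers - body_center) <= half - profile.d / 2.0 + 1e-9
    total_rate = float(profile.R_i[sel].sum())
    return TbResult(S_TB=total_rate / (A_body * N), A_body=A_body, N=N)


def relative_cost(design: ScannerDesign, reference: ScannerDesign) -> float:
    """System cost relative to a reference design.

    Half the system price is photosensors and electronics (proportional to
    the photosensor-covered area), half is scintillator (proportional to
    volume times the material cost weight).
    """
    ref_area = pm_covered_area(reference)
    ref_scint = (
        scintillator_volume(reference)
        * reference.material.relative_cost_per_volume
    )
    if ref_area <= 0 or ref_scint <= 0:
        raise ValueError("reference design has zero area or scintillator cost")
    area_ratio = pm_covered_area(design) / ref_area
    scint_ratio = (
        scintillator_volume(design) * design.material.relative_cost_per_volume
    ) / ref_scint
    return 0.5 * area_ratio + 0.5 * scint_ratio


def tb_fom(
    tb: TbResult,
    cost: float,
    reference_tb: TbResult,
    reference_cost: float = 1.0,
) -> FomResult:
    """Cost-normalised total-body figure of merit.

    ``S_TB / cost`` divided by the reference design's ``S_TB / cost`` so the
    reference scores exactly 1.
    """
    if cost <= 0 or reference_cost <= 0:
        raise ValueError("costs must be positive")
    if reference_tb.S_TB <= 0:
        raise ValueError("reference S_TB must be positive")
    ratio = (tb.S_TB / cost) / (reference_tb.S_TB / reference_cost)
    return FomResult(relative_cost=cost, tb_fom=ratio)
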