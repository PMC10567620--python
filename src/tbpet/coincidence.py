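"""True-coincidence formation and oblique-LOR suppression cuts.

Events whose two photons are both detected form one line of response
(LOR).  Very oblique LORs degrade axial resolution, so scanners discard
them: axially continuous (strip) detectors cut on the LOR angle from the
transaxial plane (acceptance angle, 57 degrees here), block tomographs cut
on the difference between the two axial detection-unit indices (the
"maximum 5 ring difference" for the uEXPLORER unit pitch).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import math

import numpy as np
import pandas as pd

from .emission import EventBatch
from .geometry import CrystalScannerSpec, ScannerDesign
from .transport import PhotonHits

#: Acceptance angle applied to strip scanners and used to derive the
#: equivalent ring-difference cut for crystal scanners (degrees).
DEFAULT_ACCEPTANCE_ANGLE = 57.0

COINCIDENCE_COLUMNS = [
    "event",
    "xA",
    "yA",
    "zA",
    "xB",
    "yB",
    "zB",
    "theta_deg",
    "unitA",
    "unitB",
    "z_true",
]


@dataclass(frozen=True)
class CutSpec:
    """Oblique-LOR cut: either an acceptance angle (strip family) or a
    maximum unit/ring difference (crystal family)."""

    theta_AA: Optional[float] = None
    max_ring_difference: Optional[int] = None

    def __post_init__(self) -> None:
        if self.theta_AA is not None and not 0 < self.theta_AA <= 90:
            raise ValueError("theta_AA must be in (0, 90]")
        if self.max_ring_difference is not None and self.max_ring_difference < 0:
            raise ValueError("max_ring_difference must be non-negative")


def default_ring_cut(
    design: ScannerDesign, theta_deg: float = DEFAULT_ACCEPTANCE_ANGLE
) -> int:
    """Ring-difference cut equivalent to an acceptance angle.

    The angle maps to a maximum axial span ``2R tan(theta)`` across the
    detector bore, expressed in the design's own unit pitch.  For the
    24.35 cm uEXPLORER unit this reproduces the canonical 5-ring cut.
    """
    spec = design.spec
    if not isinstance(spec, CrystalScannerSpec):
        raise TypeError("ring-difference cuts apply to radial-crystal designs")
    span = 2.0 * spec.ring_inner_radius * math.tan(math.radians(theta_deg))
    return int(round(span / spec.unit_pitch))


def default_cut(
    design: ScannerDesign, theta_deg: float = DEFAULT_ACCEPTANCE_ANGLE
) -> CutSpec:
    """The canonical oblique cut for a design: acceptance angle for strip
    scanners, the angle's ring-difference equivalent for crystal scanners."""
    if isinstance(design.spec, CrystalScannerSpec):
        return CutSpec(max_ring_difference=default_ring_cut(design, theta_deg))
    return CutSpec(theta_AA=theta_deg)


def build_coincidences(
    events: EventBatch,
    hits_A: PhotonHits,
    hits_B: PhotonHits,
    detected_A: np.ndarray,
    detected_B: np.ndarray,
) -> pd.DataFrame:
    """One record per event in which both photons were detected.

    The LOR angle ``theta_deg`` is measured from the transaxial plane
    (0 = perpendicular to the scanner axis) using the two detection points.
    """
    both = np.asarray(detected_A, bool) & np.asarray(detected_B, bool)
    idx = np.flatnonzero(both)
    eA = hits_A.entry[idx]
    eB = hits_B.entry[idx]
    dz = np.abs(eB[:, 2] - eA[:, 2])
    dt = np.hypot(eB[:, 0] - eA[:, 0], eB[:, 1] - eA[:, 1])
    theta = np.degrees(np.arctan2(dz, dt))
    return pd.DataFrame(
        {
            "event": idx,
            "xA": eA[:, 0],
            "yA": eA[:, 1],
            "zA": eA[:, 2],
            "xB": eB[:, 0],
            "yB": eB[:, 1],
            "zB": eB[:, 2],
            "theta_deg": theta,
            "unitA": hits_A.unit[idx],
            "unitB": hits_B.unit[idx],
            "z_true": events.z[idx],
        }
    )


def apply_angle_cut(records: pd.DataFrame, cut: CutSpec) -> pd.DataFrame:
    """Keep LORs with ``theta <= theta_AA`` (boundary inclusive)."""
    if cut.theta_AA is None:
        raise ValueError("cut spec has no theta_AA")
    return records[records["theta_deg"] <= cut.theta_AA].reset_index(drop=True)


def apply_ring_difference_cut(records: pd.DataFrame, cut: CutSpec) -> pd.DataFrame:
    """Keep LORs whose unit indices differ by at most the cut value."""
    if cut.max_ring_difference is None:
        raise ValueError("cut spec has no max_ring_difference")
    diff = (records["unitA"] - records["unitB"]).abs()
    return records[diff <= cut.max_ring_difference].reset_index(drop=True)


def apply_cut(records: pd.DataFrame, cut: Optional[CutSpec]) -> pd.DataFrame:
    """Apply whichever cut(s) the spec carries; no-op for ``None``."""
    if cut is None:
        return records
    out = records
    if cut.theta_AA is not None:
        out = apply_angle_cut(out, cut)
    if cut.max_ring_difference is not None:
        out = apply_ring_difference_cut(out, cut)
    return out
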