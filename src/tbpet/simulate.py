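"""End-to-end simulation pipeline.

``simulate`` runs emission -> transport -> coincidence formation for one
design and one source setup under a single master seed; ``profile_for`` and
``summarize`` turn the coincidence list into the sensitivity profile and
the design-comparison record.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import coincidence as coin
from . import metrics, transport
from .coincidence import CutSpec
from .emission import EventBatch, PhantomSpec, SourceSpec, duration_for, sample_events
from .geometry import ScannerDesign, pm_covered_area, scintillator_volume
from .library import REFERENCE_DESIGN, build_design
from .metrics import SensitivityProfile, Slicing

DEFAULT_EVENTS = 2_000_000


@dataclass
class SimulationResult:
    """Uncut coincidence list plus everything needed to normalise it."""

    design: ScannerDesign
    source: SourceSpec
    phantom: Optional[PhantomSpec]
    n_events: int
    seed: int
    duration: float
    coincidences: pd.DataFrame

    @property
    def n_coincidences(self) -> int:
        return len(self.coincidences)


def transport_pair(
    design: ScannerDesign,
    events: EventBatch,
    phantom: Optional[PhantomSpec],
    rng_A: np.random.Generator,
    rng_B: np.random.Generator,
):
    """Propagate both photons of every event; returns hits and detection
    flags for photon A and B."""
    acceptance = transport.detection_acceptance(design)
    out = []
    for which, rng in (("A", rng_A), ("B", rng_B)):
        hits = transport.detector_intersection(design, events, which)
        path_w = transport.water_path(events, phantom, which)
        mu_w = phantom.mu_water if phantom is not None else 0.0
        survival = transport.survival_probability(path_w, mu_w)
        detected, _ = transport.detect(
            hits, design.material, survival, acceptance, rng
        )
        out.append((hits, detected))
    return out[0], out[1]


def simulate(
    design,
    n_events: int = DEFAULT_EVENTS,
    seed: int = 0,
    source: Optional[SourceSpec] = None,
    phantom: Optional[PhantomSpec] = None,
) -> SimulationResult:
    """Simulate one design under one source setup.

    ``design`` is a :class:`ScannerDesign` or a bundled design name.  The
    master seed deterministically derives independent streams for emission
    and the two photons' detection draws.
    """
    if isinstance(design, str):
        design = build_design(design)
    if source is None:
        source = SourceSpec()
    if n_events <= 0:
        raise ValueError("n_events must be positive")
    ss = np.random.SeedSequence(seed)
    s_emit, s_a, s_b = ss.spawn(3)
    events = sample_events(source, n_events, np.random.default_rng(s_emit))
    (hits_A, det_A), (hits_B, det_B) = transport_pair(
        design, events, phantom, np.random.default_rng(s_a), np.random.default_rng(s_b)
    )
    records = coin.build_coincidences(events, hits_A, hits_B, det_A, det_B)
    return SimulationResult(
        design=design,
        source=source,
        phantom=phantom,
        n_events=n_events,
        seed=seed,
        duration=duration_for(n_events, source),
        coincidences=records,
    )


def profile_for(
    result: SimulationResult,
    cut: Optional[CutSpec] = None,
    slicing: Slicing = Slicing(),
) -> SensitivityProfile:
    """Sensitivity profile of a simulation, after an optional oblique cut."""
    records = coin.apply_cut(result.coincidences, cut)
    rates = metrics.slice_rates(records, result.duration, slicing)
    return metrics.sensitivity_profile(rates, result.source, slicing)


def summarize(
    result: SimulationResult,
    cut: Optional[CutSpec] = None,
    slicing: Slicing = Slicing(),
    reference: Optional[ScannerDesign] = None,
    reference_tb: Optional[metrics.TbResult] = None,
) -> dict:
    """Design-comparison record: S_TB, covered area, relative cost, TB-FOM.

    TB-FOM is only reported when both the reference design and its
    total-body sensitivity (same setup and cut) are supplied.
    """
    profile = profile_for(result, cut, slicing)
    tb = metrics.total_body_sensitivity(profile, source=result.source)
    record = {
        "design": result.design.name,
        "family": result.design.family,
        "material": result.design.material.name,
        "afov_cm": round(result.design.afov, 4),
        "n_events": result.n_events,
        "seed": result.seed,
        "phantom": result.phantom is not None,
        "cut": _cut_label(cut),
        "n_coincidences": int(len(coin.apply_cut(result.coincidences, cut))),
        "peak_S_cps_per_kBq": float(np.max(profile.S_i)) if profile.n_slices else 0.0,
        "S_TB_cps_per_kBq": tb.S_TB,
        "pm_covered_area_cm2": pm_covered_area(result.design),
        "scintillator_volume_cm3": scintillator_volume(result.design),
    }
    if reference is not None:
        cost = metrics.relative_cost(result.design, reference)
        record["relative_cost"] = cost
        if reference_tb is not None:
            record["tb_fom"] = metrics.tb_fom(tb, cost, reference_tb).tb_fom
    return record


def _cut_label(cut: Optional[CutSpec]) -> str:
    if cut is None:
        return "none"
    parts = []
    if cut.theta_AA is not None:
        parts.append(f"theta<={cut.theta_AA:g}deg")
    if cut.max_ring_difference is not None:
        parts.append(f"ring-diff<={cut.max_ring_difference}")
    return ",".join(parts)


def reference_design() -> ScannerDesign:
    """The cost/FOM normalisation reference (full 194.8 cm LYSO uEXPLORER)."""
    return build_design(REFERENCE_DESIGN)
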