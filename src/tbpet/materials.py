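"""Scintillator and phantom materials.

Linear attenuation coefficients are total coefficients at 511 keV; cost
weights are scintillator prices per unit volume relative to LYSO.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Total linear attenuation coefficient of water at 511 keV (1/cm).
MU_WATER_511 = 0.096

#: Fraction of interacting annihilation photons accepted by the (implicit)
#: photopeak energy window of crystal detectors.  Calibrated once against the
#: published central-slice sensitivity of the reference full-BGO 194.8 cm
#: scanner and then frozen; applied identically to every crystal design.
PHOTOPEAK_EFFICIENCY = 0.824

#: Energy-loss threshold applied to Compton interactions in plastic strips (keV).
PLASTIC_THRESHOLD_KEV = 200.0


@dataclass(frozen=True)
class Material:
    """A detector (or phantom) material.

    Parameters
    ----------
    name
        Label, e.g. ``"BGO"``.
    mu_511
        Total linear attenuation coefficient at 511 keV in 1/cm.
    relative_cost_per_volume
        Price per unit scintillator volume relative to LYSO (= 1.0).
    """

    name: str
    mu_511: float
    relative_cost_per_volume: float

    def __post_init__(self) -> None:
        if self.mu_511 <= 0:
            raise ValueError(f"mu_511 must be positive, got {self.mu_511}")
        if self.relative_cost_per_volume < 0:
            raise ValueError("relative_cost_per_volume must be non-negative")


# BGO is quoted at 2-3x cheaper than LYSO per volume; 0.4 is the midpoint.
MATERIALS: dict[str, Material] = {
    "BGO": Material("BGO", 0.955, 0.4),
    "LYSO": Material("LYSO", 0.87, 1.0),
    "LSO": Material("LSO", 0.87, 1.0),
    "plastic": Material("plastic", 0.098, 0.02),
}


def get_material(name: str) -> Material:
    """Look up a bundled material by (case-insensitive) name."""
    key = name.upper() if name.upper() in MATERIALS else name.lower()
    try:
        return MATERIALS[key]
    except KeyError:
        raise KeyError(
            f"unknown material {name!r}; bundled: {sorted(MATERIALS)}"
        ) from None
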