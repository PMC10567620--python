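"""Parametric scanner geometries.

Two detector families are modelled:

* ``radial-crystal`` — conventional block tomographs (uEXPLORER, Biograph
  Vision): axial *units* ("rings") of crystal blocks arranged on a cylinder,
  crystals pointing radially inward.
* ``axial-strip`` — J-PET style scanners: long plastic scintillator strips
  laid parallel to the scanner axis in one or more concentric layers, read
  out at both ends, with wavelength-shifting (WLS) strips for axial
  localisation.

All lengths are centimetres; areas cm^2; volumes cm^3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np

from .materials import Material, PHOTOPEAK_EFFICIENCY, PLASTIC_THRESHOLD_KEV

# WLS piece: 3 mm (axial) x 108.15 mm (azimuthal) x 6 mm (radial); the SiPM
# readout face is the 3 x 6 mm end.
WLS_AXIAL_PITCH = 0.3
WLS_AZIMUTHAL_LENGTH = 10.815
WLS_READOUT_AREA = 0.3 * 0.6

RADIAL_CRYSTAL = "radial-crystal"
AXIAL_STRIP = "axial-strip"


@dataclass(frozen=True)
class CrystalScannerSpec:
    """Block/crystal tomograph: ``n_units`` axial rings of crystal blocks."""

    n_units: int
    unit_axial_length: float
    inter_unit_gap: float
    n_blocks_per_ring: int
    crystals_per_block_transaxial: int
    crystals_per_block_axial: int
    crystal_transaxial: float
    crystal_axial: float
    crystal_depth: float
    ring_inner_radius: float
    material: Material
    occupancy: Optional[np.ndarray] = None  # bool (n_units, n_blocks_per_ring)
    packing_fraction: float = 0.85
    photopeak_efficiency: float = PHOTOPEAK_EFFICIENCY

    def __post_init__(self) -> None:
        if self.n_units <= 0:
            raise ValueError("n_units must be positive")
        for name in (
            "unit_axial_length",
            "n_blocks_per_ring",
            "crystals_per_block_transaxial",
            "crystals_per_block_axial",
            "crystal_transaxial",
            "crystal_axial",
            "crystal_depth",
            "ring_inner_radius",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.inter_unit_gap < 0:
            raise ValueError("inter_unit_gap must be non-negative")
        if not 0 < self.packing_fraction <= 1:
            raise ValueError("packing_fraction must be in (0, 1]")
        if self.occupancy is not None:
            occ = np.asarray(self.occupancy, dtype=bool)
            if occ.shape != (self.n_units, self.n_blocks_per_ring):
                raise ValueError(
                    "occupancy mask shape "
                    f"{occ.shape} != {(self.n_units, self.n_blocks_per_ring)}"
                )
            object.__setattr__(self, "occupancy", occ)

    # -- derived geometry ---------------------------------------------------

    @property
    def axial_extent(self) -> float:
        return (
            self.n_units * self.unit_axial_length
            + (self.n_units - 1) * self.inter_unit_gap
        )

    @property
    def unit_pitch(self) -> float:
        return self.unit_axial_length + self.inter_unit_gap

    @property
    def unit_fill(self) -> np.ndarray:
        """Per-unit occupancy fill fraction (1.0 everywhere when unmasked)."""
        if self.occupancy is None:
            return np.ones(self.n_units)
        return self.occupancy.mean(axis=1)

    @property
    def fill_factor(self) -> float:
        return float(self.unit_fill.mean())

    @property
    def crystals_per_block(self) -> int:
        return self.crystals_per_block_transaxial * self.crystals_per_block_axial

    @property
    def n_crystals(self) -> int:
        if self.occupancy is None:
            n_blocks = self.n_units * self.n_blocks_per_ring
        else:
            n_blocks = int(self.occupancy.sum())
        return n_blocks * self.crystals_per_block


@dataclass(frozen=True)
class StripScannerSpec:
    """J-PET style scanner: axial plastic strips in concentric layers."""

    n_layers: int
    strip_length: float
    strip_width: float  # transaxial (azimuthal)
    strip_thickness: float  # radial
    layer_radii: tuple[float, ...]  # inner radius of each layer
    n_strips_per_layer: tuple[int, ...]
    material: Material
    wls_unit_area: float = WLS_READOUT_AREA
    n_wls_readouts: int = 0
    azimuthal_fill: float = 0.98
    energy_threshold_keV: float = PLASTIC_THRESHOLD_KEV

    def __post_init__(self) -> None:
        if self.n_layers not in (1, 2, 3, 4):
            raise ValueError("n_layers must be between 1 and 4")
        for name in ("strip_length", "strip_width", "strip_thickness"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if len(self.layer_radii) != self.n_layers:
            raise ValueError("layer_radii must have one entry per layer")
        if len(self.n_strips_per_layer) != self.n_layers:
            raise ValueError("n_strips_per_layer must have one entry per layer")
        radii = self.layer_radii
        if any(r2 <= r1 for r1, r2 in zip(radii, radii[1:])):
            raise ValueError("layer radii must be strictly increasing")
        if radii[0] <= 0:
            raise ValueError("layer radii must be positive")
        if not 0 < self.azimuthal_fill <= 1:
            raise ValueError("azimuthal_fill must be in (0, 1]")
        if not 0 <= self.energy_threshold_keV <= 511:
            raise ValueError("energy_threshold_keV must be in [0, 511]")

    @property
    def axial_extent(self) -> float:
        return self.strip_length

    @property
    def n_strips(self) -> int:
        return int(sum(self.n_strips_per_layer))


Spec = Union[CrystalScannerSpec, StripScannerSpec]


@dataclass(frozen=True)
class ScannerDesign:
    """A complete tomograph: family tag, parametric spec, derived AFOV."""

    name: str
    family: str
    spec: Spec
    afov: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.family not in (RADIAL_CRYSTAL, AXIAL_STRIP):
            raise ValueError(f"unknown family {self.family!r}")
        expected = RADIAL_CRYSTAL if isinstance(self.spec, CrystalScannerSpec) else AXIAL_STRIP
        if self.family != expected:
            raise ValueError(f"family {self.family!r} does not match spec type")
        if self.afov == 0.0:
            object.__setattr__(self, "afov", self.spec.axial_extent)
        if self.afov <= 0:
            raise ValueError("afov must be positive")

    @property
    def material(self) -> Material:
        return self.spec.material

    @property
    def inner_radius(self) -> float:
        if isinstance(self.spec, CrystalScannerSpec):
            return self.spec.ring_inner_radius
        return self.spec.layer_radii[0]


# ---------------------------------------------------------------------------
# design-level quantities
# ---------------------------------------------------------------------------


def axial_extent(design: ScannerDesign) -> float:
    """Total axial span of the detector, inter-unit gaps included (cm)."""
    return design.spec.axial_extent


def pm_covered_area(design: ScannerDesign) -> float:
    """Total photosensor-covered area (cm^2).

    Radial-crystal family: the sum of inward crystal faces
    (transaxial x axial) over all present crystals — each crystal column is
    backed by SiPM area of its own footprint.  Axial-strip family: two end
    faces (width x thickness) per strip, plus one SiPM face per WLS readout.
    """
    spec = design.spec
    if isinstance(spec, CrystalScannerSpec):
        return spec.n_crystals * spec.crystal_transaxial * spec.crystal_axial
    strip_faces = spec.n_strips * 2.0 * spec.strip_width * spec.strip_thickness
    return strip_faces + spec.n_wls_readouts * spec.wls_unit_area


def scintillator_volume(design: ScannerDesign) -> float:
    """Total scintillator volume of present elements (cm^3)."""
    spec = design.spec
    if isinstance(spec, CrystalScannerSpec):
        crystal = spec.crystal_transaxial * spec.crystal_axial * spec.crystal_depth
        return spec.n_crystals * crystal
    strip = spec.strip_width * spec.strip_thickness * spec.strip_length
    return spec.n_strips * strip


def sparsify(design: ScannerDesign, pattern: Sequence) -> ScannerDesign:
    """Return a copy of a radial-crystal design with blocks masked out.

    ``pattern`` is a boolean occupancy mask of shape (n_units, n_blocks);
    ``True`` keeps a block.  An existing mask is AND-combined.
    """
    if not isinstance(design.spec, CrystalScannerSpec):
        raise TypeError("sparsify applies to radial-crystal designs only")
    spec = design.spec
    mask = np.asarray(pattern, dtype=bool)
    if mask.shape != (spec.n_units, spec.n_blocks_per_ring):
        raise ValueError(
            f"mask shape {mask.shape} != "
            f"{(spec.n_units, spec.n_blocks_per_ring)}"
        )
    if spec.occupancy is not None:
        mask = mask & spec.occupancy
    new_spec = replace(spec, occupancy=mask)
    return ScannerDesign(design.name, design.family, new_spec, design.afov)


def design_summary(design: ScannerDesign) -> dict:
    """JSON-ready record of the design-level quantities."""
    return {
        "name": design.name,
        "family": design.family,
        "material": design.material.name,
        "afov_cm": round(design.afov, 4),
        "pm_covered_area_cm2": round(pm_covered_area(design), 2),
        "scintillator_volume_cm3": round(scintillator_volume(design), 2),
    }


# ---------------------------------------------------------------------------
# transport support
# ---------------------------------------------------------------------------


def material_profile(spec: CrystalScannerSpec) -> tuple[np.ndarray, np.ndarray]:
    """Knots for the cumulative axial scintillator-material function.

    Returns ``(z, C)`` such that ``np.interp(z0, z, C)`` is the amount of
    active axial material between the upstream detector edge and ``z0``,
    weighting each unit by its occupancy fill fraction.  Used to convert a
    geometric chord through the detector shell into a chord through actual
    scintillator for designs with axial gaps or sparse units.
    """
    z0 = -spec.axial_extent / 2.0
    fill = spec.unit_fill
    knots = [z0 - 1.0]
    cum = [0.0]
    c = 0.0
    for j in range(spec.n_units):
        start = z0 + j * spec.unit_pitch
        end = start + spec.unit_axial_length
        knots.append(start)
        cum.append(c)
        c += fill[j] * spec.unit_axial_length
        knots.append(end)
        cum.append(c)
    knots.append(-z0 + 1.0)
    cum.append(c)
    return np.asarray(knots), np.asarray(cum)


def layer_radii_for(
    innermost_radius: float, n_layers: int, strip_thickness: float, layer_gap: float
) -> tuple[float, ...]:
    """Concentric layer inner radii: thickness plus a clearance per step."""
    step = strip_thickness + layer_gap
    return tuple(innermost_radius + k * step for k in range(n_layers))


def strips_per_layer(radius: float, strip_width: float) -> int:
    """Strips that tile a layer circumference (floor: no overlap)."""
    return int(math.floor(2.0 * math.pi * radius / strip_width))


def wls_readout_count(
    layer_radii: Sequence[float], strip_length: float
) -> int:
    """WLS pieces tiling one plane per layer at 3 mm axial pitch."""
    n = 0
    for r in layer_radii:
        n_phi = int(math.floor(2.0 * math.pi * r / WLS_AZIMUTHAL_LENGTH))
        n_z = int(math.floor(strip_length / WLS_AXIAL_PITCH))
        n += n_phi * n_z
    return n
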