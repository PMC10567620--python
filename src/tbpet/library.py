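"""Bundled scanner design library.

Seventeen parametric designs ship with the package as YAML files under
``tbpet/designs``: eight uEXPLORER-style crystal tomographs (BGO/LYSO x
194.8/97.4 cm AFOV x full/sparse), eight J-PET-style plastic-strip
tomographs (4x20 mm strips with 2 layers, 6x30 mm strips with 2/3/4
layers, each at 200 and 250 cm), and the Siemens Biograph Vision.
"""

from __future__ import annotations

from importlib import resources
from typing import Mapping, Union

import numpy as np
import yaml

from . import geometry
from .geometry import (
    AXIAL_STRIP,
    RADIAL_CRYSTAL,
    CrystalScannerSpec,
    ScannerDesign,
    StripScannerSpec,
)
from .materials import get_material

#: Tolerance (cm) between a bundled design's derived axial extent and its
#: catalogued AFOV.
AFOV_TOLERANCE = 0.05

#: Reference design for cost and TB-FOM normalisation.
REFERENCE_DESIGN = "uexplorer_full_lyso_194"


def _design_dir():
    return resources.files("tbpet") / "designs"


def list_designs() -> list[str]:
    """Names of all bundled designs, sorted."""
    return sorted(p.name[: -len(".yaml")] for p in _design_dir().iterdir()
                  if p.name.endswith(".yaml"))


def load_config(name: str) -> dict:
    """Raw configuration mapping of a bundled design."""
    path = _design_dir() / f"{name}.yaml"
    try:
        text = path.read_text()
    except FileNotFoundError:
        raise KeyError(
            f"unknown design {name!r}; bundled designs: {list_designs()}"
        ) from None
    return yaml.safe_load(text)


def _occupancy_from(config_value, n_units: int, n_blocks: int) -> np.ndarray:
    """Build a (units x blocks) mask from the config's sparse description."""
    if config_value == "alternate":
        # even units active, odd units empty
        rows = (np.arange(n_units) % 2) == 0
        return np.repeat(rows[:, None], n_blocks, axis=1)
    mask = np.asarray(config_value, dtype=bool)
    if mask.ndim == 1:  # per-unit flags
        mask = np.repeat(mask[:, None], n_blocks, axis=1)
    return mask


def _build_crystal(cfg: Mapping) -> CrystalScannerSpec:
    n_units = int(cfg["n_units"])
    n_blocks = int(cfg["n_blocks_per_ring"])
    occupancy = None
    if "sparse_units" in cfg:
        occupancy = _occupancy_from(cfg["sparse_units"], n_units, n_blocks)
    kwargs = {}
    for opt in ("packing_fraction", "photopeak_efficiency"):
        if opt in cfg:
            kwargs[opt] = float(cfg[opt])
    return CrystalScannerSpec(
        n_units=n_units,
        unit_axial_length=float(cfg["unit_axial_length_cm"]),
        inter_unit_gap=float(cfg["inter_unit_gap_cm"]),
        n_blocks_per_ring=n_blocks,
        crystals_per_block_transaxial=int(cfg["crystals_per_block_transaxial"]),
        crystals_per_block_axial=int(cfg["crystals_per_block_axial"]),
        crystal_transaxial=float(cfg["crystal_transaxial_cm"]),
        crystal_axial=float(cfg["crystal_axial_cm"]),
        crystal_depth=float(cfg["crystal_depth_cm"]),
        ring_inner_radius=float(cfg["ring_inner_radius_cm"]),
        material=get_material(cfg["material"]),
        occupancy=occupancy,
        **kwargs,
    )


def _build_strip(cfg: Mapping) -> StripScannerSpec:
    n_layers = int(cfg["n_layers"])
    thickness = float(cfg["strip_thickness_cm"])
    width = float(cfg["strip_width_cm"])
    length = float(cfg["strip_length_cm"])
    if "layer_radii_cm" in cfg:
        radii = tuple(float(r) for r in cfg["layer_radii_cm"])
    else:
        radii = geometry.layer_radii_for(
            float(cfg["innermost_radius_cm"]),
            n_layers,
            thickness,
            float(cfg.get("layer_gap_cm", 0.5)),
        )
    n_strips = tuple(geometry.strips_per_layer(r, width) for r in radii)
    n_wls = geometry.wls_readout_count(radii, length) if cfg.get("wls", True) else 0
    kwargs = {}
    for opt_cfg, opt in (
        ("azimuthal_fill", "azimuthal_fill"),
        ("energy_threshold_keV", "energy_threshold_keV"),
    ):
        if opt_cfg in cfg:
            kwargs[opt] = float(cfg[opt_cfg])
    return StripScannerSpec(
        n_layers=n_layers,
        strip_length=length,
        strip_width=width,
        strip_thickness=thickness,
        layer_radii=radii,
        n_strips_per_layer=n_strips,
        material=get_material(cfg["material"]),
        n_wls_readouts=n_wls,
        **kwargs,
    )


def build_design(config: Union[str, Mapping]) -> ScannerDesign:
    """Build and validate a scanner design.

    ``config`` is either the name of a bundled design or a complete
    configuration mapping following the bundled YAML schema.  A bundled
    (or catalogued) design's derived axial extent must reproduce its
    ``catalog_afov_cm`` to within 0.05 cm.
    """
    if isinstance(config, str):
        config = load_config(config)
    family = config["family"]
    if family == RADIAL_CRYSTAL:
        spec = _build_crystal(config["crystal"])
    elif family == AXIAL_STRIP:
        spec = _build_strip(config["strip"])
    else:
        raise ValueError(f"unknown scanner family {family!r}")
    design = ScannerDesign(config["name"], family, spec)
    catalog = config.get("catalog_afov_cm")
    if catalog is not None and abs(design.afov - float(catalog)) > AFOV_TOLERANCE:
        raise ValueError(
            f"design {design.name!r}: derived axial extent {design.afov:.3f} cm "
            f"does not match catalogued AFOV {catalog} cm"
        )
    return design
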