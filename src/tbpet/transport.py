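"""Analytical 511 keV photon transport.

Each photon of a back-to-back pair is propagated as a straight ray:

1. the path length through the water phantom (exact ray/cylinder and
   ray/slab intersection) gives an exponential survival probability;
2. the intersection with the detector shells gives the chord through
   scintillator material (axial gaps and sparse units reduce it);
3. the chord is converted to an interaction probability
   ``1 - exp(-mu * chord)``;
4. a family-specific acceptance factor (photopeak window for crystals,
   Klein-Nishina energy-loss threshold for plastic strips, and the
   azimuthal packing fraction for both) multiplies in;
5. a Bernoulli draw decides detection.

A photon attenuated in water is lost, never redirected: the pipeline
scores true unscattered coincidences only.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

import numpy as np
from scipy import integrate

from .emission import EventBatch, PhantomSpec
from .geometry import (
    CrystalScannerSpec,
    ScannerDesign,
    StripScannerSpec,
    material_profile,
)
from .materials import Material

ELECTRON_MASS_KEV = 510.99895


@dataclass
class PhotonHits:
    """Vectorised outcome of :func:`detector_intersection` for one photon
    (A or B) of every event in a batch.

    ``unit``/``block`` index the axial detection unit and transaxial block
    for radial-crystal designs; ``layer`` indexes the first crossed layer
    for axial-strip designs.  Indices are -1 where not applicable or on a
    miss.  ``chord`` is the path through scintillator material in cm.
    """

    hit: np.ndarray
    chord: np.ndarray
    entry: np.ndarray
    polar_deg: np.ndarray
    unit: np.ndarray
    block: np.ndarray
    layer: np.ndarray

    def __len__(self) -> int:
        return self.hit.shape[0]


def _directions(events: EventBatch, which_photon: str) -> np.ndarray:
    if which_photon == "A":
        return events.directions
    if which_photon == "B":
        return -events.directions
    raise ValueError("which_photon must be 'A' or 'B'")


# ---------------------------------------------------------------------------
# water phantom
# ---------------------------------------------------------------------------


def water_path(
    events: EventBatch, phantom: Optional[PhantomSpec], which_photon: str = "A"
) -> np.ndarray:
    """Length of each photon ray inside the phantom cylinder (cm).

    Exact intersection of the forward ray with the finite cylinder
    (radius x axial slab); zero when no phantom is configured.
    """
    n = len(events)
    if phantom is None:
        return np.zeros(n)
    p = events.positions
    u = _directions(events, which_photon)
    R = phantom.radius
    zc = phantom.axial_center
    half = phantom.length / 2.0

    # radial interval [tr0, tr1] where x^2+y^2 <= R^2
    a = u[:, 0] ** 2 + u[:, 1] ** 2
    b = 2.0 * (p[:, 0] * u[:, 0] + p[:, 1] * u[:, 1])
    c = p[:, 0] ** 2 + p[:, 1] ** 2 - R * R
    tr0 = np.full(n, -np.inf)
    tr1 = np.full(n, np.inf)
    radial = a > 0.0
    disc = b * b - 4.0 * a * c
    cross = radial & (disc > 0.0)
    sq = np.sqrt(np.where(cross, disc, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tr0 = np.where(cross, (-b - sq) / (2.0 * a), tr0)
        tr1 = np.where(cross, (-b + sq) / (2.0 * a), tr1)
    # purely axial ray: inside forever iff already inside radially
    tr1 = np.where(~radial & (c > 0.0), -np.inf, tr1)
    tr0 = np.where(radial & (disc <= 0.0), np.inf, tr0)

    # axial interval where |z - zc| <= half
    uz = u[:, 2]
    dz0 = (zc - half) - p[:, 2]
    dz1 = (zc + half) - p[:, 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        ta = dz0 / uz
        tb = dz1 / uz
    tz0 = np.where(uz != 0.0, np.minimum(ta, tb), -np.inf)
    tz1 = np.where(uz != 0.0, np.maximum(ta, tb), np.inf)
    inside_ax = np.abs(p[:, 2] - zc) <= half
    tz0 = np.where(uz == 0.0, np.where(inside_ax, -np.inf, np.inf), tz0)
    tz1 = np.where(uz == 0.0, np.where(inside_ax, np.inf, -np.inf), tz1)

    lo = np.maximum(np.maximum(tr0, tz0), 0.0)
    hi = np.minimum(tr1, tz1)
    return np.maximum(hi - lo, 0.0)


def survival_probability(path, mu: float):
    """Probability of traversing ``path`` cm of material unscattered."""
    path = np.asarray(path, dtype=float)
    if np.any(path < 0):
        raise ValueError("path must be non-negative")
    if mu < 0:
        raise ValueError("mu must be non-negative")
    out = np.exp(-mu * path)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# detector intersection
# ---------------------------------------------------------------------------


def _outward_crossing(p: np.ndarray, u: np.ndarray, radius: float) -> np.ndarray:
    """First t > 0 with transaxial radius == ``radius``.

    Assumes the ray starts inside that radius (emission on/near the axis);
    +inf for purely axial rays, which never reach the shell.
    """
    a = u[:, 0] ** 2 + u[:, 1] ** 2
    b = 2.0 * (p[:, 0] * u[:, 0] + p[:, 1] * u[:, 1])
    c = p[:, 0] ** 2 + p[:, 1] ** 2 - radius * radius
    t = np.full(p.shape[0], np.inf)
    ok = a > 0.0
    disc = b * b - 4.0 * a * c
    good = ok & (disc >= 0.0)
    sq = np.sqrt(np.where(good, disc, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(good, (-b + sq) / (2.0 * a), t)
    return t


def _polar_deg(u: np.ndarray) -> np.ndarray:
    return np.degrees(np.arctan2(np.abs(u[:, 2]), np.hypot(u[:, 0], u[:, 1])))


def _intersect_crystal(
    spec: CrystalScannerSpec, p: np.ndarray, u: np.ndarray
) -> PhotonHits:
    n = p.shape[0]
    R = spec.ring_inner_radius
    t_in = _outward_crossing(p, u, R)
    t_out = _outward_crossing(p, u, R + spec.crystal_depth)
    reaches = np.isfinite(t_in)
    t_in = np.where(reaches, t_in, 0.0)
    t_out = np.where(reaches, t_out, 0.0)

    e = p + t_in[:, None] * u
    z1 = e[:, 2]
    z2 = p[:, 2] + t_out * u[:, 2]

    z_min = -spec.axial_extent / 2.0
    rel = z1 - z_min
    j = np.floor_divide(rel, spec.unit_pitch).astype(int)
    in_afov = reaches & (j >= 0) & (j < spec.n_units)
    jc = np.clip(j, 0, spec.n_units - 1)
    # within the unit's crystal span (half-open; grazing the far edge misses)
    frac_in_unit = rel - jc * spec.unit_pitch
    in_unit = in_afov & (frac_in_unit < spec.unit_axial_length)

    phi = np.mod(np.arctan2(e[:, 1], e[:, 0]), 2.0 * np.pi)
    block = np.minimum(
        (phi / (2.0 * np.pi / spec.n_blocks_per_ring)).astype(int),
        spec.n_blocks_per_ring - 1,
    )
    if spec.occupancy is not None:
        active = in_unit & spec.occupancy[jc, block]
    else:
        active = in_unit

    # chord through scintillator: geometric shell chord scaled by the
    # fraction of its axial span overlapping active units
    chord_geo = np.where(reaches, t_out - t_in, 0.0)
    zlo = np.minimum(z1, z2)
    zhi = np.maximum(z1, z2)
    knots, cum = material_profile(spec)
    span = zhi - zlo
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(
            span > 0.0,
            (np.interp(zhi, knots, cum) - np.interp(zlo, knots, cum)) / span,
            1.0,
        )
    chord = np.where(active, chord_geo * frac, 0.0)
    hit = active & (chord > 0.0)

    return PhotonHits(
        hit=hit,
        chord=chord,
        entry=np.where(hit[:, None], e, np.nan),
        polar_deg=_polar_deg(u),
        unit=np.where(hit, jc, -1),
        block=np.where(hit, block, -1),
        layer=np.full(n, -1),
    )


def _intersect_strip(
    spec: StripScannerSpec, p: np.ndarray, u: np.ndarray
) -> PhotonHits:
    n = p.shape[0]
    half = spec.strip_length / 2.0
    chord = np.zeros(n)
    first_layer = np.full(n, -1)
    entry = np.full((n, 3), np.nan)
    have_entry = np.zeros(n, dtype=bool)

    for k, r in enumerate(spec.layer_radii):
        t1 = _outward_crossing(p, u, r)
        t2 = _outward_crossing(p, u, r + spec.strip_thickness)
        reaches = np.isfinite(t1)
        t1 = np.where(reaches, t1, 0.0)
        t2 = np.where(reaches, t2, 0.0)
        z1 = p[:, 2] + t1 * u[:, 2]
        z2 = p[:, 2] + t2 * u[:, 2]
        zlo = np.minimum(z1, z2)
        zhi = np.maximum(z1, z2)
        overlap = np.maximum(
            np.minimum(zhi, half) - np.maximum(zlo, -half), 0.0
        )
        span = zhi - zlo
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(span > 0.0, overlap / span, (np.abs(z1) < half) * 1.0)
        chord_k = np.where(reaches, (t2 - t1) * frac, 0.0)
        crossed = chord_k > 0.0
        chord += chord_k

        newly = crossed & ~have_entry
        if np.any(newly):
            # entry where the ray first has scintillator alongside it: clamp
            # the shell entry to the strip's axial range
            zc = np.clip(z1, -half, half)
            with np.errstate(divide="ignore", invalid="ignore"):
                s = np.where(z2 != z1, (zc - z1) / (z2 - z1), 0.0)
            te = t1 + np.clip(s, 0.0, 1.0) * (t2 - t1)
            pts = p + te[:, None] * u
            entry[newly] = pts[newly]
            first_layer[newly] = k
            have_entry |= newly

    hit = chord > 0.0
    return PhotonHits(
        hit=hit,
        chord=chord,
        entry=entry,
        polar_deg=_polar_deg(u),
        unit=np.full(n, -1),
        block=np.full(n, -1),
        layer=first_layer,
    )


def detector_intersection(
    design: ScannerDesign, events: EventBatch, which_photon: str = "A"
) -> PhotonHits:
    """Intersect each photon ray with the detector and accumulate the chord
    through scintillator material.

    A ray that exits axially before reaching any element — or that enters the
    detector shell inside an axial gap or a masked-off block — is a miss.
    """
    p = events.positions
    u = _directions(events, which_photon)
    if isinstance(design.spec, CrystalScannerSpec):
        return _intersect_crystal(design.spec, p, u)
    return _intersect_strip(design.spec, p, u)


# ---------------------------------------------------------------------------
# interaction physics
# ---------------------------------------------------------------------------


def interaction_probability(path, material: Material):
    """Probability of at least one interaction along ``path`` cm."""
    path = np.asarray(path, dtype=float)
    if np.any(path < 0):
        raise ValueError("path must be non-negative")
    out = 1.0 - np.exp(-material.mu_511 * path)
    return out if out.ndim else float(out)


def _kn_weight(eps: float, alpha: float) -> float:
    """Klein-Nishina cross-section density over the scattered-photon energy
    fraction ``eps`` (flat factors dropped)."""
    cos_t = 1.0 - (1.0 / eps - 1.0) / alpha
    sin2 = 1.0 - cos_t * cos_t
    return eps + 1.0 / eps - sin2


@lru_cache(maxsize=None)
def compton_accept_fraction(
    threshold_keV: float, incident_keV: float = 511.0
) -> float:
    """Fraction of single Compton scatters depositing more than the threshold.

    Integrates the Klein-Nishina differential cross-section over the
    scattered-photon energy fraction.  Equals 1 at zero threshold and 0 at
    and beyond the Compton edge (``E * 2a / (1 + 2a)``, about 341 keV for
    511 keV photons).
    """
    if not 0.0 <= threshold_keV <= incident_keV:
        raise ValueError("threshold must be between 0 and the incident energy")
    alpha = incident_keV / ELECTRON_MASS_KEV
    eps_min = 1.0 / (1.0 + 2.0 * alpha)
    eps_cut = 1.0 - threshold_keV / incident_keV  # deposit > threshold
    if eps_cut <= eps_min:
        return 0.0
    total, _ = integrate.quad(_kn_weight, eps_min, 1.0, args=(alpha,))
    accepted, _ = integrate.quad(_kn_weight, eps_min, eps_cut, args=(alpha,))
    return min(accepted / total, 1.0)


def detection_acceptance(design: ScannerDesign) -> float:
    """Per-photon acceptance factor beyond geometry and attenuation.

    Crystal designs: azimuthal packing fraction times the photopeak-window
    efficiency.  Strip designs: azimuthal fill times the Klein-Nishina
    fraction of Compton deposits above the energy-loss threshold.
    """
    spec = design.spec
    if isinstance(spec, CrystalScannerSpec):
        return spec.packing_fraction * spec.photopeak_efficiency
    return spec.azimuthal_fill * compton_accept_fraction(spec.energy_threshold_keV)


def detect(
    hits: PhotonHits,
    material: Material,
    survival,
    acceptance,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Bernoulli detection draw.

    ``p = survival * interaction_probability(chord) * acceptance`` per
    photon; returns ``(detected, p)``.
    """
    survival = np.asarray(survival, dtype=float)
    acceptance = np.asarray(acceptance, dtype=float)
    if np.any((survival < 0) | (survival > 1)):
        raise ValueError("survival must be in [0, 1]")
    if np.any((acceptance < 0) | (acceptance > 1)):
        raise ValueError("acceptance must be in [0, 1]")
    p = survival * interaction_probability(hits.chord, material) * acceptance
    p = np.where(hits.hit, p, 0.0)
    detected = rng.random(len(hits)) < p
    return detected, p
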