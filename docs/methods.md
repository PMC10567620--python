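# Methods

## Model overview

`tbpet` estimates the axial sensitivity of total-body PET designs with a
simplified, fully analytical photon transport instead of a general-purpose
Monte Carlo physics engine. A simulated decay produces exactly one pair of
exactly antiparallel 511 keV photons at a point sampled uniformly inside
the line source; each photon is then a straight ray whose fate is decided
by three independent factors:

1. **water survival** `exp(−μ_w · ℓ_w)`, with `ℓ_w` the exact chord of the
   ray through the phantom cylinder (ray/cylinder ∩ ray/slab
   intersection);
2. **interaction** `1 − exp(−μ · ℓ_d)`, with `ℓ_d` the chord through
   scintillator material accumulated across detector shells;
3. **acceptance**, a per-design constant described below.

Detection is a Bernoulli draw on the product. An event whose two photons
are both detected becomes a true coincidence; its line of response (LOR)
carries the two detection points, the LOR angle from the transaxial plane,
the axial unit indices (crystal family) and the true annihilation `z`.
Randoms, phantom scatter (an attenuated photon is lost, never redirected),
inter-crystal scatter, dead time and timing are not modelled.

## Detector families

**Radial-crystal** scanners are modelled as a cylindrical shell of inner
radius `R` and thickness equal to the crystal depth, axially segmented
into detection units (with optional inter-unit gaps) and azimuthally into
blocks. The chord of an oblique ray through the shell is scaled by the
fraction of its axial span that overlaps active units, using a
piecewise-linear cumulative-material function; a ray entering the shell
inside an axial gap or a masked-off block is a miss (first-element rule; a
ray exactly grazing a unit boundary also misses). Sparse variants are
full designs with an alternating unit occupancy mask: 29 units of 6.72 cm
(15 active) at 194.8 cm, 15 units of 6.49 cm (8 active) at 97.4 cm,
giving 0.53–0.55 of the full photosensor area, i.e. "nearly half".

**Axial-strip** scanners are 2–4 concentric shells of long plastic strips.
Each shell contributes its exact radial chord clipped to the strip length;
chords are summed over shells (multiple Compton scatters within one strip
are not chained — detection uses the total chord once).

## Acceptance factors

* Crystal family: `packing_fraction × photopeak_efficiency`.
  `packing_fraction` (default 0.85) absorbs inter-crystal and inter-block
  dead space on the barrel surface. `photopeak_efficiency` (default
  0.824) is the probability that an interacting photon passes the implicit
  photopeak energy window of the digitizer. It was calibrated **once**:
  with the multiplier at 1 the full-BGO 194.8 cm design yields a
  central-slice sensitivity of 515 cps/kBq (mean of three 4·10⁶-event
  runs); the published headline value for that scanner is ≈350 cps/kBq,
  so the default is `sqrt(350/515.3) = 0.824`. The same value applies to
  every crystal design, so all cross-design orderings are unaffected; it
  is a per-design config field for sensitivity studies.
* Strip family: `azimuthal_fill × f_KN(E_thr)` with `azimuthal_fill`
  0.98 and `f_KN` the Klein–Nishina fraction of single Compton scatters of
  a 511 keV photon depositing more than the energy-loss threshold
  (default 200 keV → 0.4408). `f_KN` is computed by adaptive quadrature of
  the Klein–Nishina cross-section over the scattered-photon energy
  fraction; the test suite checks it against an independent trapezoid
  integration over the scattering angle to 10⁻⁴.

## Key parameters

| parameter | default | notes |
|---|---|---|
| μ at 511 keV (1/cm) | BGO 0.955, LYSO/LSO 0.87, plastic 0.098, water 0.096 | standard attenuation lengths (BGO ≈1.05 cm, LYSO ≈1.15 cm) |
| ring inner radius | 39.3 cm (crystal), 41.5 cm innermost layer (strip) | not derivable from AFOV; vendor-typical values, configurable |
| uEXPLORER crystal | 2.76×2.76×18.1 mm, 35×84 per block, 24 blocks/unit | published crystal size; 8×24×2940 = 564,480 crystals |
| Biograph Vision | 8 rings × 38 panels × 20×10 crystals of 3.2×3.2×20 mm, 1 mm inter-ring gap | gap chosen so 8×3.2 + 7×0.1 = 26.3 cm exactly |
| strip cross sections | 4×20 mm and 6×30 mm (width × radial depth) | strips tile each layer circumference |
| layer spacing | strip depth + 0.5 cm clearance | hosts the WLS plane |
| WLS accounting | one plane per layer, 3 mm axial pitch, one 3×6 mm SiPM face per piece | covered-area only, no volume/detection role |
| material cost / volume | LYSO 1.0, BGO 0.4, plastic 0.02 | BGO quoted 2–3× cheaper than LYSO |
| slice width `d` | 1 cm | resolves the 6.7 cm sparse waviness with good statistics |
| acceptance angle | 57°, ring-difference equivalent `round(2R·tan 57° / pitch)` | gives the canonical 5-unit cut at the 24.35 cm uEXPLORER pitch, 18 for sparse units, 37 (no effect) for Biograph Vision |

The LOR angle convention: θ is measured from the transaxial plane, so
θ = 0 is a perpendicular LOR and the cut keeps θ ≤ 57°. The code exposes
the angle, so the opposite convention is one argument away.

## What the generator emulates — and what passing tests do not show

The event generator reproduces the two canonical sensitivity setups: a
1 mm × 250 cm axial line source, alone or centred in a 20 cm × 183 cm
water cylinder. It does **not** emulate positron range, photon
acollinearity (≈0.25°), source self-attenuation, isotope decay during
acquisition, or out-of-field activity. Consequently the test suite
validates geometric and first-order-physics behaviour — profile shapes,
orderings, cut logic, normalisations — but absolute sensitivities carry
the systematic uncertainty of the energy-window calibration above, and
nothing here predicts count-rate performance (NECR), spatial resolution
or scatter fractions of real systems.

## Numerical choices

* Slice grid: edges on half-integers (−125.5 … 125.5 cm), so the 183 cm
  body range aligns exactly with 183 slices of 1 cm and the centre slice
  is centred at z = 0.
* Events are assigned to slices by true annihilation `z` (noiseless);
  LOR-midpoint assignment is available by binning the record columns.
* `A_body = A_mean · 183/250`, the activity of the source segment inside
  the body range.
* Seeding: one master seed feeds a `SeedSequence` that spawns independent
  streams for emission and each photon's detection draws; identical
  seeds give byte-identical outputs. Comparative properties (BGO ≥ LYSO,
  full ≥ sparse, phantom ≤ bare) are tested with **common random
  numbers**, which makes the dominated design's detections an exact
  subset and the slice-wise ordering deterministic.
* Shape statistics (triangularity, plateau coefficient of variation) are
  evaluated on a 5–9 cm boxcar-smoothed profile because at the default
  10⁶-event test size per-slice Poisson noise (≈5%) would otherwise
  dominate the flatness measure.
* Problem sizes: unit tests run at 2×10⁴–3×10⁵ events, profile-shape and
  headline checks at 1–2×10⁶, where a central slice of the full BGO
  design collects ≈2,800 coincidences (≈2% relative error). The full
  17-design grid at 2×10⁶ events completes in about 45 s on one core.

## Design choices on genuinely open points

* **Ring-difference defaults.** The acceptance-angle equivalent is
  converted into each design's own unit pitch rather than applying a
  literal "5 units" everywhere; a literal 5 on the Biograph's 3.3 cm
  rings would cut LORs the short scanner is supposed to be neutral to.
* **WLS photosensor area.** How the axial-localisation WLS strips enter
  the covered-area sum is the dominant uncertainty in the strip family's
  cost: the chosen full-tiling reading (one plane per layer, 3 mm pitch)
  roughly doubles the strip-end SiPM area. Under a sparser WLS readout
  the strip scanners' relative cost drops and their TB-FOM rises
  accordingly; the `n_wls_readouts` field makes this a config choice.
* **Ranking sensitivity.** With these defaults the cost-normalised
  ranking favours the full-BGO design (TB-FOM 1.52 vs 0.88–0.98 for the
  strip designs); the strip family's standing improves under a cheaper
  WLS readout model or a higher plastic detection efficiency, so the
  ranking should be read as conditional on the cost accounting, not as a
  verdict on the technologies.

## Known limitations

* Absolute sensitivities are anchored to one published headline value
  through the photopeak-efficiency calibration; they are not ab-initio.
* The shell model ignores the transaxial block polygonalisation (a
  packing-fraction multiplier stands in for it) and depth-of-interaction
  structure within crystals.
* Strip detection treats the summed chord as one interaction opportunity;
  chaining multiple thin-layer scatters would raise plastic efficiency
  slightly at oblique angles.
* The water phantom only attenuates; near-end slices therefore gain
  sensitivity purely geometrically, with no scatter background to offset
  the effect.
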