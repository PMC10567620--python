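"""Photon transport: water paths, chords, interaction and Compton physics.

Chord lengths are cross-checked against an independent root-finding oracle
on the ray's radius function; the Klein-Nishina acceptance is cross-checked
against a trapezoid integration over the scattering angle.
"""

import numpy as np
import pytest
from scipy.optimize import brentq

from tbpet import (
    EventBatch,
    PhantomSpec,
    SourceSpec,
    compton_accept_fraction,
    detect,
    detector_intersection,
    get_material,
    interaction_probability,
    sample_events,
    survival_probability,
    water_path,
)
from tbpet.transport import ELECTRON_MASS_KEV


def one_event(position, direction):
    d = np.asarray(direction, float)
    return EventBatch([position], [d / np.linalg.norm(d)])


class TestWaterPath:
    def test_transaxial_from_center(self):
        ev = one_event((0, 0, 0), (1, 0, 0))
        assert water_path(ev, PhantomSpec())[0] == pytest.approx(10.0)

    def test_axial_from_center(self):
        ev = one_event((0, 0, 0), (0, 0, 1))
        assert water_path(ev, PhantomSpec())[0] == pytest.approx(91.5)

    def test_no_phantom(self):
        ev = one_event((0, 0, 0), (1, 0, 0))
        assert water_path(ev, None)[0] == 0.0

    def test_source_beyond_phantom_end(self):
        # annihilation outside the phantom, photon travelling away from it
        ev = one_event((0, 0, 100.0), (0, 0, 1))
        assert water_path(ev, PhantomSpec())[0] == 0.0
        # and towards/through it: full 183 cm axial crossing
        ev = one_event((0, 0, 100.0), (0, 0, -1))
        assert water_path(ev, PhantomSpec())[0] == pytest.approx(183.0)

    def test_oblique_path_shorter_than_axial(self):
        ev = one_event((0, 0, 0), (1, 0, 1))
        path = water_path(ev, PhantomSpec())[0]
        assert path == pytest.approx(10.0 * np.sqrt(2.0))


class TestSurvival:
    def test_zero_path(self):
        assert survival_probability(0.0, 0.5) == pytest.approx(1.0)

    def test_closed_form(self):
        assert survival_probability(10.0, 0.096) == pytest.approx(
            np.exp(-0.96), rel=1e-12
        )

    def test_monotone_in_path(self):
        assert survival_probability(20.0, 0.096) < survival_probability(10.0, 0.096)

    def test_negative_path_rejected(self):
        with pytest.raises(ValueError):
            survival_probability(-1.0, 0.1)


def radius_at(p, u, t):
    q = p + t * u
    return np.hypot(q[0], q[1])


def chord_oracle(p, u, r_in, r_out):
    """Bracketed root-finding for the shell crossing times."""
    p, u = np.asarray(p, float), np.asarray(u, float)
    t_hi = 10_000.0
    t1 = brentq(lambda t: radius_at(p, u, t) - r_in, 0.0, t_hi, xtol=1e-12)
    t2 = brentq(lambda t: radius_at(p, u, t) - r_out, 0.0, t_hi, xtol=1e-12)
    return t2 - t1


class TestDetectorIntersection:
    def test_axial_photon_escapes_barrel(self, full_bgo):
        ev = one_event((0, 0, 0), (0, 0, 1))
        hits = detector_intersection(full_bgo, ev)
        assert not hits.hit[0]
        assert hits.chord[0] == 0.0

    def test_normal_incidence_chord_is_crystal_depth(self, full_bgo):
        ev = one_event((0, 0, 0), (1, 0, 0))
        hits = detector_intersection(full_bgo, ev)
        assert hits.hit[0]
        assert hits.chord[0] == pytest.approx(1.81, rel=1e-12)

    def test_normal_incidence_strip_chord_is_total_thickness(self, designs):
        design = designs["jpet_630_4l_200"]
        ev = one_event((0, 0, 0), (0, 1, 0))
        hits = detector_intersection(design, ev)
        assert hits.hit[0]
        assert hits.chord[0] == pytest.approx(4 * 3.0, rel=1e-12)
        assert hits.layer[0] == 0

    @pytest.mark.parametrize("theta_deg", [10.0, 30.0, 45.0, 60.0])
    def test_oblique_chord_matches_root_finding_oracle(self, full_bgo, theta_deg):
        th = np.radians(theta_deg)
        u = np.array([np.cos(th), 0.0, np.sin(th)])
        ev = one_event((0, 0, 0), u)
        hits = detector_intersection(full_bgo, ev)
        spec = full_bgo.spec
        expected = chord_oracle(
            np.zeros(3), u, spec.ring_inner_radius,
            spec.ring_inner_radius + spec.crystal_depth,
        )
        assert hits.chord[0] == pytest.approx(expected, rel=1e-6)
        # closed form for a ray from the axis: depth / cos(theta)
        assert hits.chord[0] == pytest.approx(1.81 / np.cos(th), rel=1e-6)

    def test_unit_and_block_indexing(self, full_bgo):
        # photon at a polar angle landing 30 cm up the barrel: unit 5 of 8
        z_land = 30.0
        u = np.array([1.0, 0.0, z_land / 39.3])
        ev = one_event((0, 0, 0), u)
        hits = detector_intersection(full_bgo, ev)
        assert hits.unit[0] == int((z_land + 97.4) // 24.35)
        assert hits.block[0] == 0  # phi = 0

    def test_sparse_gap_entry_is_a_miss(self, designs):
        sparse = designs["uexplorer_sparse_bgo_194"]
        pitch = sparse.spec.unit_pitch
        # aim the photon into the first empty unit (odd index)
        z_gap = -194.8 / 2 + 1.5 * pitch
        u = np.array([1.0, 0.0, z_gap / 39.3])
        hits = detector_intersection(sparse, one_event((0, 0, 0), u))
        assert not hits.hit[0]

    def test_photon_b_is_antiparallel(self, full_bgo):
        ev = one_event((0, 0, 10.0), (1, 0, 0.2))
        hA = detector_intersection(full_bgo, ev, "A")
        hB = detector_intersection(full_bgo, ev, "B")
        assert hA.hit[0] and hB.hit[0]
        assert hA.entry[0, 0] == pytest.approx(-hB.entry[0, 0], rel=1e-9)


class TestInteraction:
    def test_zero_path(self):
        assert interaction_probability(0.0, get_material("BGO")) == 0.0

    def test_bgo_closed_form(self):
        p = interaction_probability(1.81, get_material("BGO"))
        assert p == pytest.approx(1.0 - np.exp(-0.955 * 1.81), rel=1e-12)

    def test_bgo_stops_more_than_lyso(self):
        path = 1.81
        assert interaction_probability(path, get_material("BGO")) > \
            interaction_probability(path, get_material("LYSO"))


def kn_accept_oracle(threshold_keV, incident_keV=511.0, n=400_001):
    """Klein-Nishina acceptance by trapezoid integration over the
    scattering angle (independent of the energy-fraction quadrature)."""
    alpha = incident_keV / ELECTRON_MASS_KEV
    cos_t = np.linspace(-1.0, 1.0, n)
    eps = 1.0 / (1.0 + alpha * (1.0 - cos_t))
    sin2 = 1.0 - cos_t**2
    dsdo = eps**2 * (eps + 1.0 / eps - sin2)  # KN angular density
    deposit = incident_keV * (1.0 - eps)
    total = np.trapezoid(dsdo, cos_t)
    accepted = np.trapezoid(np.where(deposit > threshold_keV, dsdo, 0.0), cos_t)
    return accepted / total


class TestComptonAcceptance:
    def test_zero_threshold_accepts_all(self):
        assert compton_accept_fraction(0.0) == pytest.approx(1.0)

    def test_compton_edge_cutoff(self):
        edge = 511.0 * (2 * 511.0 / ELECTRON_MASS_KEV) / (1 + 2 * 511.0 / ELECTRON_MASS_KEV)
        assert edge == pytest.approx(340.7, abs=0.05)
        assert compton_accept_fraction(edge + 0.01) == 0.0
        assert compton_accept_fraction(450.0) == 0.0

    def test_200_keV_matches_quadrature_oracle(self):
        assert compton_accept_fraction(200.0) == pytest.approx(
            kn_accept_oracle(200.0), abs=1e-4
        )

    @pytest.mark.parametrize("thr", [50.0, 100.0, 150.0, 250.0, 300.0])
    def test_other_thresholds_match_oracle(self, thr):
        assert compton_accept_fraction(thr) == pytest.approx(
            kn_accept_oracle(thr), abs=1e-4
        )

    def test_monotone_non_increasing(self):
        thresholds = np.linspace(0.0, 340.0, 35)
        values = [compton_accept_fraction(float(t)) for t in thresholds]
        assert all(a >= b - 1e-12 for a, b in zip(values, values[1:]))

    def test_out_of_range_threshold(self):
        with pytest.raises(ValueError):
            compton_accept_fraction(-1.0)
        with pytest.raises(ValueError):
            compton_accept_fraction(512.0)


class TestDetect:
    def make_hits(self, design, n, direction=(1, 0, 0)):
        ev = EventBatch(
            np.zeros((n, 3)), np.tile(np.asarray(direction, float), (n, 1))
        )
        return detector_intersection(design, ev)

    def test_p_zero_never_detects(self, full_bgo):
        hits = self.make_hits(full_bgo, 1000)
        rng = np.random.default_rng(0)
        detected, p = detect(hits, full_bgo.material, 0.0, 1.0, rng)
        assert not detected.any()

    def test_p_one_always_detects(self, full_bgo):
        hits = self.make_hits(full_bgo, 1000)
        hits.chord[:] = 1e9  # interaction probability -> 1
        rng = np.random.default_rng(0)
        detected, p = detect(hits, full_bgo.material, 1.0, 1.0, rng)
        assert detected.all()

    def test_half_probability_binomial(self, full_bgo):
        n = 100_000
        hits = self.make_hits(full_bgo, n)
        mu = full_bgo.material.mu_511
        hits.chord[:] = np.log(2.0) / mu  # interaction probability = 1/2
        rng = np.random.default_rng(1)
        detected, p = detect(hits, full_bgo.material, 1.0, 1.0, rng)
        np.testing.assert_allclose(p, 0.5, rtol=1e-12)
        sigma = np.sqrt(0.25 / n)
        assert abs(detected.mean() - 0.5) < 3 * sigma

    def test_invalid_probabilities_rejected(self, full_bgo):
        hits = self.make_hits(full_bgo, 10)
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            detect(hits, full_bgo.material, 1.5, 1.0, rng)


class TestBarrelSolidAngle:
    def test_center_point_coincidence_fraction(self, full_bgo):
        """With interactions forced on, the probability that both photons of
        a centred point source strike the barrel is cos(atan(2R/L))."""
        n = 200_000
        src = SourceSpec(L_mean=1e-9, diameter=0.0)
        events = sample_events(src, n, seed=42)
        hA = detector_intersection(full_bgo, events, "A")
        hB = detector_intersection(full_bgo, events, "B")
        frac = np.mean(hA.hit & hB.hit)
        expected = np.cos(np.arctan(2 * 39.3 / 194.8))
        sigma = np.sqrt(expected * (1 - expected) / n)
        assert abs(frac - expected) < 3 * sigma
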