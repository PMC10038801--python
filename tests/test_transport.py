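"""Transport: free paths, positron range, annihilation, tallies, TERMA."""
import numpy as np
import pytest
from scipy import stats

from p2t.beams import Beam, BeamPlan
from p2t.materials import (Material, get_material, uniform_phantom)
from p2t.spectrum import monoenergetic
from p2t.transport import (PositronRangeModel, compute_terma,
                           emit_annihilation_pair, positron_displacement,
                           survival_weight, tally_ground_truth, trace_primaries,
                           trace_primary)


class TestPrimaryTracing:
    def test_mean_free_path_matches_exponential(self, mono5_water_phantom, rng):
        """Free path in a uniform medium is exponential with mean 1/mu."""
        ph = mono5_water_phantom
        mu = float(ph.model.mu_total(get_material("water"), 5.0))
        n = 10 ** 5
        O = np.tile([-10.0, 0.05], (n, 1))
        D = np.tile([1.0, 0.0], (n, 1))
        status, pos, mat, plen, w = trace_primaries(
            O, D, np.zeros(n, dtype=np.int64), ph, rng)
        hit = status > 0
        # condition on interacting within the 20 cm slab
        depth = plen[hit]
        L = 20.0
        expected = 1 / mu - L * np.exp(-mu * L) / (1 - np.exp(-mu * L))
        se = (1 / mu) / np.sqrt(hit.sum())
        assert abs(depth.mean() - expected) < 3 * se

    def test_vacuum_always_escapes(self, rng):
        vac = Material("vacuum", 0.0, {"H": 1.0})
        ph = uniform_phantom(vac, half_size=5.0)
        ph.spectrum = monoenergetic(5.0)
        out = trace_primary((-10.0, 0.0), (1.0, 0.0), 5.0, ph, rng)
        assert out is None

    def test_no_pair_production_below_threshold(self, rng):
        ph = uniform_phantom("water", half_size=10.0)
        ph.spectrum = monoenergetic(1.0)
        n = 20000
        status, *_ = trace_primaries(
            np.tile([-10.0, 0.05], (n, 1)), np.tile([1.0, 0.0], (n, 1)),
            np.zeros(n, dtype=np.int64), ph, rng)
        assert np.sum(status == 3) == 0
        assert np.sum(status == 2) > 0  # Compton still occurs

    def test_interaction_mix_matches_mu_ratios(self, mono5_water_phantom, rng):
        ph = mono5_water_phantom
        w = get_material("water")
        n = 10 ** 5
        status, *_ = trace_primaries(
            np.tile([-10.0, 0.05], (n, 1)), np.tile([1.0, 0.0], (n, 1)),
            np.zeros(n, dtype=np.int64), ph, rng)
        hit = status[status > 0]
        frac_pair = np.mean(hit == 3)
        expected = float(ph.model.mu_pair(w, 5.0) / ph.model.mu_total(w, 5.0))
        se = np.sqrt(expected * (1 - expected) / hit.size)
        assert abs(frac_pair - expected) < 3 * se


class TestPositronRange:
    def test_density_scaling_is_exact(self):
        model = PositronRangeModel()
        t = np.full(1000, 1.5)
        r1 = model.sample_magnitude(t, 1.0, np.random.default_rng(5))
        r2 = model.sample_magnitude(t, 2.0, np.random.default_rng(5))
        assert np.allclose(r1, 2.0 * r2)

    def test_median_in_water_is_4p6_mm(self, rng):
        """Calibrated range law: median 3D travel distance of the 10 MV
        pair-production positron population in water is 4.6 mm."""
        model = PositronRangeModel()
        t_plus = model.t_plus_population(10 ** 5, rng)
        mags = model.sample_magnitude(t_plus, 1.0, rng)
        med = np.median(mags) * 10
        boot = np.array([np.median(rng.choice(mags, mags.size)) * 10
                         for _ in range(50)])
        assert abs(med - 4.6) < max(3 * boot.std(), 0.05)

    def test_directions_isotropic(self, rng):
        disp = positron_displacement(np.full(10 ** 4, 1.0), 1.0, rng)
        unit = disp / np.linalg.norm(disp, axis=1, keepdims=True)
        bound = 3 * np.sqrt(1 / (3 * len(unit)))
        assert np.all(np.abs(unit.mean(axis=0)) < 3 * bound)

    def test_zero_density_rejected(self, rng):
        with pytest.raises(ValueError):
            positron_displacement(np.array([1.0]), 0.0, rng)


class TestAnnihilationEmission:
    def test_back_to_back_and_energy(self, rng):
        u1, u2, e = emit_annihilation_pair(500, rng)
        assert e == 0.511
        dots = np.sum(u1 * u2, axis=1)
        assert np.allclose(dots, -1.0, atol=1e-12)

    def test_azimuthal_uniformity(self, rng):
        u1, _, _ = emit_annihilation_pair(10 ** 5, rng)
        phi = np.mod(np.arctan2(u1[:, 1], u1[:, 0]), 2 * np.pi)
        counts, _ = np.histogram(phi, bins=36, range=(0, 2 * np.pi))
        chi2 = np.sum((counts - counts.mean()) ** 2 / counts.mean())
        p = stats.chi2.sf(chi2, df=35)
        assert p > 0.001


class TestSurvival:
    def test_vacuum_survival_is_one(self, rng):
        vac = Material("vacuum", 0.0, {"H": 1.0})
        ph = uniform_phantom(vac, half_size=5.0)
        assert survival_weight((0.0, 0.0), (1.0, 0.0), ph)[0] == 1.0

    def test_water_chord_closed_form(self, water_phantom):
        w = survival_weight((-10.0, 0.05), (1.0, 0.0), water_phantom)[0]
        mu = water_phantom.mu511[0, 0]
        assert w == pytest.approx(np.exp(-mu * 20.0), rel=1e-9)

    def test_longer_chord_smaller_weight(self, water_phantom):
        w_long = survival_weight((-10.0, 0.05), (1.0, 0.0), water_phantom)[0]
        w_short = survival_weight((5.0, 0.05), (1.0, 0.0), water_phantom)[0]
        assert w_long < w_short <= 1.0


class TestGroundTruthTally:
    def test_single_event(self, water_phantom):
        img = tally_ground_truth(np.array([[0.1, 0.1]]), np.array([2.5]),
                                 water_phantom)
        assert img.values.sum() == 2.5
        assert np.count_nonzero(img.values) == 1

    def test_conservation_and_outside_drop(self, water_phantom, rng):
        pts = rng.uniform(-12, 12, size=(5000, 2))
        w = rng.uniform(0.5, 2.0, 5000)
        img = tally_ground_truth(pts, w, water_phantom)
        inside = np.all(np.abs(pts) < 10.0, axis=1)
        assert img.values.sum() == pytest.approx(w[inside].sum())
        assert img.provenance["dropped_events"] == int(np.sum(~inside))

    def test_linearity_in_weights(self, water_phantom):
        p = np.array([[1.0, 2.0]])
        one = tally_ground_truth(p, np.array([1.0]), water_phantom)
        halves = tally_ground_truth(np.vstack([p, p]), np.array([0.5, 0.5]),
                                    water_phantom)
        assert np.array_equal(one.values, halves.values)


class TestTerma:
    def _plan(self):
        return BeamPlan((Beam(angle_deg=0.0, sad=100.0,
                              pencil_offsets=np.array([0.0]),
                              pencil_width=30.0, fluence=np.array([1.0])),))

    def test_zero_fluence_zero_terma(self, water_phantom):
        plan = BeamPlan((Beam(angle_deg=0.0, sad=100.0,
                              pencil_offsets=np.array([0.0]),
                              pencil_width=30.0, fluence=np.array([0.0])),))
        img = compute_terma(plan, water_phantom)
        assert np.all(img.values == 0.0)

    def test_linearity_in_spectrum_bins(self):
        """Two-line spectrum TERMA equals the probability-weighted sum of
        the single-line TERMAs."""
        from p2t.spectrum import Spectrum
        plan = self._plan()
        phs = []
        for spec in (monoenergetic(2.0), monoenergetic(6.0),
                     Spectrum(np.array([2.0, 6.0]), np.array([0.25, 0.75]))):
            ph = uniform_phantom("water", half_size=10.0)
            ph.spectrum = spec
            phs.append(compute_terma(plan, ph, n_groups=2).values)
        combined = 0.25 * phs[0] + 0.75 * phs[1]
        assert np.allclose(phs[2], combined, rtol=1e-9)

    def test_uniform_water_single_bin_profile(self):
        """Single-line beam on uniform water: TERMA = f * E * mu / rho."""
        ph = uniform_phantom("water", half_size=10.0)
        ph.spectrum = monoenergetic(5.0)
        plan = self._plan()
        img = compute_terma(plan, ph, n_groups=1)
        from p2t.beams import fluence_map
        flu = fluence_map(plan, ph, keep_per_beam=False).total
        w = get_material("water")
        mu = float(ph.model.mu_total(w, 5.0))
        expected = flu * 5.0 * mu / w.density
        ok = flu > 0
        assert np.allclose(img.values[ok], expected[ok], rtol=1e-9)
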