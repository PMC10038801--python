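"""Beams: spectra, release timing, Siddon tracing, fluence maps."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from p2t.beams import (Beam, BeamPlan, fan_beam_plan, fluence_map, load_plan,
                       release_times, save_plan, schedule_beams,
                       siddon_raytrace)
from p2t.materials import uniform_phantom
from p2t.spectrum import Spectrum, default_10mv_spectrum, monoenergetic


class TestSpectrum:
    def test_single_line_samples(self, rng):
        sp = monoenergetic(6.0)
        assert np.all(sp.sample(100, rng) == 6.0)

    def test_sample_mean_matches_analytic(self, rng):
        sp = default_10mv_spectrum()
        n = 10 ** 6
        draws = sp.sample(n, rng)
        se = np.sqrt(np.sum(sp.probabilities * (sp.energies - sp.mean()) ** 2) / n)
        assert abs(draws.mean() - sp.mean()) < 3 * se

    def test_support_respects_endpoint(self, rng):
        sp = default_10mv_spectrum()
        assert sp.sample(10 ** 5, rng).max() <= 10.0

    def test_empty_spectrum_rejected(self):
        with pytest.raises(ValueError):
            Spectrum(np.array([]), np.array([]))


class TestReleaseTiming:
    def test_single_release_in_first_gap(self, rng):
        t = release_times(1, rate=100.0, rng=rng)
        assert 0 <= t[0] < 2 / 100.0

    def test_mean_gap_is_inverse_rate(self, rng):
        rate = 50.0
        t = release_times(10 ** 5, rate, rng)
        gaps = np.diff(np.concatenate([[0.0], t]))
        se = (2 / rate) / np.sqrt(12 * len(gaps))  # SD of U(0, 2/R)
        assert abs(gaps.mean() - 1 / rate) < 3 * se

    def test_strictly_sorted(self, rng):
        t = release_times(10 ** 4, 1e3, rng)
        assert np.all(np.diff(t) > 0)

    def test_negative_count_rejected(self, rng):
        with pytest.raises(ValueError):
            release_times(-1, 1.0, rng)


class TestSchedule:
    def _plan(self, mode, n_pencils=2, n_photons=50):
        return BeamPlan((Beam(angle_deg=0.0, mode=mode,
                              pencil_offsets=np.arange(n_pencils) * 0.2,
                              fluence=np.full(n_pencils, float(n_photons)),
                              rate=1e3),))

    def test_spbe_pencils_strictly_sequential(self, rng):
        b, p, t, _ = schedule_beams(self._plan("SPBE"), rng)
        assert t[p == 0].max() < t[p == 1].min()

    def test_ve_pencils_start_together(self, rng):
        b, p, t, _ = schedule_beams(self._plan("VE"), rng)
        # every pencil's first photon is an independent first gap from zero
        for pi in (0, 1):
            assert t[p == pi].min() < 2 / 1e3

    def test_empty_plan(self, rng):
        plan = BeamPlan((Beam(angle_deg=0.0, pencil_offsets=np.array([0.0]),
                              fluence=np.array([0.0])),))
        b, p, t, _ = schedule_beams(plan, rng)
        assert t.size == 0


class TestSiddon:
    def test_axis_aligned_row(self, water_phantom):
        hits = siddon_raytrace((-10.0, 0.05), (-8.0, 0.05), water_phantom)
        assert len(hits) == 10
        lengths = [l for _, l in hits]
        assert np.allclose(lengths, 0.2)

    def test_single_voxel_diagonal(self, water_phantom):
        hits = siddon_raytrace((-10.0, -10.0), (-9.8, -9.8), water_phantom)
        assert len(hits) == 1
        assert hits[0][1] == pytest.approx(0.2 * np.sqrt(2), abs=1e-9)

    def test_degenerate_segment_rejected(self, water_phantom):
        with pytest.raises(ValueError):
            siddon_raytrace((1.0, 1.0), (1.0, 1.0), water_phantom)

    @given(st.floats(-15, 15), st.floats(-15, 15),
           st.floats(-15, 15), st.floats(-15, 15))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_length_conservation_and_symmetry(self, x1, y1, x2, y2):
        """Summed voxel lengths equal the grid-clipped chord length, and
        the traversal is direction-symmetric."""
        ph = uniform_phantom("water", half_size=10.0, spacing=0.5)
        p1, p2 = np.array([x1, y1]), np.array([x2, y2])
        if np.hypot(*(p2 - p1)) < 1e-6:
            return
        fwd = siddon_raytrace(p1, p2, ph)
        total = sum(l for _, l in fwd)
        # analytic clip of the segment to the box
        d = p2 - p1
        lo, hi = 0.0, 1.0
        for ax in (0, 1):
            if abs(d[ax]) < 1e-12:
                if not -10 <= p1[ax] < 10:
                    lo, hi = 1.0, 0.0
                continue
            ta, tb = (-10 - p1[ax]) / d[ax], (10 - p1[ax]) / d[ax]
            lo, hi = max(lo, min(ta, tb)), min(hi, max(ta, tb))
        expected = max(hi - lo, 0.0) * np.hypot(*d)
        assert total == pytest.approx(expected, abs=1e-8)
        rev = siddon_raytrace(p2, p1, ph)
        assert sorted((v, round(l, 9)) for v, l in fwd) == \
               sorted((v, round(l, 9)) for v, l in rev)


class TestFluence:
    def test_inverse_square_in_vacuum(self):
        """Fluence between two voxels on one ray falls as 1/r^2 (no medium)."""
        ph = uniform_phantom("air", half_size=10.0)
        beam = Beam(angle_deg=0.0, sad=100.0,
                    pencil_offsets=np.array([0.0]), pencil_width=30.0,
                    fluence=np.array([1.0]))
        flu = fluence_map(BeamPlan((beam,)), ph)
        x, y = ph.voxel_centers()
        iy = len(y) // 2
        f = flu.total[iy, :]
        r = 100.0 + x  # distance from the source at (-100, 0)
        ratio = f[10] / f[-10]
        assert ratio == pytest.approx((r[-10] / r[10]) ** 2, rel=1e-3)

    def test_exponential_attenuation_in_water(self, water_phantom):
        beam = Beam(angle_deg=0.0, sad=100.0,
                    pencil_offsets=np.array([0.0]), pencil_width=30.0,
                    fluence=np.array([1.0]))
        flu = fluence_map(BeamPlan((beam,)), water_phantom)
        x, y = water_phantom.voxel_centers()
        iy = len(y) // 2
        i1, i2 = 10, 60  # 10 cm apart along the beam
        f1, f2 = flu.total[iy, i1], flu.total[iy, i2]
        mu = water_phantom.mu10mv[iy, 0]
        geom = ((100 + x[i1]) / (100 + x[i2])) ** 2
        assert f2 / f1 == pytest.approx(geom * np.exp(-mu * (x[i2] - x[i1])),
                                        rel=1e-6)

    def test_opposing_beams_symmetric(self, water_disk_phantom):
        plan = fan_beam_plan(2, coverage=16.0)
        flu = fluence_map(plan, water_disk_phantom, keep_per_beam=False)
        rot = np.rot90(flu.total, 2)
        assert np.allclose(flu.total, rot, rtol=1e-9, atol=1e-12)

    def test_additive_and_linear_in_reference_fluence(self, water_disk_phantom):
        plan1 = fan_beam_plan(1, coverage=16.0, fluence_per_pencil=1.0)
        plan2 = fan_beam_plan(1, coverage=16.0, fluence_per_pencil=3.0,
                              start_angle=90.0)
        both = BeamPlan(plan1.beams + plan2.beams)
        f1 = fluence_map(plan1, water_disk_phantom, keep_per_beam=False).total
        f2 = fluence_map(plan2, water_disk_phantom, keep_per_beam=False).total
        f12 = fluence_map(both, water_disk_phantom).total
        assert np.allclose(f12, f1 + f2, rtol=1e-12)
        f2_unit = fluence_map(
            fan_beam_plan(1, coverage=16.0, start_angle=90.0),
            water_disk_phantom, keep_per_beam=False).total
        assert np.allclose(f2, 3.0 * f2_unit, rtol=1e-12)

    def test_aperture_gives_exact_zero_outside(self, water_disk_phantom):
        plan = fan_beam_plan(1, coverage=16.0, aperture=(-6.0, -2.0))
        flu = fluence_map(plan, water_disk_phantom, keep_per_beam=False)
        x, y = water_disk_phantom.voxel_centers()
        xx, yy = np.meshgrid(x, y)
        assert np.all(flu.total[yy > 0.0] == 0.0)
        in_band = (yy < -3.0) & (yy > -4.5) & (np.abs(xx) < 4.0)
        assert flu.total[in_band].min() > 0.0

    def test_source_inside_phantom_rejected(self, water_phantom):
        plan = BeamPlan((Beam(angle_deg=0.0, sad=5.0,
                              pencil_offsets=np.array([0.0]),
                              fluence=np.array([1.0])),))
        with pytest.raises(ValueError, match="source"):
            fluence_map(plan, water_phantom)

    def test_plan_yaml_roundtrip(self, tmp_path):
        plan = fan_beam_plan(3, mode="SPBE", coverage=4.0)
        save_plan(plan, tmp_path / "plan.yaml")
        back = load_plan(tmp_path / "plan.yaml")
        assert back.n_beams == 3
        assert back.beams[1].mode == "SPBE"
        assert np.allclose(back.beams[0].pencil_offsets,
                           plan.beams[0].pencil_offsets)
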