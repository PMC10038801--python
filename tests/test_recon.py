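"""Reconstruction: rebinning, attenuation correction, FBP, SPB, TOF."""
import numpy as np
import pytest

from p2t.beams import Beam, BeamPlan
from p2t.detection import LORData, RingDetector
from p2t.image import Image
from p2t.materials import uniform_phantom
from p2t.recon import (DEFAULT_SPLAT_SIGMA, Sinogram,
                       attenuation_correct_sinogram, fbp, fluence_correct,
                       rebin_to_sinogram, spb_reconstruct, tof_locate,
                       tof_reconstruct)
from p2t.transport import SPEED_OF_LIGHT_CM_NS as C

RING = RingDetector()
FINE_RING = RingDetector(n_elements=14400)


def make_lors(ring, elem_i, elem_j, dt=None, weight=None, beam=None,
              pencil=None):
    n = len(elem_i)
    ei = np.asarray(elem_i, dtype=np.int64)
    ej = np.asarray(elem_j, dtype=np.int64)
    return LORData(
        ring, ei, ej,
        np.zeros(n) if dt is None else np.asarray(dt, dtype=float),
        np.ones(n) if weight is None else np.asarray(weight, dtype=float),
        np.zeros(n, dtype=np.int64) if beam is None else np.asarray(beam),
        np.zeros(n, dtype=np.int64) if pencil is None else np.asarray(pencil),
        np.arange(n, dtype=np.int64), np.arange(n, dtype=np.int64))


def chord_elements(ring, point, angle, jitter=0.0):
    """Element pair of the chord through ``point`` with direction ``angle``."""
    u = np.array([np.cos(angle), np.sin(angle)])
    p = np.asarray(point, dtype=float)
    b = 2 * p @ u
    c = p @ p - ring.radius ** 2
    s1 = (-b + np.sqrt(b * b - 4 * c)) / 2
    s2 = (-b - np.sqrt(b * b - 4 * c)) / 2
    out = []
    for s in (s1, s2):
        q = p + s * u
        az = np.mod(np.arctan2(q[1], q[0]) + jitter, 2 * np.pi)
        out.append(int(az / ring.sector_angle))
    return out


class TestRebinning:
    def test_diametral_lor_offset_zero(self):
        lors = make_lors(RING, [100], [820])
        sino = rebin_to_sinogram(lors)
        # offset of a chord between antipodal sector centres is exactly 0
        ir = np.argwhere(sino.counts > 1e-9)
        assert len(ir) == 1
        assert sino.radial_centers()[ir[0][0]] == pytest.approx(0.0, abs=0.1)
        from p2t.recon import lor_offset_angle
        s, _ = lor_offset_angle(lors)
        assert s[0] == pytest.approx(0.0, abs=1e-12)

    def test_count_conservation(self, rng):
        n = 2000
        ei = rng.integers(0, 1440, n)
        ej = (ei + rng.integers(400, 1000, n)) % 1440
        w = rng.uniform(0.2, 2.0, n)
        lors = make_lors(RING, ei, ej, weight=w)
        sino = rebin_to_sinogram(lors)
        from p2t.recon import lor_offset_angle
        offs, _ = lor_offset_angle(lors)
        in_fov = np.abs(offs) < sino.radial_extent
        assert sino.counts.sum() == pytest.approx(w[in_fov].sum())
        assert sino.dropped == int(np.sum(~in_fov))

    def test_central_lor_hits_center_bin(self):
        e1, e2 = chord_elements(RING, (0.0, 0.0), 0.3)
        sino = rebin_to_sinogram(make_lors(RING, [e1], [e2]))
        ir = int(np.argwhere(sino.counts > 0)[0][0])
        assert abs(ir - sino.n_radial // 2) <= 1


class TestAttenuationCorrection:
    def test_zero_mu_identity(self):
        ph = uniform_phantom("air", half_size=10.0)
        ph._cache["mu511"] = np.zeros(ph.shape)
        sino = Sinogram(np.ones((227, 16)))
        out = attenuation_correct_sinogram(sino, ph)
        assert np.allclose(out.counts, sino.counts)

    def test_central_chord_factor(self, water_disk_phantom):
        """A through-centre bin of the 8 cm water disk gains exp(mu*16)."""
        sino = Sinogram(np.zeros((227, 8)))
        sino.counts[113, :] = 1.0  # central radial bin
        out = attenuation_correct_sinogram(sino, water_disk_phantom)
        mu = water_disk_phantom.mu511.max()
        # rasterised disk boundary allows ~half-voxel chord error per edge
        assert np.allclose(out.counts[113, :], np.exp(mu * 16.0), rtol=0.025)

    def test_factors_at_least_one(self, water_disk_phantom, rng):
        sino = Sinogram(rng.random((227, 32)))
        out = attenuation_correct_sinogram(sino, water_disk_phantom)
        assert np.all(out.counts >= sino.counts - 1e-12)


class TestFBP:
    def grid(self, n=65, spacing=0.4):
        # odd size puts a voxel centre at the exact origin
        return uniform_phantom("air", half_size=n * spacing / 2,
                               spacing=spacing)

    def test_point_source_peaks_at_center(self):
        sino = Sinogram(np.zeros((127, 90)), radial_extent=12.7)
        sino.counts[63, :] = 1.0
        img = fbp(sino, self.grid())
        iy, ix = np.unravel_index(np.argmax(img.values), img.values.shape)
        assert (iy, ix) == (32, 32)

    def test_linearity(self, rng):
        s1 = Sinogram(rng.random((127, 45)), radial_extent=12.7)
        s2 = Sinogram(rng.random((127, 45)), radial_extent=12.7)
        g = self.grid()
        both = fbp(Sinogram(s1.counts + s2.counts, 12.7), g).values
        sep = fbp(s1, g).values + fbp(s2, g).values
        assert np.allclose(both, sep, rtol=1e-9, atol=1e-12)

    def test_zero_sinogram_zero_image(self):
        img = fbp(Sinogram(np.zeros((127, 45)), 12.7), self.grid())
        assert np.all(img.values == 0.0)

    def test_uniform_disk_roundtrip_against_oracle(self):
        """Analytic chord-length sinogram of a uniform disk reconstructs to
        a flat interior, agreeing with an independent inverse-Radon oracle."""
        from skimage.transform import iradon
        R = 5.0
        n_r, n_a = 127, 180
        extent = 12.7
        s = (-extent + (np.arange(n_r) + 0.5) * 2 * extent / n_r)
        proj = 2.0 * np.sqrt(np.clip(R * R - s * s, 0.0, None))
        sino = Sinogram(np.tile(proj[:, None], (1, n_a)), extent)
        g = self.grid()
        mine = fbp(sino, g).values
        x, y = g.voxel_centers()
        xx, yy = np.meshgrid(x, y)
        interior = xx ** 2 + yy ** 2 < (0.7 * R) ** 2
        flat = mine[interior]
        assert np.ptp(flat) / flat.mean() < 0.05
        # the disk has unit density, so the plateau itself must be ~1
        assert flat.mean() == pytest.approx(1.0, abs=0.05)

        # oracle: skimage iradon (own ramp filter, own pixel scaling) must
        # agree on the normalised radial shape of the reconstruction
        theta = np.degrees((np.arange(n_a) + 0.5) * np.pi / n_a)
        oracle = iradon(sino.counts, theta=theta, filter_name="ramp",
                        output_size=n_r, circle=False)
        ds_o = 2 * extent / n_r
        xo = (np.arange(n_r) - (n_r - 1) / 2) * ds_o
        xxo, yyo = np.meshgrid(xo, xo)
        int_o = xxo ** 2 + yyo ** 2 < (0.7 * R) ** 2
        mine_profile = mine[32, :] / flat.mean()
        oracle_profile = np.interp(x, xo, oracle[n_r // 2, :]
                                   / oracle[int_o].mean())
        core = np.abs(x) < 0.8 * R
        assert np.max(np.abs(mine_profile[core] - oracle_profile[core])) < 0.05


class TestSPB:
    def plan(self, width=0.2):
        return BeamPlan((Beam(angle_deg=0.0, sad=100.0,
                              pencil_offsets=np.array([0.0]),
                              pencil_width=width,
                              fluence=np.array([1.0])),))

    def test_exact_crossing_mass_and_center(self):
        ph = uniform_phantom("air", half_size=10.0)
        e1, e2 = chord_elements(FINE_RING, (2.0, 0.0), np.pi / 2)
        lors = make_lors(FINE_RING, [e1], [e2], weight=[1.7])
        img = spb_reconstruct(lors, self.plan(), ph,
                              attenuation_correct=False)
        assert img.values.sum() == pytest.approx(1.7, rel=1e-6)
        x, y = ph.voxel_centers()
        xx, yy = np.meshgrid(x, y)
        cx = np.sum(img.values * xx) / img.values.sum()
        cy = np.sum(img.values * yy) / img.values.sum()
        assert cx == pytest.approx(2.0, abs=0.05)
        assert cy == pytest.approx(0.0, abs=0.05)

    def test_parallel_lor_contributes_nothing(self):
        ph = uniform_phantom("air", half_size=10.0)
        # chord parallel to the pencil axis (angle 0) away from it
        e1, e2 = chord_elements(FINE_RING, (0.0, 3.0), 0.0)
        img = spb_reconstruct(make_lors(FINE_RING, [e1], [e2]),
                              self.plan(), ph, attenuation_correct=False)
        assert img.values.sum() == pytest.approx(0.0, abs=1e-9)

    def test_missing_pencil_id_rejected(self):
        ph = uniform_phantom("air", half_size=10.0)
        lors = make_lors(FINE_RING, [0], [7200], pencil=np.array([-1]))
        with pytest.raises(ValueError, match="pencil"):
            spb_reconstruct(lors, self.plan(), ph)

    def test_profile_width_variance_addition(self, rng):
        """Point-like source spread across the pencil width, imaged with
        45-degree LORs: profile variance = sigma^2 + width^2/12, matching
        a brute-force splat of the analytically located points."""
        ph = uniform_phantom("air", half_size=10.0, spacing=0.1)
        width = 0.6
        n = 20000
        ys = rng.uniform(-width / 2, width / 2, n)
        lors_e = np.array([chord_elements(FINE_RING, (0.0, y), np.pi / 4)
                           for y in ys])
        lors = make_lors(FINE_RING, lors_e[:, 0], lors_e[:, 1])
        img = spb_reconstruct(lors, self.plan(width), ph,
                              attenuation_correct=False)
        profile = img.values.sum(axis=0)
        x, _ = ph.voxel_centers()
        mean = np.sum(profile * x) / profile.sum()
        var = np.sum(profile * (x - mean) ** 2) / profile.sum()
        sigma_eff2 = DEFAULT_SPLAT_SIGMA ** 2 + width ** 2 / 12.0
        # oracle: located point of a 45-degree LOR through (0, y) is (-y, 0)
        var_oracle = DEFAULT_SPLAT_SIGMA ** 2 + np.var(ys)
        assert var == pytest.approx(var_oracle, rel=0.05)
        assert var == pytest.approx(sigma_eff2, rel=0.06)


class TestTOF:
    def test_zero_dt_is_midpoint(self):
        lors = make_lors(RING, [0], [720], dt=[0.0])
        pts, clamped = tof_locate(lors)
        assert clamped == 0
        assert np.allclose(pts[0], lors.endpoints()[0][0] * 0.0, atol=1e-9)

    def test_100ps_offset_is_15mm(self):
        lors = make_lors(RING, [0], [720], dt=[0.1])
        pts, _ = tof_locate(lors)
        A, B = lors.endpoints()
        mid = (A[0] + B[0]) / 2
        offset = np.linalg.norm(pts[0] - mid)
        assert offset * 10 == pytest.approx(15.0, abs=0.05)
        # displaced toward the earlier-triggered side? dt = t_i - t_j > 0
        # means element i fired later, so the point lies closer to j
        assert np.linalg.norm(pts[0] - B[0]) < np.linalg.norm(pts[0] - A[0])

    def test_outside_chord_clamped(self):
        chord = 2 * RING.radius
        lors = make_lors(RING, [0], [720], dt=[-(chord / C) * 1.5])
        pts, clamped = tof_locate(lors)
        assert clamped == 1
        A, _ = lors.endpoints()
        assert np.allclose(pts[0], A[0], atol=1e-9)

    def test_offset_within_half_chord(self, rng):
        n = 500
        ei = rng.integers(0, 1440, n)
        ej = (ei + rng.integers(300, 1100, n)) % 1440
        dt = rng.uniform(-3, 3, n)
        lors = make_lors(RING, ei, ej, dt=dt)
        pts, _ = tof_locate(lors)
        A, B = lors.endpoints()
        mid = (A + B) / 2
        half = np.linalg.norm(B - A, axis=1) / 2
        off = np.linalg.norm(pts - mid, axis=1)
        assert np.all(off <= half + 1e-9)

    def test_reconstruction_mass(self):
        ph = uniform_phantom("air", half_size=10.0)
        lors = make_lors(RING, [0, 100], [720, 820], dt=[0.0, 0.01],
                         weight=[1.0, 2.0])
        img = tof_reconstruct(lors, ph, attenuation_correct=False)
        assert img.values.sum() == pytest.approx(3.0, rel=1e-6)


class TestFluenceCorrect:
    def test_unit_fluence_identity(self, water_phantom):
        img = Image.like_grid(water_phantom,
                              np.random.default_rng(0).random(water_phantom.shape))
        out = fluence_correct(img, np.ones(water_phantom.shape))
        assert np.allclose(out.values, img.values)
        assert out.normalization == "fluence-corrected"

    def test_constant_fluence_scales(self, water_phantom):
        img = Image.like_grid(water_phantom, np.ones(water_phantom.shape))
        out = fluence_correct(img, np.full(water_phantom.shape, 2.0))
        assert np.allclose(out.values, 0.5)

    def test_masked_fraction_bookkeeping(self, water_phantom):
        f = np.ones(water_phantom.shape)
        f[:10, :] = 1e-9  # far below the floor
        img = Image.like_grid(water_phantom, np.ones(water_phantom.shape))
        out = fluence_correct(img, f, floor=0.5)
        frac = 10 * water_phantom.shape[1] / f.size
        assert out.provenance["masked_fraction"] == pytest.approx(frac)
        assert np.all(out.values[:10, :] == 0.0)

    def test_grid_mismatch_rejected(self, water_phantom):
        img = Image.like_grid(water_phantom, np.ones(water_phantom.shape))
        with pytest.raises(ValueError):
            fluence_correct(img, np.ones((3, 3)))
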