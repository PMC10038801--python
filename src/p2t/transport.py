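"""Simplified Monte Carlo transport: primaries, positrons, annihilation.

Primaries fly in straight lines from the source; the free path to the first
interaction is sampled exactly from the inhomogeneous exponential law by
marching the voxel grid (Siddon-segment sampling) and the interaction type
is drawn with probabilities mu_i / mu_total at the interaction voxel.
Photoelectric and Compton interactions terminate the history (secondaries
are not tracked); only pair-production events propagate: the positron drifts
by a sampled 3D displacement, annihilates, and emits two back-to-back
511 keV photons in the imaging plane.

A forced-pair variance-reduction mode samples the interaction point from the
same analog law but always scores a pair event with statistical weight
mu_pp / mu_total, preserving every expectation while multiplying the usable
event yield.

The positron range law is a Weibull magnitude with scale linear in the
positron kinetic energy, calibrated (deterministically, by quantile
inversion) so the median 3D displacement in water over the pair-producing
10 MV photon population is 4.6 mm; magnitudes scale inversely with local
density.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from . import _kernels
from .image import Image
from .materials import (PAIR_THRESHOLD_MEV, CrossSectionModel, VoxelPhantom,
                        default_model, get_material)
from .spectrum import Spectrum, default_10mv_spectrum

__all__ = [
    "PairEvent", "Interaction", "PositronRangeModel",
    "trace_primary", "trace_primaries", "positron_displacement",
    "emit_annihilation_pair", "survival_weight", "tally_ground_truth",
    "compute_terma", "SPEED_OF_LIGHT_CM_NS",
]

SPEED_OF_LIGHT_CM_NS = 29.9792458  # cm/ns

_TYPE_NAMES = {0: "escape", 1: "photoelectric", 2: "compton", 3: "pair"}


@dataclass
class Interaction:
    kind: str           # photoelectric | compton | pair
    position: np.ndarray
    material_id: int
    path_length: float  # cm from the ray origin
    weight: float = 1.0


@dataclass
class PairEvent:
    """Arrays describing a batch of pair-production / annihilation events."""

    pp_position: np.ndarray       # (n, 2) pair-production location, cm
    t_plus: np.ndarray            # (n,) positron kinetic energy, MeV
    annihilation: np.ndarray      # (n, 2) annihilation point, cm
    displacement: np.ndarray      # (n,) 3D travel distance, cm
    time_ns: np.ndarray           # (n,) annihilation time
    beam: np.ndarray              # (n,) int
    pencil: np.ndarray            # (n,) int
    weight: np.ndarray            # (n,) statistical weight, > 0

    def __len__(self):
        return self.t_plus.size


# ---------------------------------------------------------------------------
# Primary tracing
# ---------------------------------------------------------------------------

def trace_primaries(origins, directions, energy_bins, phantom: VoxelPhantom,
                    rng: np.random.Generator, force_pair: bool = False):
    """Trace many primaries to their first interaction (or escape).

    ``energy_bins`` indexes the phantom spectrum's energy grid.  Returns
    (status, positions, material_ids, path_lengths, weights) with status
    0=escape, 1=photoelectric, 2=Compton, 3=pair.
    """
    O = np.ascontiguousarray(origins, dtype=float)
    D = np.ascontiguousarray(directions, dtype=float)
    if np.any(~np.isfinite(O)) or np.any(~np.isfinite(D)):
        raise ValueError("non-finite position or direction")
    n = O.shape[0]
    tables = phantom.mu_tables()
    tau = -np.log(rng.random(n))
    type_u = rng.random(n)
    return _kernels.trace_primaries_kernel(
        O, D, np.ascontiguousarray(energy_bins, dtype=np.int64), tau, type_u,
        tables["total"], tables["pair"], tables["compton"],
        phantom.material_index, phantom.origin[0], phantom.origin[1],
        phantom.spacing[0], phantom.spacing[1], 1 if force_pair else 0)


def trace_primary(origin, direction, energy: float, phantom: VoxelPhantom,
                  rng: np.random.Generator) -> Interaction | None:
    """Analog single-photon trace; returns None on escape."""
    direction = np.asarray(direction, dtype=float)
    nrm = np.linalg.norm(direction)
    if not np.isclose(nrm, 1.0, atol=1e-6):
        raise ValueError("direction must be unit-norm")
    if energy <= 0:
        raise ValueError("energy must be > 0")
    # nearest spectrum bin carries the energy dependence of the tables
    eb = int(np.argmin(np.abs(phantom.spectrum.energies - energy)))
    status, pos, mat, plen, w = trace_primaries(
        np.atleast_2d(origin), direction[None, :], np.array([eb]), phantom, rng)
    if status[0] == 0:
        return None
    return Interaction(_TYPE_NAMES[int(status[0])], pos[0], int(mat[0]),
                       float(plen[0]), float(w[0]))


# ---------------------------------------------------------------------------
# Positron range
# ---------------------------------------------------------------------------

@dataclass
class PositronRangeModel:
    """Weibull positron-range law calibrated on the in-water median.

    Travel distance R | T+  ~  Weibull(shape k, scale a * T+), with the
    single coefficient ``a`` solved so that the median R over the
    pair-producing photon population of ``spectrum`` in water equals
    ``median_target_cm``.  Magnitudes scale as rho_water / rho.
    """

    shape: float = 1.35
    median_target_cm: float = 0.46
    spectrum: Spectrum = field(default_factory=default_10mv_spectrum)
    model: CrossSectionModel | None = None
    _scale: float | None = field(default=None, repr=False)

    def _pair_energy_weights(self) -> np.ndarray:
        """Spectrum weights of photons at their pair-production events."""
        model = self.model or default_model()
        water = get_material("water")
        w = self.spectrum.probabilities * model.mu_pair(water, self.spectrum.energies)
        total = w.sum()
        if total <= 0:
            raise ValueError("spectrum has no pair-producing component")
        return w / total

    def t_plus_population(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Sample positron kinetic energies T+ of pair events in water.

        The photon energy is drawn from the spectrum weighted by the
        pair-production coefficient; the available energy hv - 1.022 MeV is
        split uniformly (the Bethe-Heitler partition is nearly flat)."""
        w = self._pair_energy_weights()
        e = rng.choice(self.spectrum.energies, size=n, p=w)
        return rng.random(n) * (e - PAIR_THRESHOLD_MEV)

    @property
    def scale_cm_per_mev(self) -> float:
        """Calibrated scale coefficient ``a`` (cm/MeV), solved on demand."""
        if self._scale is None:
            w = self._pair_energy_weights()
            emax = self.spectrum.energies - PAIR_THRESHOLD_MEV
            ok = emax > 0  # only pair-producing bins carry weight
            w = w[ok]
            u = (np.arange(400) + 0.5) / 400.0  # uniform T+ partition nodes
            t_grid = emax[ok, None] * u[None, :]  # (bins, nodes)

            def cdf_at_median(a):
                with np.errstate(divide="ignore"):
                    z = (self.median_target_cm / (a * t_grid)) ** self.shape
                cdf = 1.0 - np.exp(-z)  # t -> 0 gives cdf -> 1
                return float(np.sum(w * cdf.mean(axis=1))) - 0.5

            self._scale = brentq(cdf_at_median, 1e-4, 100.0, xtol=1e-12)
        return self._scale

    def sample_magnitude(self, t_plus: np.ndarray, density,
                         rng: np.random.Generator) -> np.ndarray:
        """3D travel distances (cm) for positron energies in a medium of
        the given density (g/cm^3, water-relative inverse scaling)."""
        t_plus = np.asarray(t_plus, dtype=float)
        rho = np.asarray(density, dtype=float)
        if np.any(rho <= 0):
            raise ValueError("positron range undefined at zero density")
        base = self.scale_cm_per_mev * t_plus * rng.weibull(self.shape, t_plus.shape)
        return base / rho


def positron_displacement(t_plus, density, rng: np.random.Generator,
                          model: PositronRangeModel | None = None) -> np.ndarray:
    """Isotropic 3D displacement vectors (n, 3) of positrons before
    annihilation; magnitudes from the calibrated range law."""
    model = model or PositronRangeModel()
    t_plus = np.atleast_1d(np.asarray(t_plus, dtype=float))
    mag = model.sample_magnitude(t_plus, density, rng)
    v = rng.normal(size=(t_plus.size, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return v * mag[:, None]


# ---------------------------------------------------------------------------
# Annihilation photons
# ---------------------------------------------------------------------------

def emit_annihilation_pair(n: int, rng: np.random.Generator):
    """In-plane isotropic emission directions for ``n`` annihilations.

    Returns (u, -u, energy): two exactly antiparallel unit vectors per event
    and the common 0.511 MeV photon energy.
    """
    psi = rng.uniform(0.0, 2.0 * np.pi, size=n)
    u = np.column_stack([np.cos(psi), np.sin(psi)])
    return u, -u, 0.511


def survival_weight(points, directions, phantom: VoxelPhantom,
                    reach: float = 400.0) -> np.ndarray:
    """Escape probability exp(-int mu_511 dl) from each point along its ray.

    The integral runs from the point to the grid exit; ``reach`` just has to
    exceed the grid diagonal.
    """
    P = np.atleast_2d(np.asarray(points, dtype=float))
    D = np.atleast_2d(np.asarray(directions, dtype=float))
    integ = _kernels.line_integrals(
        np.ascontiguousarray(P), np.ascontiguousarray(P + reach * D),
        np.ascontiguousarray(phantom.mu511, dtype=float),
        phantom.origin[0], phantom.origin[1],
        phantom.spacing[0], phantom.spacing[1])
    return np.exp(-integ)


# ---------------------------------------------------------------------------
# Tallies
# ---------------------------------------------------------------------------

def tally_ground_truth(points: np.ndarray, weights: np.ndarray,
                       grid: VoxelPhantom) -> Image:
    """Voxel-wise weighted tally of annihilation points (the GT image).

    Events outside the grid are dropped; their count is recorded in the
    image provenance.
    """
    points = np.atleast_2d(points)
    weights = np.broadcast_to(np.asarray(weights, dtype=float), points.shape[:1])
    ny, nx = grid.shape
    xmin, xmax, ymin, ymax = grid.extent
    inside = ((points[:, 0] >= xmin) & (points[:, 0] < xmax)
              & (points[:, 1] >= ymin) & (points[:, 1] < ymax))
    hist, _, _ = np.histogram2d(
        points[inside, 1], points[inside, 0],
        bins=(ny, nx), range=((ymin, ymax), (xmin, xmax)),
        weights=weights[inside])
    return Image.like_grid(grid, hist,
                           provenance={"method": "GT",
                                       "dropped_events": int(np.sum(~inside))})


def compute_terma(plan, phantom: VoxelPhantom, n_groups: int = 8,
                  blur_sigma_cm: float | None = None) -> Image:
    """TERMA map: sum over energy groups of f(E) * E * mu(E) / rho.

    Zero-density voxels are excluded (set to 0).  If ``blur_sigma_cm`` is
    given, the TERMA is convolved with an isotropic Gaussian as a documented
    dose surrogate for the finite range of secondary electrons.
    """
    from .beams import spectral_fluence_map
    energies, weights, maps = spectral_fluence_map(plan, phantom, n_groups)
    rho = phantom.density
    terma = np.zeros(phantom.shape)
    ok = rho > 0
    for e_g, w_g, f_g in zip(energies, weights, maps):
        mu_g = np.array([float(phantom.model.mu_total(m, e_g))
                         for m in phantom.materials])[phantom.material_index]
        terma[ok] += w_g * f_g[ok] * e_g * mu_g[ok] / rho[ok]
    prov = {"method": "TERMA", "n_groups": int(len(energies)),
            "zero_density_voxels": int(np.sum(~ok))}
    if blur_sigma_cm is not None:
        from scipy.ndimage import gaussian_filter
        terma = gaussian_filter(terma, sigma=blur_sigma_cm / phantom.spacing[0])
        prov["dose_surrogate_blur_cm"] = blur_sigma_cm
    return Image.like_grid(phantom, terma, provenance=prov)
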