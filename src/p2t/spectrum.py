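"""Binned bremsstrahlung energy spectra.

A ``Spectrum`` is a discrete probability distribution over photon energies
(MeV).  The default imaging/therapy beam is a 10 MV bremsstrahlung spectrum:
the analytic thick-target shape f(E) ~ (E_max - E)/E, truncated below 0.2 MeV
(soft photons that never reach the patient through flattening filter and
collimator) and binned at 0.1 MeV.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Spectrum", "default_10mv_spectrum", "monoenergetic"]


@dataclass(frozen=True)
class Spectrum:
    """Discrete photon-energy spectrum on a fixed grid.

    Parameters
    ----------
    energies:
        Bin-centre energies in MeV, strictly increasing, all > 0.
    probabilities:
        Per-bin emission probability; non-negative, sums to 1.
    endpoint:
        Maximum (accelerating-potential) energy in MeV.
    """

    energies: np.ndarray
    probabilities: np.ndarray
    endpoint: float = 10.0
    _cdf: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        e = np.asarray(self.energies, dtype=float)
        p = np.asarray(self.probabilities, dtype=float)
        if e.size == 0:
            raise ValueError("empty spectrum")
        if e.shape != p.shape:
            raise ValueError("energies and probabilities must match in shape")
        if np.any(e <= 0) or np.any(e > self.endpoint + 1e-12):
            raise ValueError("spectrum support must lie in (0, endpoint]")
        if np.any(p < 0):
            raise ValueError("probabilities must be non-negative")
        s = p.sum()
        if not np.isfinite(s) or s <= 0:
            raise ValueError("probabilities must have positive sum")
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "probabilities", p / s)
        object.__setattr__(self, "_cdf", np.cumsum(p / s))

    @property
    def n_bins(self) -> int:
        return self.energies.size

    def mean(self) -> float:
        """Fluence-weighted mean energy (MeV)."""
        return float(np.sum(self.energies * self.probabilities))

    def energy_fluence_weights(self) -> np.ndarray:
        """Per-bin energy-fluence weights p(E)*E, normalised to sum to 1.

        These weight the penetrating part of the beam and are used for
        beam-effective attenuation coefficients and TERMA-style averages.
        """
        w = self.probabilities * self.energies
        return w / w.sum()

    def sample_bins(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` i.i.d. bin indices from the spectrum."""
        if n < 0:
            raise ValueError("n must be non-negative")
        u = rng.random(n)
        return np.searchsorted(self._cdf, u, side="right").clip(0, self.n_bins - 1)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` i.i.d. photon energies (MeV) from the binned spectrum."""
        return self.energies[self.sample_bins(n, rng)]


def default_10mv_spectrum(endpoint: float = 10.0, e_min: float = 0.2,
                          bin_width: float = 0.1) -> Spectrum:
    """Analytic thick-target 10 MV bremsstrahlung spectrum.

    f(E) proportional to (endpoint - E)/E on [e_min, endpoint], binned at
    ``bin_width`` MeV (bin centres).
    """
    edges = np.arange(e_min, endpoint + 0.5 * bin_width, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    p = (endpoint - centers) / centers
    p = np.clip(p, 0.0, None)
    return Spectrum(centers, p, endpoint=endpoint)


def monoenergetic(energy: float) -> Spectrum:
    """Single-line spectrum (useful for tests and calibration)."""
    return Spectrum(np.array([energy]), np.array([1.0]), endpoint=energy)
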