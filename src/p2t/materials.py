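"""Elements, materials, attenuation models and voxel phantoms.

The imaging signal in pair-production tomography is governed by the
pair-production attenuation coefficient, which is proportional to rho * Z_eff
with Z_eff the weight-fraction-weighted mean atomic number (Bragg additivity).
This module provides:

* an element table (Z, A, bulk density) and named material compositions
  (standard tissue-substitute compositions plus 5 %-by-weight high-Z aqueous
  solutions),
* a three-channel parametric cross-section model (photoelectric, Compton,
  pair production) with the correct proportionalities in rho, Z_eff and
  energy thresholds — absolute scales are arbitrary and calibrated to
  textbook water magnitudes,
* 2D voxel phantoms with derived density / Z_eff / attenuation maps, and the
  elliptical fixture phantoms used throughout.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .spectrum import Spectrum, default_10mv_spectrum

__all__ = [
    "Element", "Material", "CrossSectionModel", "VoxelPhantom",
    "ELEMENTS", "get_material", "material_names", "high_z_solution",
    "effective_atomic_number", "attenuation_coefficient",
    "bragg_additivity_contrast", "build_elliptical_phantom",
    "nanoparticle_phantom", "tissue_phantom", "uniform_phantom",
    "default_model", "insert_layout", "load_materials_csv",
    "PAIR_THRESHOLD_MEV", "NANOPARTICLE_LAYOUT", "TISSUE_LAYOUT",
]

#: Pair-production threshold 2*m0*c^2 (MeV).
PAIR_THRESHOLD_MEV = 1.022


@dataclass(frozen=True)
class Element:
    symbol: str
    Z: int
    A: float
    density: float  # bulk density, g/cm^3

    def __post_init__(self):
        if self.Z < 1:
            raise ValueError(f"Z must be >= 1, got {self.Z}")
        if self.A <= 0:
            raise ValueError(f"A must be > 0, got {self.A}")


def _load_elements() -> dict[str, Element]:
    with resources.files("p2t.data").joinpath("elements.csv").open() as fh:
        df = pd.read_csv(fh)
    table = {}
    for row in df.itertuples(index=False):
        if row.symbol in table:
            raise ValueError(f"duplicate element symbol {row.symbol!r}")
        table[row.symbol] = Element(row.symbol, int(row.Z), float(row.A),
                                    float(row.density_g_cm3))
    return table


ELEMENTS: dict[str, Element] = _load_elements()


@dataclass(frozen=True)
class Material:
    """A compound or mixture: mass density plus elemental weight fractions."""

    name: str
    density: float  # g/cm^3
    fractions: Mapping[str, float]

    def __post_init__(self):
        if self.density < 0:
            raise ValueError(f"density must be >= 0, got {self.density}")
        for sym, f in self.fractions.items():
            if sym not in ELEMENTS:
                raise KeyError(f"unknown element symbol {sym!r}")
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"weight fraction of {sym} out of [0,1]: {f}")
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"weight fractions of {self.name!r} sum to {total}, not 1")
        object.__setattr__(self, "fractions", dict(self.fractions))

    @property
    def zeff(self) -> float:
        return effective_atomic_number(self)


def effective_atomic_number(material: Material) -> float:
    """Effective atomic number Z_eff = sum_i Z_i f_i (Bragg additivity).

    The weight-fraction-weighted mean atomic number governs the
    pair-production mass attenuation of a compound, so the fluence-corrected
    image intensity is proportional to rho * Z_eff.
    """
    return float(sum(ELEMENTS[sym].Z * f for sym, f in material.fractions.items()))


def bragg_additivity_contrast(material: Material, reference: Material) -> float:
    """Theoretical relative image contrast of ``material`` against ``reference``.

    Returns (rho*Z_eff - rho_ref*Z_eff_ref) / (rho_ref*Z_eff_ref), the
    increment in rho*Z_eff relative to the reference material.
    """
    if reference.density <= 0:
        raise ValueError("reference density must be > 0")
    ref = reference.density * reference.zeff
    return (material.density * material.zeff - ref) / ref


def _parse_composition(text: str) -> dict[str, float]:
    out: dict[str, float] = {}
    for token in text.split():
        sym, frac = token.split(":")
        out[sym] = float(frac)
    return out


def _load_materials() -> dict[str, Material]:
    with resources.files("p2t.data").joinpath("materials.csv").open() as fh:
        df = pd.read_csv(fh)
    table = {}
    for row in df.itertuples(index=False):
        frac = _parse_composition(row.composition)
        # Source tables carry whole-0.1% fractions; renormalise the residual
        # rounding so the Sum(f_i)=1 invariant holds exactly.
        total = sum(frac.values())
        frac = {k: v / total for k, v in frac.items()}
        table[row.name] = Material(row.name, float(row.density_g_cm3), frac)
    return table


_MATERIALS: dict[str, Material] = _load_materials()


def get_material(name: str) -> Material:
    try:
        return _MATERIALS[name]
    except KeyError:
        raise KeyError(f"unknown material {name!r}; known: {sorted(_MATERIALS)}")


def material_names() -> list[str]:
    return sorted(_MATERIALS)


def load_materials_csv(path) -> dict[str, Material]:
    """Load a user materials table (columns: name, density_g_cm3, composition)."""
    df = pd.read_csv(path)
    out = {}
    for row in df.itertuples(index=False):
        out[row.name] = Material(row.name, float(row.density_g_cm3),
                                 _parse_composition(row.composition))
    return out


def high_z_solution(symbol: str, weight_fraction: float = 0.05,
                    solvent: Material | None = None) -> Material:
    """Aqueous solution of a high-Z element at the given weight fraction.

    Density follows ideal volume additivity,
    rho = 1 / (w/rho_elem + (1-w)/rho_solvent), matching the nanoparticle
    inserts (5 % element, 95 % water by weight).
    """
    if symbol not in ELEMENTS:
        raise KeyError(f"unknown element symbol {symbol!r}")
    solvent = solvent or get_material("water")
    w = float(weight_fraction)
    if not 0 < w < 1:
        raise ValueError("weight_fraction must be in (0,1)")
    rho = 1.0 / (w / ELEMENTS[symbol].density + (1 - w) / solvent.density)
    fractions = {sym: f * (1 - w) for sym, f in solvent.fractions.items()}
    fractions[symbol] = fractions.get(symbol, 0.0) + w
    return Material(f"{symbol.lower()}_{w:g}_solution", rho, fractions)


# ---------------------------------------------------------------------------
# Cross-section model
# ---------------------------------------------------------------------------

def _compton_shape(E):
    """Energy dependence of the Compton coefficient, normalised to 1 at 511 keV.

    Power-law fit of the Klein-Nishina-driven decline of the water Compton
    mass attenuation between 0.511 and 10 MeV.
    """
    return np.power(np.asarray(E, dtype=float) / 0.511, -0.574)


def _pp_shape(E):
    """Energy dependence of pair production: zero below 1.022 MeV, then a
    slightly superlinear rise in the energy excess over threshold."""
    excess = np.clip(np.asarray(E, dtype=float) - PAIR_THRESHOLD_MEV, 0.0, None)
    return np.power(excess, 1.25)


@dataclass(frozen=True)
class CrossSectionModel:
    """Parametric three-channel attenuation model.

    mu_pe      = pe_scale      * rho * Z_eff**pe_exponent / E**3
    mu_compton = compton_scale * rho * compton_shape(E)
    mu_pp      = pp_scale      * rho * Z_eff * pp_shape(E)   (0 below 1.022 MeV)

    The Compton channel uses a single global electron-density proxy
    proportional to rho (Z/A treated as a material-independent constant);
    only proportionalities matter because all images are normalised.
    Absolute scales are calibrated by :meth:`default` so that
    mu_total(water, 10 MV effective) ~ 0.05 /cm and mu(water, 511 keV)
    ~ 0.096 /cm, textbook magnitudes that keep attenuation-correction
    factors realistic.
    """

    pp_scale: float
    compton_scale: float
    pe_scale: float
    pe_exponent: float = 3.0

    def __post_init__(self):
        if self.pp_scale <= 0 or self.compton_scale <= 0 or self.pe_scale <= 0:
            raise ValueError("all cross-section scales must be > 0")

    # -- per-channel coefficients (1/cm), vectorised over E -----------------
    def mu_photoelectric(self, material: Material, E) -> np.ndarray:
        if material.density < 0:
            raise ValueError("negative density")
        E = np.asarray(E, dtype=float)
        if np.any(E <= 0):
            raise ValueError("energy must be > 0")
        return (self.pe_scale * material.density
                * material.zeff ** self.pe_exponent / E ** 3)

    def mu_compton(self, material: Material, E) -> np.ndarray:
        E = np.asarray(E, dtype=float)
        if np.any(E <= 0):
            raise ValueError("energy must be > 0")
        return self.compton_scale * material.density * _compton_shape(E)

    def mu_pair(self, material: Material, E) -> np.ndarray:
        E = np.asarray(E, dtype=float)
        return self.pp_scale * material.density * material.zeff * _pp_shape(E)

    def mu_total(self, material: Material, E) -> np.ndarray:
        return (self.mu_photoelectric(material, E)
                + self.mu_compton(material, E)
                + self.mu_pair(material, E))

    def mu_effective(self, material: Material, spectrum: Spectrum) -> float:
        """Beam-effective total attenuation (1/cm) for a poly-energetic beam.

        Energy-fluence weighting (p(E)*E) is used: over a soft bremsstrahlung
        spectrum plain fluence weighting over-weights the low-energy photons
        that are removed within the first centimetres, whereas the
        energy-fluence average tracks the penetrating component whose
        attenuation the correction models (broad-beam effective mu of water
        for a 10 MV beam is ~0.05 /cm).
        """
        w = spectrum.energy_fluence_weights()
        return float(np.sum(w * self.mu_total(material, spectrum.energies)))

    def mu_pair_effective(self, material: Material, spectrum: Spectrum) -> float:
        """Energy-fluence-weighted pair-production coefficient (1/cm)."""
        w = spectrum.energy_fluence_weights()
        return float(np.sum(w * self.mu_pair(material, spectrum.energies)))

    @classmethod
    def default(cls, spectrum: Spectrum | None = None) -> "CrossSectionModel":
        """Calibrated default model (deterministic, computed on demand)."""
        spectrum = spectrum or default_10mv_spectrum()
        water = get_material("water")
        zw = water.zeff
        pe_scale = 7e-9  # keeps the photoelectric channel negligible above 0.2 MeV
        mu_pe_511 = pe_scale * zw ** 3 / 0.511 ** 3
        compton_scale = (0.096 - mu_pe_511) / float(_compton_shape(0.511))
        # choose pp_scale so the water beam-effective total is 0.05 /cm
        w = spectrum.energy_fluence_weights()
        E = spectrum.energies
        mu_ce = compton_scale * float(np.sum(w * _compton_shape(E)))
        mu_pee = pe_scale * zw ** 3 * float(np.sum(w / E ** 3))
        residual = 0.05 - mu_ce - mu_pee
        if residual <= 0:
            raise RuntimeError("cross-section calibration failed: Compton "
                               "channel already exceeds the water target")
        s_pp = float(np.sum(w * _pp_shape(E)))
        pp_scale = residual / (zw * s_pp)
        return cls(pp_scale=pp_scale, compton_scale=compton_scale,
                   pe_scale=pe_scale)


_DEFAULT_MODEL: CrossSectionModel | None = None


def default_model() -> CrossSectionModel:
    global _DEFAULT_MODEL
    if _DEFAULT_MODEL is None:
        _DEFAULT_MODEL = CrossSectionModel.default()
    return _DEFAULT_MODEL


def attenuation_coefficient(material: Material, channel,
                            model: CrossSectionModel | None = None,
                            spectrum: Spectrum | None = None) -> float:
    """Total attenuation coefficient (1/cm) for a named channel.

    ``channel`` is ``"511keV"``, ``"10MV"`` (beam-effective over the default
    or supplied spectrum) or a photon energy in MeV.
    """
    model = model or default_model()
    if channel == "511keV":
        return float(model.mu_total(material, 0.511))
    if channel == "10MV":
        return model.mu_effective(material, spectrum or default_10mv_spectrum())
    return float(model.mu_total(material, float(channel)))


# ---------------------------------------------------------------------------
# Voxel phantoms
# ---------------------------------------------------------------------------

class VoxelPhantom:
    """2D axial voxel phantom (one slice; the slab thickness is metadata).

    Voxels use 0-based indices with half-open extents
    [origin + i*spacing, origin + (i+1)*spacing); arrays are indexed
    ``[iy, ix]``.  Derived maps (density, Z_eff, attenuation) are pure
    functions of the material index map and the material table, rebuilt
    deterministically on demand.
    """

    def __init__(self, origin, spacing, material_index: np.ndarray,
                 materials: Sequence[Material], slab_thickness: float = 10.0,
                 body_ellipse: tuple | None = None,
                 model: CrossSectionModel | None = None,
                 spectrum: Spectrum | None = None):
        self.origin = np.asarray(origin, dtype=float)        # (x0, y0)
        self.spacing = np.asarray(spacing, dtype=float)      # (dx, dy)
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be > 0")
        self.material_index = np.asarray(material_index, dtype=np.int16)
        if self.material_index.ndim != 2:
            raise ValueError("material_index must be 2D (ny, nx)")
        if self.material_index.min() < 0 or self.material_index.max() >= len(materials):
            raise ValueError("material_index out of range of material table")
        self.materials = list(materials)
        self.slab_thickness = float(slab_thickness)
        self.body_ellipse = body_ellipse  # (cx, cy, semi_x, semi_y)
        self.model = model or default_model()
        self.spectrum = spectrum or default_10mv_spectrum()
        self._cache: dict[str, np.ndarray] = {}

    # -- geometry ----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.material_index.shape  # (ny, nx)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of the grid bounding box."""
        ny, nx = self.shape
        return (self.origin[0], self.origin[0] + nx * self.spacing[0],
                self.origin[1], self.origin[1] + ny * self.spacing[1])

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) centre coordinate vectors."""
        ny, nx = self.shape
        x = self.origin[0] + (np.arange(nx) + 0.5) * self.spacing[0]
        y = self.origin[1] + (np.arange(ny) + 0.5) * self.spacing[1]
        return x, y

    def center_grids(self) -> tuple[np.ndarray, np.ndarray]:
        x, y = self.voxel_centers()
        return np.meshgrid(x, y)

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Map (n,2) world points to (n,2) integer (ix, iy); no bounds check."""
        p = np.atleast_2d(points)
        return np.floor((p - self.origin) / self.spacing).astype(np.int64)

    # -- material property tables -----------------------------------------
    def _per_material(self, fn) -> np.ndarray:
        return np.array([fn(m) for m in self.materials], dtype=float)

    def _map(self, key: str, fn) -> np.ndarray:
        if key not in self._cache:
            self._cache[key] = self._per_material(fn)[self.material_index]
        return self._cache[key]

    @property
    def density(self) -> np.ndarray:
        return self._map("density", lambda m: m.density)

    @property
    def zeff(self) -> np.ndarray:
        return self._map("zeff", lambda m: m.zeff)

    @property
    def mu511(self) -> np.ndarray:
        return self._map("mu511", lambda m: float(self.model.mu_total(m, 0.511)))

    @property
    def mu10mv(self) -> np.ndarray:
        return self._map("mu10mv",
                         lambda m: self.model.mu_effective(m, self.spectrum))

    @property
    def alpha_pp(self) -> np.ndarray:
        """Beam-effective pair-production coefficient map (1/cm)."""
        return self._map("alpha_pp",
                         lambda m: self.model.mu_pair_effective(m, self.spectrum))

    def mu_tables(self) -> dict[str, np.ndarray]:
        """Per-(spectrum bin, material) coefficient tables for transport.

        Returns arrays of shape (n_bins, n_materials) for the total,
        pair-production, Compton and photoelectric channels.
        """
        if "tables" not in self._cache:
            E = self.spectrum.energies
            pe = np.stack([self.model.mu_photoelectric(m, E) for m in self.materials], axis=1)
            co = np.stack([self.model.mu_compton(m, E) for m in self.materials], axis=1)
            pp = np.stack([self.model.mu_pair(m, E) for m in self.materials], axis=1)
            self._cache["tables"] = {
                "total": pe + co + pp, "pair": pp, "compton": co, "photoelectric": pe,
            }
        return self._cache["tables"]

    def material_map(self, name: str) -> np.ndarray:
        """Boolean mask of voxels made of the named material."""
        idx = [i for i, m in enumerate(self.materials) if m.name == name]
        if not idx:
            raise KeyError(f"material {name!r} not in phantom")
        return np.isin(self.material_index, idx)

    # -- IO -----------------------------------------------------------------
    def save(self, path_prefix: str) -> None:
        """Save as raw array + JSON sidecar."""
        np.save(f"{path_prefix}.npy", self.material_index)
        meta = {
            "origin": self.origin.tolist(),
            "spacing": self.spacing.tolist(),
            "slab_thickness": self.slab_thickness,
            "body_ellipse": list(self.body_ellipse) if self.body_ellipse else None,
            "materials": [
                {"name": m.name, "density": m.density, "fractions": m.fractions}
                for m in self.materials
            ],
        }
        with open(f"{path_prefix}.json", "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def load(cls, path_prefix: str) -> "VoxelPhantom":
        arr = np.load(f"{path_prefix}.npy")
        with open(f"{path_prefix}.json") as fh:
            meta = json.load(fh)
        mats = [Material(m["name"], m["density"], m["fractions"])
                for m in meta["materials"]]
        ell = meta.get("body_ellipse")
        return cls(meta["origin"], meta["spacing"], arr, mats,
                   slab_thickness=meta["slab_thickness"],
                   body_ellipse=tuple(ell) if ell else None)


def build_elliptical_phantom(
    minor: float = 20.0,
    major: float = 24.0,
    inserts: Iterable[tuple[tuple[float, float], float, Material]] = (),
    spacing: float = 0.2,
    body: Material | None = None,
    outside: Material | None = None,
    margin: float = 0.4,
) -> VoxelPhantom:
    """Elliptical body phantom with circular inserts.

    ``minor``/``major`` are full axis lengths (cm); the major axis lies along
    x.  ``inserts`` is an iterable of ((cx, cy), radius, material); inserts
    must lie inside the ellipse and must not overlap.
    """
    body = body or get_material("water")
    outside = outside or get_material("air")
    a, b = major / 2.0, minor / 2.0
    half_x = a + margin
    half_y = b + margin
    nx = int(np.ceil(2 * half_x / spacing))
    ny = int(np.ceil(2 * half_y / spacing))
    origin = (-nx * spacing / 2.0, -ny * spacing / 2.0)

    materials: list[Material] = [outside, body]
    index = np.zeros((ny, nx), dtype=np.int16)
    x = origin[0] + (np.arange(nx) + 0.5) * spacing
    y = origin[1] + (np.arange(ny) + 0.5) * spacing
    xx, yy = np.meshgrid(x, y)
    inside = (xx / a) ** 2 + (yy / b) ** 2 <= 1.0
    index[inside] = 1

    claimed = np.zeros_like(index, dtype=bool)
    for (cx, cy), radius, mat in inserts:
        if radius <= 0:
            raise ValueError("insert radius must be > 0")
        # farthest point of the insert must stay inside the ellipse
        r_dir = np.hypot(cx / a, cy / b)
        if r_dir > 0:
            scale = (np.hypot(cx, cy) + radius) / np.hypot(cx, cy)
        else:
            scale = 1.0
        if ((scale * cx / a) ** 2 + (scale * cy / b) ** 2) > 1.0 + 1e-9:
            raise ValueError(f"insert {mat.name!r} at ({cx},{cy}) r={radius} "
                             "extends outside the body ellipse")
        mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius ** 2
        if np.any(mask & claimed):
            raise ValueError(f"insert {mat.name!r} overlaps a previous insert")
        claimed |= mask
        materials.append(mat)
        index[mask] = len(materials) - 1

    return VoxelPhantom(origin, (spacing, spacing), index, materials,
                        body_ellipse=(0.0, 0.0, a, b))


#: (label, angle deg) layout of the 10 insert positions, counter-clockwise
#: from +x; the three bottom slots (234, 270, 306) host the partial-view ROI.
_INSERT_ANGLES_DEG = (18, 54, 90, 126, 162, 198, 234, 270, 306, 342)
INSERT_RING_SCALE = 0.64
DEFAULT_INSERT_RADIUS = 1.75


def _insert_centers(a: float = 12.0, b: float = 10.0) -> list[tuple[float, float]]:
    out = []
    for ang in _INSERT_ANGLES_DEG:
        t = np.deg2rad(ang)
        out.append((INSERT_RING_SCALE * a * np.cos(t),
                    INSERT_RING_SCALE * b * np.sin(t)))
    return out


#: slot -> material for the high-Z nanoparticle phantom; the bottom three
#: slots are iodine, ytterbium and bismuth (left to right), mirroring the
#: partial-view region of interest.
NANOPARTICLE_LAYOUT = ("water", "Ba", "Gd", "Ta", "Au", "water_b",
                       "I", "Yb", "Bi", "water_c")

TISSUE_LAYOUT = ("water", "muscle", "liver", "trabecular_bone", "dense_bone",
                 "air_insert", "lung_inhale", "lung_exhale", "adipose", "breast")


def nanoparticle_phantom(spacing: float = 0.2,
                         insert_radius: float = DEFAULT_INSERT_RADIUS) -> VoxelPhantom:
    """Elliptical water phantom with 7 high-Z 5 %-solution inserts + 3 water.

    High-Z elements span Z = 53..83 (I, Ba, Gd, Yb, Ta, Au, Bi).
    """
    centers = _insert_centers()
    inserts = []
    water = get_material("water")
    for slot, (cx, cy) in zip(NANOPARTICLE_LAYOUT, centers):
        if slot.startswith("water"):
            mat = Material(slot if slot != "water" else "water_insert",
                           water.density, water.fractions)
        else:
            mat = high_z_solution(slot, 0.05)
        inserts.append(((cx, cy), insert_radius, mat))
    return build_elliptical_phantom(inserts=inserts, spacing=spacing)


def tissue_phantom(spacing: float = 0.2,
                   insert_radius: float = DEFAULT_INSERT_RADIUS) -> VoxelPhantom:
    """Elliptical water phantom with 10 tissue-substitute inserts."""
    centers = _insert_centers()
    inserts = []
    for slot, (cx, cy) in zip(TISSUE_LAYOUT, centers):
        if slot == "water":
            w = get_material("water")
            mat = Material("water_insert", w.density, w.fractions)
        elif slot == "air_insert":
            a = get_material("air")
            mat = Material("air_insert", a.density, a.fractions)
        else:
            mat = get_material(slot)
        inserts.append(((cx, cy), insert_radius, mat))
    return build_elliptical_phantom(inserts=inserts, spacing=spacing)


def insert_layout(phantom_kind: str = "nanoparticle") -> dict[str, tuple[float, float]]:
    """Insert label -> centre coordinates for the fixture phantoms."""
    layout = NANOPARTICLE_LAYOUT if phantom_kind == "nanoparticle" else TISSUE_LAYOUT
    return dict(zip(layout, _insert_centers()))


def uniform_phantom(material: Material | str = "water", half_size: float = 10.0,
                    spacing: float = 0.2, disk_radius: float | None = None) -> VoxelPhantom:
    """Square phantom, either uniform or a centred disk in air."""
    if isinstance(material, str):
        material = get_material(material)
    n = int(np.ceil(2 * half_size / spacing))
    origin = (-n * spacing / 2.0, -n * spacing / 2.0)
    air = get_material("air")
    if disk_radius is None:
        index = np.ones((n, n), dtype=np.int16)
    else:
        x = origin[0] + (np.arange(n) + 0.5) * spacing
        xx, yy = np.meshgrid(x, x)
        index = (xx ** 2 + yy ** 2 <= disk_radius ** 2).astype(np.int16)
    return VoxelPhantom(origin, (spacing, spacing), index, [air, material],
                        body_ellipse=(0.0, 0.0,
                                      disk_radius or half_size,
                                      disk_radius or half_size))
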