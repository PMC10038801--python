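"""Image container shared by the transport tally and the reconstructions."""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["Image"]

NORMALIZATION_TAGS = ("raw", "water-insert", "target-mean", "fluence-corrected")


@dataclass
class Image:
    """Values on a 2D voxel grid with spacing metadata and provenance.

    ``normalization`` records how the values are scaled ("raw" counts,
    "fluence-corrected", or normalised to a reference ROI); ``provenance``
    carries the producing method, seed and applied corrections.
    """

    values: np.ndarray
    origin: np.ndarray
    spacing: np.ndarray
    normalization: str = "raw"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("image values must be 2D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image contains non-finite values")
        if self.normalization not in NORMALIZATION_TAGS:
            raise ValueError(f"unknown normalization tag {self.normalization!r}")

    @classmethod
    def like_grid(cls, grid, values: np.ndarray | None = None, **kw) -> "Image":
        """Build an image on the same grid as a phantom/other image."""
        v = np.zeros(grid.shape) if values is None else values
        return cls(v, grid.origin.copy(), grid.spacing.copy(), **kw)

    @property
    def shape(self):
        return self.values.shape

    def with_values(self, values: np.ndarray, normalization: str | None = None,
                    **extra_provenance) -> "Image":
        prov = dict(self.provenance, **extra_provenance)
        return Image(values, self.origin.copy(), self.spacing.copy(),
                     normalization or self.normalization, prov)

    def voxel_centers(self):
        ny, nx = self.shape
        x = self.origin[0] + (np.arange(nx) + 0.5) * self.spacing[0]
        y = self.origin[1] + (np.arange(ny) + 0.5) * self.spacing[1]
        return x, y

    def roi_mask(self, center, radius) -> np.ndarray:
        """Boolean mask of voxels whose centres fall in a circular ROI."""
        x, y = self.voxel_centers()
        xx, yy = np.meshgrid(x, y)
        return (xx - center[0]) ** 2 + (yy - center[1]) ** 2 <= radius ** 2

    def save(self, path_prefix: str) -> None:
        np.save(f"{path_prefix}.npy", self.values)
        meta = {"origin": self.origin.tolist(), "spacing": self.spacing.tolist(),
                "normalization": self.normalization,
                "provenance": {k: str(v) for k, v in self.provenance.items()}}
        with open(f"{path_prefix}.json", "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def load(cls, path_prefix: str) -> "Image":
        values = np.load(f"{path_prefix}.npy")
        with open(f"{path_prefix}.json") as fh:
            meta = json.load(fh)
        return cls(values, meta["origin"], meta["spacing"],
                   meta["normalization"], meta.get("provenance", {}))

    def to_nifti(self, path: str) -> None:
        """Optional NIfTI export (requires nibabel)."""
        import nibabel as nib
        affine = np.diag([self.spacing[0], self.spacing[1], 1.0, 1.0])
        affine[:2, 3] = self.origin
        nib.save(nib.Nifti1Image(self.values.T[..., None], affine), path)
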