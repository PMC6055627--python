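"""Grey matter density volumes and integer-labelled parcellations.

Volumes hold voxelwise grey matter density in [0, 1] on a regular grid in
native space.  I/O goes through NIfTI-1 (nibabel); the affine is diagonal,
built from the voxel size and origin — no oblique geometry is supported
because the extraction never leaves voxel space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["GreyMatterVolume", "AtlasParcellation"]


@dataclass
class GreyMatterVolume:
    """A 3D grey matter density map with voxel geometry.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Grey matter density per voxel, in [0, 1], finite everywhere.
    voxel_size_mm : tuple of float
        Physical edge lengths of one voxel in mm.
    origin : tuple of float
        World-space offset of voxel (0, 0, 0).
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"data must be 3-dimensional, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        if self.data.min() < 0 or self.data.max() > 1:
            raise ValueError("grey matter densities must lie in [0, 1]")
        if len(self.voxel_size_mm) != 3 or any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel_size_mm must be 3 positive lengths")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres (mm^3 / 1000)."""
        return float(np.prod(self.voxel_size_mm)) / 1000.0

    @property
    def total_gm_volume_ml(self) -> float:
        """Total grey matter volume: sum of densities times voxel volume."""
        return float(self.data.sum()) * self.voxel_volume_ml

    def _affine(self) -> np.ndarray:
        aff = np.diag(list(self.voxel_size_mm) + [1.0])
        aff[:3, 3] = self.origin
        return aff

    def save(self, path) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), self._affine()), str(path))

    @classmethod
    def load(cls, path) -> "GreyMatterVolume":
        img = nib.load(str(path))
        data = np.clip(np.asanyarray(img.dataobj, dtype=float), 0.0, 1.0)
        zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
        origin = tuple(float(v) for v in img.affine[:3, 3])
        return cls(data=data, voxel_size_mm=zooms, origin=origin)


@dataclass
class AtlasParcellation:
    """Integer-labelled parcellation aligned to a grey matter volume.

    Label 0 is background; labels 1..n_regions name regions.  The atlas is
    assumed already aligned to the grey matter grid (alignment is an input
    contract, not something this package performs).
    """

    labels: np.ndarray
    region_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D integer volume")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer-typed")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative (0 = background)")
        if not self.region_names:
            self.region_names = [f"region_{i}" for i in range(1, self.n_regions + 1)]
        if len(self.region_names) < self.n_regions:
            raise ValueError("region_names shorter than the number of labels present")

    @property
    def n_regions(self) -> int:
        return int(self.labels.max())

    def save(self, path, voxel_size_mm=(2.0, 2.0, 2.0)) -> None:
        aff = np.diag(list(voxel_size_mm) + [1.0])
        nib.save(nib.Nifti1Image(self.labels.astype(np.int16), aff), str(path))

    @classmethod
    def load(cls, path, region_names=None) -> "AtlasParcellation":
        img = nib.load(str(path))
        labels = np.asanyarray(img.dataobj).astype(np.int64)
        return cls(labels=labels, region_names=list(region_names or []))
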