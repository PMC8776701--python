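"""Gridded volumes and displacement fields.

All per-patient volumes (CT, dose, ventilation, masks) live on a common
regular grid described by voxel spacing and origin in millimetres.  Array
axes are (x, y, z) with the anatomical convention

    axis 0 : left -> right       (index 0 = patient left)
    axis 1 : anterior -> posterior (index 0 = anterior)
    axis 2 : superior -> inferior  (index 0 = superior)

A displacement field is defined on the exhale (fixed) grid; each voxel's
vector, in millimetres, points to the corresponding location in the inhale
(moving) image, i.e. the registered inhale value at x is inhale(x + u(x)).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

VALID_KINDS = ("HU", "dose_Gy", "ventilation", "percentile", "mask")


@dataclass
class GriddedVolume:
    """A 3D scalar field with voxel spacing and origin (both in mm)."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    kind: str = "HU"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.values.ndim}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")
        if self.kind not in VALID_KINDS:
            raise ValueError(f"unknown kind {self.kind!r}; expected one of {VALID_KINDS}")
        if self.kind == "mask":
            uniq = np.unique(self.values[np.isfinite(self.values)])
            if not np.all(np.isin(uniq, (0.0, 1.0))):
                raise ValueError("mask volumes must contain only {0, 1}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def same_grid(self, other: "GriddedVolume | DisplacementField") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_mm, other.spacing_mm)
            and np.allclose(self.origin_mm, other.origin_mm)
        )

    def with_values(self, values: np.ndarray, kind: str | None = None) -> "GriddedVolume":
        return replace(self, values=np.asarray(values, dtype=float),
                       kind=self.kind if kind is None else kind)

    def as_bool(self) -> np.ndarray:
        if self.kind != "mask":
            raise ValueError(f"expected a mask volume, got kind={self.kind!r}")
        return self.values.astype(bool)


@dataclass
class DisplacementField:
    """A 3D vector field (mm) on the exhale grid, pointing into the inhale image."""

    u: np.ndarray  # shape (nx, ny, nz, 3)
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        if self.u.ndim != 4 or self.u.shape[-1] != 3:
            raise ValueError(f"expected shape (nx, ny, nz, 3), got {self.u.shape}")
        if not np.all(np.isfinite(self.u)):
            raise ValueError("displacement field contains non-finite values")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.u.shape[:3]

    def component(self, i: int) -> np.ndarray:
        return self.u[..., i]


def _affine(spacing: tuple[float, ...], origin: tuple[float, ...]) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def save_volume(vol: GriddedVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(vol.values.astype(np.float32), _affine(vol.spacing_mm, vol.origin_mm))
    img.header["descrip"] = vol.kind.encode()[:79]
    nib.save(img, str(path))


def load_volume(path: str | Path, kind: str = "HU") -> GriddedVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(v) for v in img.affine[:3, 3])
    descrip = bytes(img.header["descrip"]).split(b"\x00")[0].decode(errors="ignore")
    if descrip in VALID_KINDS:
        kind = descrip
    return GriddedVolume(data, tuple(float(z) for z in zooms), origin, kind)


def save_field(fld: DisplacementField, path: str | Path) -> None:
    img = nib.Nifti1Image(fld.u.astype(np.float32), _affine(fld.spacing_mm, fld.origin_mm))
    img.header.set_intent("vector")
    nib.save(img, str(path))


def load_field(path: str | Path) -> DisplacementField:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 5:  # NIfTI vector images are often stored (x, y, z, 1, 3)
        data = data[:, :, :, 0, :]
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return DisplacementField(data, tuple(float(z) for z in zooms), origin)
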