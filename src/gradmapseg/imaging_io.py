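"""NIfTI volume and label-mask I/O with a single in-memory axis convention.

All arrays in this package are indexed ``(z, y, x)`` with matching per-axis
spacing in millimetres, regardless of how the file stores them on disk; the
reader reorients. Voxel indices are 0-based and all boxes/intervals elsewhere
are half-open ``[lo, hi)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

VALID_LABELS = frozenset({0, 1, 2})
#: label semantics: 0 background, 1 primary tumor (GTVp), 2 nodal tumor (GTVn)
LABEL_NAMES = {0: "background", 1: "GTVp", 2: "GTVn"}


@dataclass
class VolumeImage:
    """A 3D scalar grid with physical spacing.

    Parameters
    ----------
    data : ndarray
        3D array indexed ``(z, y, x)``.
    spacing : tuple of float
        Voxel size in mm per axis, ``(z, y, x)`` order; all strictly positive.
    affine : ndarray, optional
        4x4 voxel-to-physical mapping. Defaults to a diagonal affine built
        from the spacing.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or not all(np.isfinite(s) and s > 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 strictly positive finite values, got {self.spacing}")
        if np.issubdtype(self.data.dtype, np.floating) and not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains NaN/Inf voxels")
        if self.affine is None:
            self.affine = _default_affine(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class LabelMask(VolumeImage):
    """Integer label grid aligned to a :class:`VolumeImage`; values in {0, 1, 2}."""

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if np.issubdtype(arr.dtype, np.floating):
            rounded = np.rint(arr)
            if not np.allclose(arr, rounded, atol=1e-6, equal_nan=False):
                raise ValueError("mask contains non-integer voxel values")
            arr = rounded
        self.data = arr.astype(np.uint8, casting="unsafe")
        bad = np.setdiff1d(np.unique(self.data), sorted(VALID_LABELS))
        if bad.size:
            raise ValueError(f"mask contains labels outside {{0,1,2}}: {bad.tolist()}")
        super().__post_init__()

    def label_counts(self) -> dict[int, int]:
        """Voxel count per foreground label."""
        return {lab: int(np.count_nonzero(self.data == lab)) for lab in (1, 2)}


def _default_affine(spacing_zyx: tuple[float, float, float]) -> np.ndarray:
    # on-disk axis order is (x, y, z); spacing is carried (z, y, x) in memory
    sx, sy, sz = spacing_zyx[2], spacing_zyx[1], spacing_zyx[0]
    return np.diag([sx, sy, sz, 1.0])


def _load(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float], np.ndarray]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    # nibabel arrays are (x, y, z); internal convention is (z, y, x)
    data = np.transpose(data, (2, 1, 0))
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return data, spacing, np.asarray(img.affine)


def read_volume(path: str | Path) -> VolumeImage:
    """Read a NIfTI scalar volume, normalising axis order to ``(z, y, x)``.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    ValueError
        If the volume contains NaN or Inf voxels.
    """
    data, spacing, affine = _load(path)
    if np.issubdtype(data.dtype, np.floating) and not np.all(np.isfinite(data)):
        raise ValueError(f"{path}: volume contains NaN/Inf voxels")
    return VolumeImage(data=data, spacing=spacing, affine=affine)


def read_mask(path: str | Path) -> LabelMask:
    """Read a NIfTI label mask; every voxel must be in {0, 1, 2}."""
    data, spacing, affine = _load(path)
    try:
        return LabelMask(data=data, spacing=spacing, affine=affine)
    except ValueError as e:
        raise ValueError(f"{path}: {e}") from None


def write_volume(image: VolumeImage, path: str | Path) -> None:
    """Write a volume or mask to NIfTI.

    Masks are stored as uint8, everything else as float32, so integer data
    round-trips exactly and float data within float32 precision.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(image, LabelMask):
        out = image.data.astype(np.uint8)
    else:
        out = np.asarray(image.data, dtype=np.float32)
    # back to on-disk (x, y, z)
    out = np.transpose(out, (2, 1, 0))
    affine = image.affine if image.affine is not None else _default_affine(image.spacing)
    nifti = nib.Nifti1Image(out, affine)
    nifti.header.set_zooms((image.spacing[2], image.spacing[1], image.spacing[0]))
    nib.save(nifti, str(path))


def check_same_grid(a: VolumeImage, b: VolumeImage, what: str = "volumes") -> None:
    """Raise ``ValueError`` unless the two grids share shape and spacing."""
    if a.shape != b.shape:
        raise ValueError(f"{what} differ in shape: {a.shape} vs {b.shape}")
    if not np.allclose(a.spacing, b.spacing, rtol=1e-5):
        raise ValueError(f"{what} differ in spacing: {a.spacing} vs {b.spacing}")
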