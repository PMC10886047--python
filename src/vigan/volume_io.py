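"""Volume containers and I/O.

Every module in the package consumes one canonical representation: a dense
3D grid of voxel intensities normalized to [0, 1], axis order ``(x, y, z)``
with z as the axial (slice) axis.  The raster order for the flat voxel index
``m`` is x fastest, then y, then z (Fortran order over (x, y, z)).

Supported on-disk formats are NIfTI (via nibabel, value-exact for float
storage) and directories of lexicographically ordered 16-bit grayscale PNG
slices (one file per axial plane, slice 0 = first file).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import nibabel as nib
import numpy as np

__all__ = [
    "Volume",
    "ImageSet",
    "read_volume",
    "write_volume",
    "normalize_hu",
    "extract_slice",
    "stack_slices",
]

#: Default Hounsfield window for CT import: air (−1000) to dense bone (2000).
DEFAULT_HU_WINDOW = (-1000.0, 2000.0)


@dataclass
class Volume:
    """A dense 3D intensity grid.

    Parameters
    ----------
    data
        Array of shape ``(l, w, h)`` = (x, y, z resolutions), values in [0, 1].
    spacing
        Optional per-axis physical voxel size in millimetres.
    """

    data: np.ndarray
    spacing: Optional[tuple] = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got ndim={self.data.ndim}")
        if any(s < 1 for s in self.data.shape):
            raise ValueError(f"all axes must have extent >= 1, got {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite voxels")
        if self.data.min() < 0.0 or self.data.max() > 1.0:
            raise ValueError("voxel values must lie in [0, 1]; normalize first")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.size)

    def ravel(self) -> np.ndarray:
        """Voxel values in raster order of the flat index m: x fastest, then y, then z."""
        return self.data.ravel(order="F")


@dataclass
class ImageSet:
    """Ordered stack of 2D grayscale slices used to condition the generator.

    ``slices`` has shape ``(K, l, w)``; ``z_positions`` optionally records the
    axial index each slice came from (needed for sparse conditioning).
    """

    slices: np.ndarray
    z_positions: Optional[np.ndarray] = field(default=None)

    def __post_init__(self):
        self.slices = np.asarray(self.slices, dtype=np.float64)
        if self.slices.ndim != 3 or self.slices.shape[0] < 1:
            raise ValueError("ImageSet requires a (K>=1, l, w) stack")
        if not np.all(np.isfinite(self.slices)):
            raise ValueError("ImageSet contains non-finite values")
        if self.slices.min() < 0.0 or self.slices.max() > 1.0:
            raise ValueError("ImageSet values must lie in [0, 1]")
        if self.z_positions is not None:
            self.z_positions = np.asarray(self.z_positions, dtype=int)
            if len(self.z_positions) != self.count:
                raise ValueError("z_positions length must equal slice count")

    @property
    def count(self) -> int:
        return int(self.slices.shape[0])

    @property
    def resolution(self) -> tuple:
        return tuple(self.slices.shape[1:])


# --------------------------------------------------------------------- I/O

def read_volume(path, format: str = "nifti", normalized: bool = True) -> Volume:
    """Read a volume from NIfTI or a directory of PNG slices.

    The z-axis follows slice order: slice 0 is the first file of the
    lexicographically sorted directory, or the first plane of the NIfTI array.
    With ``normalized=False`` raw intensities are returned un-checked as a
    plain array (caller must window/normalize, e.g. via :func:`normalize_hu`).
    """
    path = Path(path)
    if format == "nifti":
        if not path.exists():
            raise FileNotFoundError(path)
        try:
            img = nib.load(str(path))
            data = np.asarray(img.dataobj, dtype=np.float64)
        except Exception as e:  # nibabel raises several unrelated types
            raise ValueError(f"cannot read NIfTI file {path}: {e}") from e
        if data.ndim != 3:
            raise ValueError(f"expected a 3D NIfTI, got shape {data.shape}")
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return Volume(data, spacing=spacing) if normalized else data
    elif format == "slice_stack":
        if not path.is_dir():
            raise FileNotFoundError(f"slice_stack expects a directory: {path}")
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in {".png", ".tif", ".tiff"})
        if not files:
            raise ValueError(f"no slice images found in {path}")
        planes = []
        for f in files:
            try:
                arr = iio.imread(f)
            except Exception as e:
                raise ValueError(f"cannot read slice {f}: {e}") from e
            if arr.ndim != 2:
                raise ValueError(f"slice {f} is not single-channel grayscale")
            planes.append(arr)
        shapes = {p.shape for p in planes}
        if len(shapes) != 1:
            raise ValueError(f"inconsistent slice dimensions: {sorted(shapes)}")
        scale = _scale_for_dtype(planes[0].dtype)
        stack = np.stack(planes).astype(np.float64) / scale  # (h, l, w)
        data = np.moveaxis(stack, 0, -1)  # (l, w, h)
        return Volume(data) if normalized else data
    raise ValueError(f"unknown format {format!r}; expected 'nifti' or 'slice_stack'")


def write_volume(v: Volume, path, format: str = "nifti") -> None:
    """Write a volume as float NIfTI (value-exact round trip) or a 16-bit PNG stack."""
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"parent directory does not exist: {path.parent}")
    if format == "nifti":
        affine = np.eye(4)
        if v.spacing is not None:
            affine[0, 0], affine[1, 1], affine[2, 2] = v.spacing
        nib.save(nib.Nifti1Image(v.data.astype(np.float64), affine), str(path))
    elif format == "slice_stack":
        path.mkdir(exist_ok=True)
        h = v.shape[2]
        width = max(4, int(math.log10(max(h - 1, 1))) + 1)
        for k in range(h):
            plane = np.round(v.data[:, :, k] * 65535.0).astype(np.uint16)
            iio.imwrite(path / f"slice_{k:0{width}d}.png", plane)
    else:
        raise ValueError(f"unknown format {format!r}")


def normalize_hu(raw: np.ndarray, window=DEFAULT_HU_WINDOW) -> Volume:
    """Window Hounsfield-like intensities into a [0, 1] Volume.

    ``out = clip((raw - low) / (high - low), 0, 1)`` — monotone in ``raw``.
    """
    low, high = float(window[0]), float(window[1])
    if low >= high:
        raise ValueError(f"window requires low < high, got ({low}, {high})")
    raw = np.asarray(raw, dtype=np.float64)
    return Volume(np.clip((raw - low) / (high - low), 0.0, 1.0))


def extract_slice(v: Volume, k: int) -> np.ndarray:
    """The k-th axial (xy) plane of the volume, 0-based along z."""
    h = v.shape[2]
    if not 0 <= k < h:
        raise IndexError(f"slice index {k} out of range [0, {h})")
    return v.data[:, :, k]


def stack_slices(slices: Sequence[np.ndarray]) -> Volume:
    """Reassemble axial planes (in z order) into a Volume; inverse of extract_slice."""
    return Volume(np.stack(slices, axis=-1))


def _scale_for_dtype(dtype) -> float:
    if np.issubdtype(dtype, np.integer):
        return float(np.iinfo(dtype).max)
    return 1.0


def _ensure_same_shape(a: Volume, b: Volume) -> None:
    if a.shape != b.shape:
        raise ValueError(f"volume shapes differ: {a.shape} vs {b.shape}")
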