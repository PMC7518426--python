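"""Volume containers, NIfTI I/O, resampling, patching, and MIP rendering.

All volumes use ``(z, y, x)`` axis order with 0-based indices; ``z`` is the
scan axis (feet -> head increasing). Spacing is stored as ``(sz, sy, sx)`` in
mm per voxel. On disk, volumes are NIfTI with the array transposed to the
conventional ``(x, y, z)`` order and spacing carried in the header zooms, so
files remain readable by standard viewers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

LABEL_CLASSES = (0, 1, 2, 3, 4)  # background, bone, aorta, carotid, intracranial


class FormatError(ValueError):
    """Raised when an on-disk volume violates the expected layout."""


@dataclass
class Volume:
    """A 3D scalar field (HU-like intensities) with voxel spacing in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise FormatError(f"volume must be 3D, got {self.data.ndim}D")
        if min(self.data.shape) < 1:
            raise FormatError("all volume dimensions must be >= 1")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive floats, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise FormatError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class LabelVolume:
    """Integer class field on the same grid as its paired :class:`Volume`.

    Classes: 0 background, 1 bone, 2 aorta, 3 carotid, 4 intracranial.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise FormatError(f"label volume must be 3D, got {self.data.ndim}D")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise FormatError(f"label volume must have integer dtype, got {self.data.dtype}")
        present = set(np.unique(self.data).tolist())
        if not present <= set(LABEL_CLASSES):
            raise FormatError(f"label values {sorted(present)} outside {LABEL_CLASSES}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


def _affine_from_spacing(spacing: tuple[float, float, float]) -> np.ndarray:
    sz, sy, sx = spacing
    return np.diag([sx, sy, sz, 1.0])


def write_volume(volume: Volume | LabelVolume, path) -> None:
    """Write a volume or label volume to NIfTI (.nii / .nii.gz)."""
    if isinstance(volume, LabelVolume):
        arr = volume.data.astype(np.int16)
    else:
        arr = volume.data.astype(np.float32)
    img = nib.Nifti1Image(arr.transpose(2, 1, 0), _affine_from_spacing(volume.spacing))
    img.header.set_zooms(tuple(reversed(volume.spacing)))
    nib.save(img, str(path))


def _load(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    try:
        img = nib.load(str(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed header, wrong magic, ...
        raise FormatError(f"cannot read {path!s} as NIfTI: {exc}") from exc
    arr = np.asanyarray(img.dataobj)
    if arr.ndim != 3:
        raise FormatError(f"{path!s}: expected a 3D payload, got {arr.ndim}D")
    sx, sy, sz = img.header.get_zooms()[:3]
    return arr.transpose(2, 1, 0), (float(sz), float(sy), float(sx))


def read_volume(path) -> Volume:
    """Read a NIfTI file as a float :class:`Volume` in (z, y, x) order."""
    arr, spacing = _load(path)
    return Volume(arr.astype(np.float32), spacing)


def read_label_volume(path) -> LabelVolume:
    """Read a NIfTI file as an integer :class:`LabelVolume`."""
    arr, spacing = _load(path)
    if not np.issubdtype(arr.dtype, np.integer):
        rounded = np.rint(arr)
        if not np.allclose(arr, rounded):
            raise FormatError(f"{path!s}: non-integer values in label payload")
        arr = rounded
    return LabelVolume(arr.astype(np.int16), spacing)


def normalize_resolution(
    volume: Volume | LabelVolume,
    target_spacing: tuple[float, float, float] | float,
) -> Volume | LabelVolume:
    """Resample to ``target_spacing`` (mm), linear for images, nearest for labels.

    Output dimensions are ``round(dim * spacing / target)`` per axis.
    """
    if np.isscalar(target_spacing):
        target_spacing = (float(target_spacing),) * 3
    target_spacing = tuple(float(s) for s in target_spacing)
    if any(s <= 0 for s in target_spacing):
        raise ValueError(f"target spacing must be positive, got {target_spacing}")
    zoom = [s / t for s, t in zip(volume.spacing, target_spacing)]
    if all(abs(z - 1.0) < 1e-12 for z in zoom):
        return type(volume)(volume.data.copy(), target_spacing)
    if isinstance(volume, LabelVolume):
        out = ndimage.zoom(volume.data, zoom, order=0, mode="nearest", grid_mode=True)
        return LabelVolume(out.astype(volume.data.dtype), target_spacing)
    out = ndimage.zoom(volume.data.astype(np.float32), zoom, order=1,
                       mode="nearest", grid_mode=True)
    return Volume(out, target_spacing)


@dataclass
class PatchGrid:
    """Cubic sliding-window decomposition of a volume.

    Edge patches are clamped so they end at the volume boundary (overlapping
    the previous patch); axes shorter than ``patch_size`` produce one
    zero-padded patch.
    """

    volume_shape: tuple[int, int, int]
    patch_size: int = 256
    stride: int | None = None
    origins: list[tuple[int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.stride is None:
            self.stride = self.patch_size
        if self.patch_size < 1:
            raise ValueError("patch_size must be >= 1")
        if not 1 <= self.stride <= self.patch_size:
            raise ValueError(
                f"stride must be in [1, patch_size]; stride={self.stride} with "
                f"patch_size={self.patch_size} would leave gaps")
        if not self.origins:
            axes = []
            for dim in self.volume_shape:
                if dim <= self.patch_size:
                    axes.append([0])
                    continue
                n = int(np.ceil((dim - self.patch_size) / self.stride)) + 1
                axes.append([min(i * self.stride, dim - self.patch_size) for i in range(n)])
            self.origins = [(z, y, x) for z in axes[0] for y in axes[1] for x in axes[2]]

    @property
    def n_patches(self) -> int:
        return len(self.origins)

    def patch_slices(self, origin: tuple[int, int, int]):
        return tuple(slice(o, min(o + self.patch_size, d))
                     for o, d in zip(origin, self.volume_shape))


def make_patch_grid(volume_shape, patch_size: int = 256, stride: int | None = None) -> PatchGrid:
    return PatchGrid(tuple(int(d) for d in volume_shape), int(patch_size),
                     None if stride is None else int(stride))


def extract_patches(data: np.ndarray, grid: PatchGrid) -> list[np.ndarray]:
    """Cut a volume array into ``patch_size`` cubes (zero-padded at short axes)."""
    if tuple(data.shape) != tuple(grid.volume_shape):
        raise ValueError(f"data shape {data.shape} != grid shape {grid.volume_shape}")
    p = grid.patch_size
    patches = []
    for origin in grid.origins:
        sl = grid.patch_slices(origin)
        chunk = data[sl]
        if chunk.shape != (p, p, p):
            pad = [(0, p - s) for s in chunk.shape]
            chunk = np.pad(chunk, pad)
        patches.append(chunk)
    return patches


def stitch(patches: list[np.ndarray], grid: PatchGrid, reduce: str = "mean") -> np.ndarray:
    """Reassemble patches onto the full grid; overlaps combined by mean or max."""
    if len(patches) != grid.n_patches:
        raise ValueError(f"expected {grid.n_patches} patches, got {len(patches)}")
    if reduce not in ("mean", "max"):
        raise ValueError(f"reduce must be 'mean' or 'max', got {reduce!r}")
    out = np.zeros(grid.volume_shape, dtype=np.float64)
    if reduce == "mean":
        count = np.zeros(grid.volume_shape, dtype=np.int32)
    else:
        out.fill(-np.inf)
    for patch, origin in zip(patches, grid.origins):
        if patch.shape != (grid.patch_size,) * 3:
            raise ValueError(f"patch shape {patch.shape} does not conform to grid")
        sl = grid.patch_slices(origin)
        valid = patch[tuple(slice(0, s.stop - s.start) for s in sl)]
        if reduce == "mean":
            out[sl] += valid
            count[sl] += 1
        else:
            np.maximum(out[sl], valid, out=out[sl])
    if reduce == "mean":
        out /= count
    return out


def mip(data: np.ndarray, axis: int = 0) -> np.ndarray:
    """Maximum intensity projection: collapse one axis by per-ray max."""
    data = np.asarray(data)
    if data.ndim != 3:
        raise ValueError("mip expects a 3D array")
    if axis not in (0, 1, 2):
        raise ValueError(f"axis must be 0, 1 or 2, got {axis}")
    return data.max(axis=axis)


def save_mip_png(data: np.ndarray, path, axis: int = 0) -> np.ndarray:
    """Render a MIP to an 8-bit grayscale PNG (min-max windowed)."""
    import imageio.v3 as iio

    img = mip(data, axis=axis).astype(np.float64)
    lo, hi = img.min(), img.max()
    if hi > lo:
        img = (img - lo) / (hi - lo)
    else:
        img = np.zeros_like(img)
    img8 = (img * 255).round().astype(np.uint8)
    iio.imwrite(str(path), img8[::-1])  # flip so +y is up in the image
    return img8
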