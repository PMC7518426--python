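"""Label denoising and training-set augmentation.

Scattered-noise removal drops small connected components per foreground
class. Augmentation applies an identical in-plane geometric transform to the
image and its label (horizontal flip, rotation up to 25 degrees about the
scan axis, in-plane shifts up to 20 voxels), image-only random box occlusion
(one uniform fill value per box, emulating metal-implant artifacts), and
additive Gaussian noise. A dataset of N pairs is expanded to 5N by default:
the originals once, plus randomly drawn augmentations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .phantom import CONNECTIVITY_26
from .volume_io import LabelVolume, Volume


@dataclass
class AugmentSpec:
    """Sampling ranges for the augmentation draws (desk-scale defaults)."""

    allow_flip: bool = True
    max_rotation_deg: float = 25.0
    max_shift: int = 20
    occlusion_size_range: tuple[int, int] = (4, 12)
    occlusion_prob: float = 0.5
    noise_sigma: float = 10.0
    expansion_factor: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_rotation_deg < 0:
            raise ValueError("max_rotation_deg must be >= 0")
        if self.max_shift < 0:
            raise ValueError("max_shift must be >= 0")
        if int(self.expansion_factor) != self.expansion_factor or self.expansion_factor < 1:
            raise ValueError("expansion_factor must be an integer >= 1")
        lo, hi = self.occlusion_size_range
        if not 1 <= lo <= hi:
            raise ValueError("occlusion_size_range must be ordered and >= 1")


@dataclass
class AugmentDraw:
    """One concrete sampled transform; the identity draw is all zeros."""

    flip: bool = False
    angle_deg: float = 0.0
    shift: tuple[int, int] = (0, 0)  # (dy, dx) voxels, in-plane
    occlusion: tuple[tuple[int, int, int], tuple[int, int, int], float] | None = None
    noise_sigma: float = 0.0
    noise_seed: int = 0

    @property
    def is_identity(self) -> bool:
        return (not self.flip and self.angle_deg == 0.0 and self.shift == (0, 0)
                and self.occlusion is None and self.noise_sigma == 0.0)


def sample_draw(spec: AugmentSpec, rng: np.random.Generator,
                volume_shape: tuple[int, int, int]) -> AugmentDraw:
    """Sample one transform; |angle| <= max_rotation_deg, |shift| <= max_shift."""
    flip = bool(spec.allow_flip and rng.integers(2))
    angle = float(rng.uniform(-spec.max_rotation_deg, spec.max_rotation_deg))
    shift = (int(rng.integers(-spec.max_shift, spec.max_shift + 1)),
             int(rng.integers(-spec.max_shift, spec.max_shift + 1)))
    occlusion = None
    if rng.random() < spec.occlusion_prob:
        size = tuple(int(rng.integers(spec.occlusion_size_range[0],
                                      spec.occlusion_size_range[1] + 1))
                     for _ in range(3))
        origin = tuple(int(rng.integers(0, max(s - b, 0) + 1))
                       for s, b in zip(volume_shape, size))
        fill = float(rng.uniform(0.0, 1.0))
        occlusion = (origin, size, fill)
    return AugmentDraw(flip=flip, angle_deg=angle, shift=shift, occlusion=occlusion,
                       noise_sigma=spec.noise_sigma,
                       noise_seed=int(rng.integers(2 ** 31)))


def augment_pair(volume: Volume, label: LabelVolume, draw: AugmentDraw,
                 ) -> tuple[Volume, LabelVolume]:
    """Apply one draw: identical geometry to image and label, image-only noise.

    The label is resampled with nearest-neighbour interpolation so it stays
    integer; occlusion and noise never touch the label.
    """
    if volume.shape != label.shape:
        raise ValueError(f"volume shape {volume.shape} != label shape {label.shape}")
    img = volume.data.astype(np.float32)
    lab = label.data.copy()

    if draw.flip:
        img = img[:, :, ::-1]
        lab = lab[:, :, ::-1]
    if draw.angle_deg != 0.0:
        img = ndimage.rotate(img, draw.angle_deg, axes=(1, 2), reshape=False,
                             order=1, mode="nearest")
        lab = ndimage.rotate(lab, draw.angle_deg, axes=(1, 2), reshape=False,
                             order=0, mode="nearest")
    if draw.shift != (0, 0):
        dy, dx = draw.shift
        img = ndimage.shift(img, (0, dy, dx), order=1, mode="nearest")
        lab = ndimage.shift(lab, (0, dy, dx), order=0, mode="nearest")

    img = np.ascontiguousarray(img)
    if draw.occlusion is not None:
        (oz, oy, ox), (bz, by, bx), fill_frac = draw.occlusion
        lo, hi = float(img.min()), float(img.max())
        img[oz:oz + bz, oy:oy + by, ox:ox + bx] = lo + fill_frac * (hi - lo)
    if draw.noise_sigma > 0:
        noise_rng = np.random.default_rng(draw.noise_seed)
        img = img + noise_rng.normal(0.0, draw.noise_sigma, img.shape).astype(np.float32)

    return Volume(img, volume.spacing), LabelVolume(np.ascontiguousarray(lab), label.spacing)


def expand_dataset(
    pairs: list[tuple[Volume, LabelVolume]],
    spec: AugmentSpec,
) -> list[tuple[Volume, LabelVolume]]:
    """Expand N pairs to ``expansion_factor * N``: originals once + random draws.

    Deterministic for a fixed ``spec.seed``.
    """
    if not pairs:
        return []
    rng = np.random.default_rng(spec.seed)
    out = list(pairs)
    for _ in range(spec.expansion_factor - 1):
        for vol, lab in pairs:
            draw = sample_draw(spec, rng, vol.shape)
            out.append(augment_pair(vol, lab, draw))
    return out


def remove_scattered_noise(label: LabelVolume, min_component_size: int = 27) -> LabelVolume:
    """Drop 26-connected components smaller than ``min_component_size`` per class.

    Voxels only ever change class to background; the operation is idempotent.
    """
    if min_component_size < 1:
        raise ValueError("min_component_size must be >= 1")
    out = label.data.copy()
    for cls in np.unique(out):
        if cls == 0:
            continue
        labeled, n = ndimage.label(out == cls, structure=CONNECTIVITY_26)
        if n == 0:
            continue
        sizes = np.bincount(labeled.ravel())
        small = np.flatnonzero(sizes < min_component_size)
        small = small[small != 0]
        if len(small):
            out[np.isin(labeled, small)] = 0
    return LabelVolume(out, label.spacing)
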