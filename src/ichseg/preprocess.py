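"""Hounsfield-unit contrast windowing and the augmentation policies.

Windowing maps an HU interval linearly onto [0, 1] with clipping; the
segmentation window is [-50, 150] HU, chosen to straddle the 40-90 HU range
of acute hematoma while keeping soft-tissue contrast.

Three augmentation policies are provided:

* ``segmentation_default`` — the light geometric chain applied during
  fine-tuning (translate +-10%, rotate +-15 deg, scale [0.9, 1.1],
  horizontal flip p=0.5, resize), applied identically to image and mask;
* ``global_default`` (T_G) — the heavy contrastive chain (translate +-15%,
  rotate +-90 deg, scale [0.8, 1.2], flip p=0.5, contrast/brightness jitter,
  Gaussian blur, random crop-and-resize);
* ``local_default`` (T_L) — as T_G but rotation limited to +-45 deg and NO
  horizontal flip, so that feature locations stay comparable across views.

The composition order is fixed: translate -> rotate -> scale -> flip ->
photometric -> crop/resize.  All draws come from a seeded generator, images
are interpolated bilinearly, masks nearest-neighbour, and out-of-frame
pixels are filled with 0 (windowed air).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage

__all__ = [
    "WindowSpec",
    "AugmentationSpec",
    "SEGMENTATION_WINDOW",
    "window_rescale",
    "augment_seg",
    "augment_global",
    "augment_local",
    "resize_image",
]


@dataclass(frozen=True)
class WindowSpec:
    lo: float
    hi: float

    def __post_init__(self):
        if self.lo >= self.hi:
            raise ValueError(f"window lower bound {self.lo} must be < upper bound {self.hi}")


#: default contrast window for hemorrhage segmentation, in HU
SEGMENTATION_WINDOW = WindowSpec(-50.0, 150.0)


def window_rescale(values: np.ndarray, window: WindowSpec = SEGMENTATION_WINDOW) -> np.ndarray:
    """clip((v - lo) / (hi - lo), 0, 1), elementwise and monotone in v."""
    v = np.asarray(values, dtype=np.float32)
    if not np.all(np.isfinite(v)):
        raise ValueError("window_rescale requires finite input")
    return np.clip((v - window.lo) / (window.hi - window.lo), 0.0, 1.0)


@dataclass(frozen=True)
class AugmentationSpec:
    translate_range: tuple[float, float] = (-0.10, 0.10)
    rotate_range: tuple[float, float] = (-15.0, 15.0)
    scale_range: tuple[float, float] = (0.9, 1.1)
    hflip_prob: float = 0.5
    contrast_prob: float = 0.0
    brightness_prob: float = 0.0
    blur_prob: float = 0.0
    crop_resize: bool = False
    out_size: int = 256
    # photometric magnitudes (SimCLR-style defaults, on the [0, 1] scale)
    contrast_range: tuple[float, float] = (0.8, 1.2)
    brightness_range: tuple[float, float] = (-0.1, 0.1)
    blur_sigma_range: tuple[float, float] = (0.1, 2.0)
    crop_area_range: tuple[float, float] = (0.6, 1.0)

    def __post_init__(self):
        for p in (self.hflip_prob, self.contrast_prob, self.brightness_prob, self.blur_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        for interval in (self.translate_range, self.rotate_range, self.scale_range,
                         self.contrast_range, self.brightness_range,
                         self.blur_sigma_range, self.crop_area_range):
            if interval[0] > interval[1]:
                raise ValueError(f"interval {interval} must be ordered")
        if self.out_size < 1:
            raise ValueError("out_size must be positive")

    @classmethod
    def segmentation_default(cls, out_size: int = 256) -> "AugmentationSpec":
        return cls(out_size=out_size)

    @classmethod
    def global_default(cls, out_size: int = 256) -> "AugmentationSpec":
        """Heavy contrastive transformation T_G."""
        return cls(
            translate_range=(-0.15, 0.15),
            rotate_range=(-90.0, 90.0),
            scale_range=(0.8, 1.2),
            hflip_prob=0.5,
            contrast_prob=0.5,
            brightness_prob=0.5,
            blur_prob=0.5,
            crop_resize=True,
            out_size=out_size,
        )

    @classmethod
    def local_default(cls, out_size: int = 256) -> "AugmentationSpec":
        """Localization-preserving transformation T_L: no horizontal flip,
        rotation limited to +-45 degrees."""
        return cls(
            translate_range=(-0.15, 0.15),
            rotate_range=(-45.0, 45.0),
            scale_range=(0.8, 1.2),
            hflip_prob=0.0,
            contrast_prob=0.5,
            brightness_prob=0.5,
            blur_prob=0.5,
            crop_resize=True,
            out_size=out_size,
        )

    def to_dict(self) -> dict:
        return asdict(self)


def resize_image(image: np.ndarray, out_size: int, order: int = 1) -> np.ndarray:
    """Resize a square-or-not 2D image to (out_size, out_size)."""
    h, w = image.shape
    if (h, w) == (out_size, out_size):
        return image.copy()
    zoom = (out_size / h, out_size / w)
    out = ndimage.zoom(image, zoom, order=order, mode="nearest", grid_mode=True)
    # grid_mode zoom guarantees the exact output size for integer targets
    return out[:out_size, :out_size]


def _draw_geometric(spec: AugmentationSpec, rng: np.random.Generator) -> dict:
    return {
        "ty": rng.uniform(*spec.translate_range),
        "tx": rng.uniform(*spec.translate_range),
        "angle": rng.uniform(*spec.rotate_range),
        "scale": rng.uniform(*spec.scale_range),
        "flip": rng.random() < spec.hflip_prob,
    }


def _affine_apply(image: np.ndarray, draw: dict, order: int) -> np.ndarray:
    """translate -> rotate -> scale about the image center, fill value 0."""
    h, w = image.shape
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    ang = np.deg2rad(draw["angle"])
    rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
    fwd = draw["scale"] * rot  # applied after translation
    t = np.array([draw["ty"] * h, draw["tx"] * w])
    # forward map: p' = C + F (p + t - C); affine_transform needs the inverse
    inv = np.linalg.inv(fwd)
    offset = -inv @ center + center - t
    return ndimage.affine_transform(
        image, inv, offset=offset, order=order, mode="constant", cval=0.0
    )


def _photometric(image, spec, rng):
    """Contrast/brightness jitter and Gaussian blur; draws are always
    consumed so the random stream does not depend on earlier outcomes."""
    do_contrast = rng.random() < spec.contrast_prob
    c = rng.uniform(*spec.contrast_range)
    do_brightness = rng.random() < spec.brightness_prob
    b = rng.uniform(*spec.brightness_range)
    do_blur = rng.random() < spec.blur_prob
    sigma = rng.uniform(*spec.blur_sigma_range)
    if do_contrast:
        m = image.mean()
        image = (image - m) * c + m
    if do_brightness:
        image = image + b
    if do_blur:
        image = ndimage.gaussian_filter(image, sigma=sigma, truncate=2.0)
    return image


def _crop_resize(image, spec, rng, order):
    h, w = image.shape
    area = rng.uniform(*spec.crop_area_range)
    side = int(round(np.sqrt(area) * min(h, w)))
    side = max(1, min(side, min(h, w)))
    r0 = int(rng.integers(0, h - side + 1))
    c0 = int(rng.integers(0, w - side + 1))
    crop = image[r0 : r0 + side, c0 : c0 + side]
    return resize_image(crop, spec.out_size, order=order)


def augment_seg(
    image: np.ndarray,
    mask: np.ndarray,
    spec: AugmentationSpec | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Identical geometric transform for image and mask, then resize.

    The mask is interpolated nearest-neighbour and stays binary.
    """
    if image.shape != mask.shape:
        raise ValueError(f"image {image.shape} and mask {mask.shape} must share shape")
    spec = spec or AugmentationSpec.segmentation_default(out_size=image.shape[0])
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draw = _draw_geometric(spec, rng)
    img = _affine_apply(np.asarray(image, dtype=np.float32), draw, order=1)
    msk = _affine_apply(np.asarray(mask, dtype=np.float32), draw, order=0)
    if draw["flip"]:
        img = img[:, ::-1]
        msk = msk[:, ::-1]
    img = resize_image(img, spec.out_size, order=1)
    msk = resize_image(msk, spec.out_size, order=0)
    return img, (msk > 0.5).astype(np.uint8)


def _augment_view(image, spec, rng):
    draw = _draw_geometric(spec, rng)
    img = _affine_apply(np.asarray(image, dtype=np.float32), draw, order=1)
    if draw["flip"]:
        img = img[:, ::-1]
    img = _photometric(img, spec, rng)
    if spec.crop_resize:
        img = _crop_resize(img, spec, rng, order=1)
    elif img.shape != (spec.out_size, spec.out_size):
        img = resize_image(img, spec.out_size, order=1)
    return np.clip(img, 0.0, 1.0)


def augment_global(
    image: np.ndarray,
    spec: AugmentationSpec | None = None,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """One heavily augmented view under T_G; output re-clipped to [0, 1]."""
    spec = spec or AugmentationSpec.global_default(out_size=image.shape[0])
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return _augment_view(image, spec, rng)


def augment_local(
    image: np.ndarray,
    spec: AugmentationSpec | None = None,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """One view under T_L.  Specs containing horizontal flips are rejected:
    the local contrastive comparison relies on feature localization."""
    spec = spec or AugmentationSpec.local_default(out_size=image.shape[0])
    if spec.hflip_prob != 0.0:
        raise ValueError("T_L must not contain horizontal flips (hflip_prob must be 0)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return _augment_view(image, spec, rng)
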