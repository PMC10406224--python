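"""Synthetic head-CT phantom: HU volumes with ground-truth hemorrhage masks.

The generator emulates the structure a slice-wise segmentation pipeline
actually relies on, not CT physics: an air background (about -1000 HU), a
high-attenuation elliptical skull shell (about +1000 HU), brain parenchyma
(about +30 HU) with CSF-filled ventricles (about +5 HU), and hyperdense
hemorrhage lesions drawn from the 40-90 HU interval typical of acute
hematoma.  Lesion geometry mimics the five clinical subtypes at cartoon
level:

* IPH - an elliptical blob inside the parenchyma;
* IVH - a blob confined to the ventricle region;
* SDH - a thin crescent hugging the inner skull boundary over a wide arc;
* EDH - a thicker lens on the inner skull boundary over a short arc;
* SAH - a thin, irregular band near the cortical periphery.

Every volume carries a voxel-wise binary hemorrhage mask, per-subtype
masks, the intracranial-cavity mask, and slice-level weak labels in the
7-way order (no-ICH, ICH, IPH, IVH, SAH, SDH, EDH).  Generation is fully
seeded and reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "SUBTYPES",
    "WEAK_LABEL_CLASSES",
    "PhantomConfig",
    "HUVolume",
    "LabeledVolume",
    "PlacementError",
    "generate_volume",
    "generate_dataset",
    "voxel_volume",
    "weak_labels_from_masks",
]

SUBTYPES = ("IPH", "IVH", "SAH", "SDH", "EDH")
WEAK_LABEL_CLASSES = ("no-ICH", "ICH") + SUBTYPES

#: normalized elliptical radius of the inner skull boundary (cavity edge)
_RHO_CAVITY = 0.88


class PlacementError(RuntimeError):
    """Raised when a lesion cannot be placed after bounded retries."""


@dataclass(frozen=True)
class PhantomConfig:
    image_size: int = 64
    n_slices: int = 24
    spacing: tuple[float, float, float] = (3.0, 3.0, 5.0)
    hu_air: float = -1000.0
    hu_brain: float = 30.0
    hu_csf: float = 5.0
    hu_skull: float = 1000.0
    hu_lesion_range: tuple[float, float] = (40.0, 90.0)
    noise_sd: float = 4.0
    subtype_mix: tuple[float, ...] = (0.30, 0.15, 0.20, 0.20, 0.15)
    ich_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 16 or self.n_slices < 1:
            raise ValueError("image_size >= 16 and n_slices >= 1 required")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        lo, hi = self.hu_lesion_range
        if not (self.hu_brain < lo < hi < self.hu_skull):
            raise ValueError("hu_lesion_range must lie strictly between brain and skull HU")
        if len(self.subtype_mix) != len(SUBTYPES):
            raise ValueError(f"subtype_mix needs {len(SUBTYPES)} entries")
        if abs(sum(self.subtype_mix) - 1.0) > 1e-8 or any(p < 0 for p in self.subtype_mix):
            raise ValueError("subtype_mix must be a probability vector summing to 1")
        if not 0.0 <= self.ich_fraction <= 1.0:
            raise ValueError("ich_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class HUVolume:
    """3D grid of Hounsfield units, slice axis last, with voxel spacing in mm."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    volume_id: str = ""

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be 3D (H, W, n_slices)")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxels must be finite")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[2]


@dataclass
class LabeledVolume:
    volume: HUVolume
    ich_mask: np.ndarray
    icm_mask: np.ndarray
    subtype_masks: dict[str, np.ndarray]
    weak_labels: np.ndarray  # (n_slices, 7) in WEAK_LABEL_CLASSES order
    clean_voxels: np.ndarray | None = field(default=None, repr=False)

    def validate(self) -> None:
        shape = self.volume.voxels.shape
        for name, m in [("ich_mask", self.ich_mask), ("icm_mask", self.icm_mask)] + [
            (k, v) for k, v in self.subtype_masks.items()
        ]:
            if m.shape != shape:
                raise ValueError(f"{name} shape {m.shape} != volume shape {shape}")
            if not np.isin(m, (0, 1)).all():
                raise ValueError(f"{name} must be binary")
        union = np.zeros(shape, dtype=bool)
        for m in self.subtype_masks.values():
            union |= m.astype(bool)
        if not np.array_equal(union, self.ich_mask.astype(bool)):
            raise ValueError("ich_mask must equal the union of subtype masks")
        if np.any(self.ich_mask.astype(bool) & ~self.icm_mask.astype(bool)):
            raise ValueError("ich_mask must be contained in icm_mask")
        expected = weak_labels_from_masks(self.ich_mask, self.subtype_masks)
        if not np.array_equal(expected, self.weak_labels):
            raise ValueError("weak labels inconsistent with masks")


def weak_labels_from_masks(ich_mask: np.ndarray, subtype_masks: dict[str, np.ndarray]) -> np.ndarray:
    """Recompute the per-slice 7-way weak-label matrix from voxel masks."""
    n_slices = ich_mask.shape[2]
    labels = np.zeros((n_slices, len(WEAK_LABEL_CLASSES)), dtype=np.int8)
    ich_present = ich_mask.reshape(-1, n_slices).any(axis=0)
    labels[:, 0] = ~ich_present
    labels[:, 1] = ich_present
    for j, name in enumerate(SUBTYPES):
        labels[:, 2 + j] = subtype_masks[name].reshape(-1, n_slices).any(axis=0)
    return labels


def voxel_volume(spacing) -> float:
    """Voxel volume in mm^3 (product of edge lengths), rounded to 2 decimals
    for display — e.g. (0.33, 0.33, 5) mm -> 0.54 mm^3."""
    sx, sy, sz = spacing
    if sx <= 0 or sy <= 0 or sz <= 0:
        raise ValueError("spacing must be strictly positive")
    return round(float(sx * sy * sz), 2)


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _head_geometry(config: PhantomConfig, rng: np.random.Generator):
    """Per-volume head geometry: centers, semi-axes, z profile, ventricles."""
    s = config.image_size
    nz = config.n_slices
    cx = s / 2 + rng.uniform(-0.02, 0.02) * s
    cy = s / 2 + rng.uniform(-0.02, 0.02) * s
    ax = 0.40 * s * rng.uniform(0.95, 1.05)
    ay = 0.34 * s * rng.uniform(0.95, 1.05)
    zc = (nz - 1) / 2
    zextent = max(nz * 0.75, 1.0)
    zscale = np.sqrt(np.clip(1.0 - ((np.arange(nz) - zc) / zextent) ** 2, 0.2, 1.0))
    # two lateral ventricles, present on the middle band of slices
    v_dy = 0.10 * s
    v_rx, v_ry = 0.13 * s, 0.055 * s
    v_slices = np.abs(np.arange(nz) - zc) <= 0.35 * nz
    return dict(cx=cx, cy=cy, ax=ax, ay=ay, zscale=zscale,
                v_dy=v_dy, v_rx=v_rx, v_ry=v_ry, v_slices=v_slices)


def _rho(geom, z, shape):
    """Normalized elliptical radius field for slice z (1.0 = outer skull)."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    sz = geom["zscale"][z]
    return np.sqrt(
        ((yy - geom["cx"]) / (geom["ax"] * sz)) ** 2
        + ((xx - geom["cy"]) / (geom["ay"] * sz)) ** 2
    )


def _theta(geom, shape):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return np.arctan2(xx - geom["cy"], yy - geom["cx"])


def _ventricle_slice(geom, z, shape):
    if not geom["v_slices"][z]:
        return np.zeros(shape, dtype=bool)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    mask = np.zeros(shape, dtype=bool)
    for sign in (-1, 1):
        mask |= (
            ((yy - geom["cx"]) / geom["v_rx"]) ** 2
            + ((xx - (geom["cy"] + sign * geom["v_dy"])) / geom["v_ry"]) ** 2
        ) <= 1.0
    return mask


def _wrapped_angle_diff(theta, theta0):
    d = theta - theta0
    return np.abs((d + np.pi) % (2 * np.pi) - np.pi)


def _lesion_slice_mask(subtype, geom, z, shape, params, rng):
    """2D lesion support on slice z for one lesion (before cavity clipping)."""
    rho = _rho(geom, z, shape)
    cavity = rho < _RHO_CAVITY
    vent = _ventricle_slice(geom, z, shape)
    if subtype == "IPH":
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        py, px, rx, ry, ang = params
        ca, sa = np.cos(ang), np.sin(ang)
        u = (yy - py) * ca + (xx - px) * sa
        v = -(yy - py) * sa + (xx - px) * ca
        blob = (u / rx) ** 2 + (v / ry) ** 2 <= 1.0
        return blob & (rho < 0.80) & ~vent
    if subtype == "IVH":
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        py, px, r = params
        blob = (yy - py) ** 2 + (xx - px) ** 2 <= r**2
        return blob & vent
    theta = _theta(geom, shape)
    if subtype == "SDH":
        theta0, half_arc, width = params
        band = (rho >= _RHO_CAVITY - width) & cavity
        return band & (_wrapped_angle_diff(theta, theta0) <= half_arc)
    if subtype == "EDH":
        theta0, half_arc, width = params
        dtheta = _wrapped_angle_diff(theta, theta0)
        # lens: thickest at the arc center, tapering to the edges
        local_w = width * np.clip(1.0 - (dtheta / max(half_arc, 1e-6)) ** 2, 0.0, 1.0)
        return (rho >= _RHO_CAVITY - local_w) & cavity & (dtheta <= half_arc)
    if subtype == "SAH":
        theta0, half_arc, speckle = params
        band = (rho >= 0.72) & (rho < _RHO_CAVITY - 0.01) & cavity
        return band & (_wrapped_angle_diff(theta, theta0) <= half_arc) & speckle
    raise ValueError(f"unknown subtype '{subtype}'")


def _draw_lesion_params(subtype, config, geom, rng):
    s = config.image_size
    if subtype == "IPH":
        ang = rng.uniform(0, np.pi)
        r = rng.uniform(0.30, 0.55)
        phi = rng.uniform(0, 2 * np.pi)
        py = geom["cx"] + r * geom["ax"] * 0.8 * np.cos(phi)
        px = geom["cy"] + r * geom["ay"] * 0.8 * np.sin(phi)
        return (py, px, rng.uniform(0.06, 0.13) * s, rng.uniform(0.05, 0.11) * s, ang)
    if subtype == "IVH":
        sign = rng.choice((-1, 1))
        py = geom["cx"] + rng.uniform(-0.5, 0.5) * geom["v_rx"]
        px = geom["cy"] + sign * geom["v_dy"]
        return (py, px, rng.uniform(0.5, 1.4) * geom["v_rx"])
    theta0 = rng.uniform(-np.pi, np.pi)
    if subtype == "SDH":
        # crescent thickness as a fraction of the cavity radius; sized like the
        # moderate-to-large collections that are realistic segmentation targets
        return (theta0, np.deg2rad(rng.uniform(50, 80)), rng.uniform(0.09, 0.15))
    if subtype == "EDH":
        return (theta0, np.deg2rad(rng.uniform(25, 45)), rng.uniform(0.16, 0.26))
    # SAH: irregular speckle pattern shared across the lesion's slices
    noise = rng.standard_normal((s, s))
    speckle = ndimage.gaussian_filter(noise, sigma=1.5) > -0.15
    return (theta0, np.deg2rad(rng.uniform(60, 120)), speckle)


def _sample_subtype(config, rng) -> str:
    return SUBTYPES[rng.choice(len(SUBTYPES), p=np.asarray(config.subtype_mix))]


def generate_volume(
    config: PhantomConfig,
    with_ich: bool = True,
    seed: int | None = None,
    volume_id: str = "phantom",
    max_retries: int = 50,
) -> LabeledVolume:
    """Generate one labeled phantom volume.

    Deterministic for fixed ``(config, with_ich, seed)``.  If ``with_ich``,
    between 1 and 3 lesions are placed with subtype frequencies following
    ``config.subtype_mix``; each lesion's HU values are drawn from
    ``config.hu_lesion_range`` (before additive noise).  Raises
    :class:`PlacementError` if a lesion cannot be placed.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    s, nz = config.image_size, config.n_slices
    geom = _head_geometry(config, rng)
    shape2d = (s, s)

    clean = np.full((s, s, nz), config.hu_air, dtype=np.float32)
    icm = np.zeros((s, s, nz), dtype=np.uint8)
    for z in range(nz):
        rho = _rho(geom, z, shape2d)
        sl = np.full(shape2d, config.hu_air, dtype=np.float32)
        sl[rho <= 1.0] = config.hu_skull
        cavity = rho < _RHO_CAVITY
        sl[cavity] = config.hu_brain
        vent = _ventricle_slice(geom, z, shape2d) & cavity
        sl[vent] = config.hu_csf
        clean[:, :, z] = sl
        icm[:, :, z] = cavity

    subtype_masks = {name: np.zeros((s, s, nz), dtype=np.uint8) for name in SUBTYPES}
    if with_ich:
        n_lesions = int(rng.integers(1, 4))
        lo, hi = config.hu_lesion_range
        jitter = min(5.0, (hi - lo) / 4.0)
        for _ in range(n_lesions):
            placed = False
            for _attempt in range(max_retries):
                subtype = _sample_subtype(config, rng)
                if subtype == "IVH":
                    candidates = np.flatnonzero(geom["v_slices"])
                else:
                    candidates = np.arange(nz)
                zc = int(rng.choice(candidates))
                dz = int(rng.integers(1, 3))
                zlo, zhi = max(0, zc - dz), min(nz, zc + dz + 1)
                params = _draw_lesion_params(subtype, config, geom, rng)
                mask3d = np.zeros((s, s, nz), dtype=bool)
                for z in range(zlo, zhi):
                    m = _lesion_slice_mask(subtype, geom, z, shape2d, params, rng)
                    mask3d[:, :, z] = m & icm[:, :, z].astype(bool)
                if mask3d.sum() >= 8:
                    base = rng.uniform(lo + jitter, hi - jitter)
                    vox_jitter = rng.uniform(-jitter, jitter, size=int(mask3d.sum()))
                    clean[mask3d] = np.clip(base + vox_jitter, lo, hi).astype(np.float32)
                    subtype_masks[subtype][mask3d] = 1
                    placed = True
                    break
            if not placed:
                raise PlacementError(
                    f"could not place a lesion in volume '{volume_id}' "
                    f"after {max_retries} retries"
                )

    ich = np.zeros((s, s, nz), dtype=np.uint8)
    for m in subtype_masks.values():
        ich |= m
    noisy = clean + rng.normal(0.0, config.noise_sd, size=clean.shape).astype(
        np.float32
    ) if config.noise_sd > 0 else clean.copy()

    labeled = LabeledVolume(
        volume=HUVolume(noisy, config.spacing, volume_id),
        ich_mask=ich,
        icm_mask=icm,
        subtype_masks=subtype_masks,
        weak_labels=weak_labels_from_masks(ich, subtype_masks),
        clean_voxels=clean,
    )
    labeled.validate()
    return labeled


def generate_dataset(
    config: PhantomConfig,
    n_volumes: int,
    seed: int | None = None,
) -> tuple[list[LabeledVolume], pd.DataFrame]:
    """Generate a dataset with exactly ``round(ich_fraction * n_volumes)``
    hemorrhage volumes, plus a manifest of per-volume ICH presence and
    subtype inventory."""
    if n_volumes < 1:
        raise ValueError("n_volumes must be >= 1")
    base_seed = config.seed if seed is None else seed
    rng = np.random.default_rng(base_seed)
    n_ich = int(round(config.ich_fraction * n_volumes))
    flags = np.zeros(n_volumes, dtype=bool)
    flags[rng.permutation(n_volumes)[:n_ich]] = True
    volumes, rows = [], []
    for i in range(n_volumes):
        vid = f"vol_{i:03d}"
        vol_seed = int((base_seed * 1_000_003 + 7919 * i + 1) % 2**31)
        lv = generate_volume(config, with_ich=bool(flags[i]), seed=vol_seed, volume_id=vid)
        volumes.append(lv)
        row = {
            "volume_id": vid,
            "n_slices": lv.volume.n_slices,
            "ich": bool(lv.ich_mask.any()),
        }
        for name in SUBTYPES:
            row[name.lower()] = bool(lv.subtype_masks[name].any())
        rows.append(row)
    manifest = pd.DataFrame(rows)
    return volumes, manifest


def dataset_from_manifest(config: PhantomConfig, manifest: pd.DataFrame, seed: int):
    """Regenerate the volumes a manifest describes (same seeds as generate_dataset)."""
    n = len(manifest)
    volumes = []
    for i, row in manifest.reset_index(drop=True).iterrows():
        vol_seed = int((seed * 1_000_003 + 7919 * i + 1) % 2**31)
        volumes.append(
            generate_volume(config, with_ich=bool(row["ich"]), seed=vol_seed,
                            volume_id=row["volume_id"])
        )
    return volumes
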