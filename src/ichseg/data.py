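"""Slice-level data containers shared by the training stages.

A :class:`SliceDataset` holds windowed 2D slices with optional voxel masks
and slice-level weak labels, and enforces the label requirements of each
method: a self-supervised pretext task is handed a dataset whose mask and
weak-label accessors are locked, so any accidental label use fails loudly
(and every access is counted for the audit trail).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phantom import LabeledVolume, WEAK_LABEL_CLASSES
from .preprocess import WindowSpec, SEGMENTATION_WINDOW, window_rescale, resize_image

__all__ = ["SliceSample", "SliceDataset", "LabelAccessError", "volumes_to_dataset"]


class LabelAccessError(RuntimeError):
    """A stage read labels its supervision level forbids."""


@dataclass(frozen=True)
class SliceSample:
    """One windowed 2D slice with optional voxel mask and 7-way weak label."""

    image: np.ndarray
    mask: np.ndarray | None
    weak_label: np.ndarray | None
    volume_id: str
    slice_index: int


@dataclass
class SliceDataset:
    _images: np.ndarray                      # (N, H, W) in [0, 1]
    _masks: np.ndarray | None = None         # (N, H, W) binary
    _weak_labels: np.ndarray | None = None   # (N, 7)
    volume_ids: list[str] = field(default_factory=list)
    slice_indices: np.ndarray | None = None
    allow_masks: bool = True
    allow_weak_labels: bool = True
    audit: dict = field(default_factory=lambda: {"mask_reads": 0, "weak_label_reads": 0})

    def __len__(self) -> int:
        return len(self._images)

    @property
    def images(self) -> np.ndarray:
        return self._images

    @property
    def masks(self) -> np.ndarray:
        if not self.allow_masks:
            raise LabelAccessError("segmentation masks are locked for this stage")
        if self._masks is None:
            raise ValueError("dataset carries no masks")
        self.audit["mask_reads"] += 1
        return self._masks

    @property
    def weak_labels(self) -> np.ndarray:
        if not self.allow_weak_labels:
            raise LabelAccessError("weak labels are locked for this stage")
        if self._weak_labels is None:
            raise ValueError("dataset carries no weak labels")
        self.audit["weak_label_reads"] += 1
        return self._weak_labels

    def has_masks(self) -> bool:
        return self._masks is not None and self.allow_masks

    def has_weak_labels(self) -> bool:
        return self._weak_labels is not None and self.allow_weak_labels

    def restricted(self, allow_masks: bool, allow_weak_labels: bool) -> "SliceDataset":
        """A view with tighter permissions, sharing arrays and the audit log."""
        return SliceDataset(
            _images=self._images,
            _masks=self._masks,
            _weak_labels=self._weak_labels,
            volume_ids=self.volume_ids,
            slice_indices=self.slice_indices,
            allow_masks=allow_masks and self.allow_masks,
            allow_weak_labels=allow_weak_labels and self.allow_weak_labels,
            audit=self.audit,
        )

    def subset(self, idx) -> "SliceDataset":
        idx = np.asarray(idx)
        return SliceDataset(
            _images=self._images[idx],
            _masks=None if self._masks is None else self._masks[idx],
            _weak_labels=None if self._weak_labels is None else self._weak_labels[idx],
            volume_ids=[self.volume_ids[i] for i in idx],
            slice_indices=None if self.slice_indices is None else self.slice_indices[idx],
            allow_masks=self.allow_masks,
            allow_weak_labels=self.allow_weak_labels,
            audit=self.audit,
        )


def volumes_to_dataset(
    volumes: list[LabeledVolume],
    window: WindowSpec = SEGMENTATION_WINDOW,
    out_size: int | None = None,
    mask_source: str = "ich",
) -> SliceDataset:
    """Window every slice of every volume into one dataset.

    ``mask_source`` selects the voxel ground truth: "ich" (hemorrhage) or
    "icm" (intracranial cavity, used to train the cavity masker).
    """
    if mask_source not in ("ich", "icm"):
        raise ValueError("mask_source must be 'ich' or 'icm'")
    images, masks, weaks, vids, sidx = [], [], [], [], []
    for lv in volumes:
        win = window_rescale(lv.volume.voxels, window)
        src = lv.ich_mask if mask_source == "ich" else lv.icm_mask
        for z in range(lv.volume.n_slices):
            img = win[:, :, z]
            msk = src[:, :, z]
            if out_size is not None and img.shape != (out_size, out_size):
                img = resize_image(img, out_size, order=1)
                msk = (resize_image(msk.astype(np.float32), out_size, order=0) > 0.5)
            images.append(img.astype(np.float32))
            masks.append(np.asarray(msk, dtype=np.uint8))
            weaks.append(lv.weak_labels[z])
            vids.append(lv.volume.volume_id)
            sidx.append(z)
    return SliceDataset(
        _images=np.stack(images),
        _masks=np.stack(masks),
        _weak_labels=np.stack(weaks).astype(np.int8),
        volume_ids=vids,
        slice_indices=np.array(sidx),
    )


def weak_label_names() -> tuple[str, ...]:
    return WEAK_LABEL_CLASSES
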