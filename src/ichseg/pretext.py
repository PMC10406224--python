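"""The six pretext pre-training drivers.

Self-supervised (no labels touched):

* ``restoration`` — context restoration: N patch-pair swaps corrupt each
  slice and the full U-Net is trained to undo them under an MSE loss; the
  whole network transfers downstream.
* ``global`` — SimCLR-style contrastive task: every slice is augmented
  twice under T_G, embedded by the encoder + MLP projection head
  (512-512-128 at full scale), and trained with the temperature-scaled
  NT-Xent loss over the mini-batch; only the encoder transfers.
* ``local`` — local contrastive task: view pairs under T_L pass through the
  encoder plus a three-block partial decoder (skips kept) and a 1x1 conv
  projection head; matching feature-map regions across views are positives,
  all other sampled regions negatives.  The encoder is initialized from a
  prior ``global`` checkpoint and frozen; encoder + partial decoder transfer.

Weakly-supervised (slice-level classification labels only):

* ``binary`` — ICH present vs. absent, softmax cross-entropy;
* ``multilabel_ce`` — 7-way sigmoid head, class-weighted binary CE
  (weights = inverse class frequency on the training split, mean 1);
* ``multilabel_dl`` — same head trained with the Dice loss on the 7-vector.

All three classification tasks transfer the encoder only.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from . import losses
from .data import SliceDataset
from .nn import Adam, Checkpoint
from .preprocess import AugmentationSpec, augment_global, augment_local
from .unet import (
    ClassifierHead,
    EncoderWithHead,
    MLPProjectionHead,
    TransferScope,
    UNetSpec,
    backbone_state,
    build_partial_decoder,
    build_unet,
    transfer_weights,
)

__all__ = [
    "PRETEXT_TASKS",
    "TASK_SCOPES",
    "CorruptionConfig",
    "PretextRunConfig",
    "corrupt_context",
    "build_global_batch",
    "build_local_batch",
    "make_multilabel_target",
    "balance_slices",
    "run_pretext",
    "PretextPretrainer",
]

PRETEXT_TASKS = (
    "restoration",
    "global",
    "local",
    "binary",
    "multilabel_ce",
    "multilabel_dl",
)

#: which parameter groups each task's checkpoint initializes downstream
TASK_SCOPES = {
    "restoration": TransferScope.FULL_NETWORK,
    "global": TransferScope.ENCODER_ONLY,
    "local": TransferScope.ENCODER_PLUS_PARTIAL_DECODER,
    "binary": TransferScope.ENCODER_ONLY,
    "multilabel_ce": TransferScope.ENCODER_ONLY,
    "multilabel_dl": TransferScope.ENCODER_ONLY,
}

_SELF_SUPERVISED = ("restoration", "global", "local")
_CLASSIFICATION = ("binary", "multilabel_ce", "multilabel_dl")


@dataclass(frozen=True)
class CorruptionConfig:
    """Context-restoration corruption: n_swaps patch-pair exchanges
    (20 swaps of 20x20 pixels at full scale)."""

    n_swaps: int = 20
    patch_h: int = 20
    patch_w: int = 20

    def __post_init__(self):
        if self.n_swaps < 0:
            raise ValueError("n_swaps must be >= 0")
        if self.patch_h < 1 or self.patch_w < 1:
            raise ValueError("patch dimensions must be positive")


def corrupt_context(
    image: np.ndarray,
    config: CorruptionConfig = CorruptionConfig(),
    seed: int | np.random.Generator = 0,
    return_swaps: bool = False,
):
    """Sequentially swap ``n_swaps`` pairs of equal-size patches.

    The two patches of one swap are drawn uniformly and redrawn until
    disjoint, so the output is always a pixel permutation of the input
    (successive swaps may overlap freely).  ``n_swaps = 0`` is the identity.
    """
    img = np.array(image, dtype=np.float32, copy=True)
    h, w = img.shape
    ph, pw = config.patch_h, config.patch_w
    if ph > h or pw > w:
        raise ValueError(f"patch {ph}x{pw} larger than image {h}x{w}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    swaps = []
    for _ in range(config.n_swaps):
        for _try in range(1000):
            r1, c1 = int(rng.integers(0, h - ph + 1)), int(rng.integers(0, w - pw + 1))
            r2, c2 = int(rng.integers(0, h - ph + 1)), int(rng.integers(0, w - pw + 1))
            if abs(r1 - r2) >= ph or abs(c1 - c2) >= pw:
                break
        else:
            raise RuntimeError("could not draw disjoint patches")
        a = img[r1 : r1 + ph, c1 : c1 + pw].copy()
        img[r1 : r1 + ph, c1 : c1 + pw] = img[r2 : r2 + ph, c2 : c2 + pw]
        img[r2 : r2 + ph, c2 : c2 + pw] = a
        swaps.append(((r1, c1), (r2, c2)))
    return (img, swaps) if return_swaps else img


def build_global_batch(images: np.ndarray, spec_tg: AugmentationSpec | None = None,
                       seed: int = 0):
    """Augment each image twice under T_G; returns (2N views, pairing) where
    partner(2k) = 2k+1 (a fixed-point-free involution)."""
    return _build_view_batch(images, spec_tg, seed, augment_global)


def build_local_batch(images: np.ndarray, spec_tl: AugmentationSpec | None = None,
                      seed: int = 0):
    """As :func:`build_global_batch` but with the localization-preserving T_L."""
    return _build_view_batch(images, spec_tl, seed, augment_local)


def _build_view_batch(images, spec, seed, augmenter):
    images = np.asarray(images)
    if images.ndim != 3 or len(images) < 1:
        raise ValueError("images must be a non-empty (N, H, W) stack")
    rng = np.random.default_rng(seed)
    views = []
    for img in images:
        views.append(augmenter(img, spec, seed=rng))
        views.append(augmenter(img, spec, seed=rng))
    pairing = np.arange(2 * len(images)) ^ 1
    return np.stack(views), pairing


def make_multilabel_target(subtype_flags, ich: int | None = None) -> np.ndarray:
    """7-way weak-label vector (no-ICH, ICH, IPH, IVH, SAH, SDH, EDH).

    ``subtype_flags`` is a 5-vector over (IPH, IVH, SAH, SDH, EDH); ``ich``
    defaults to "any subtype present".  A subtype flag without the ICH flag
    is inconsistent and raises.
    """
    flags = np.asarray(subtype_flags, dtype=int)
    if flags.shape != (5,) or not np.isin(flags, (0, 1)).all():
        raise ValueError("subtype_flags must be a binary 5-vector")
    any_sub = int(flags.any())
    if ich is None:
        ich = any_sub
    ich = int(ich)
    if any_sub and not ich:
        raise ValueError("inconsistent weak label: subtype flagged but ICH = 0")
    return np.array([1 - ich, ich, *flags], dtype=np.int8)


def balance_slices(
    dataset: SliceDataset, validation_n: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Class-balanced train/validation slice index lists.

    Keeps an equal number of hemorrhage and hemorrhage-free slices (the
    minority count each), holds out ``validation_n`` of them for validation,
    and returns disjoint (train_idx, validation_idx).
    """
    weak = dataset.weak_labels
    ich_idx = np.flatnonzero(weak[:, 1] == 1)
    normal_idx = np.flatnonzero(weak[:, 1] == 0)
    n_each = min(len(ich_idx), len(normal_idx))
    if n_each == 0:
        raise ValueError("need slices of both classes to balance")
    if validation_n >= 2 * n_each:
        raise ValueError(
            f"validation_n={validation_n} leaves no training data (2x{n_each} balanced slices)"
        )
    rng = np.random.default_rng(seed)
    keep = np.concatenate([
        rng.permutation(ich_idx)[:n_each],
        rng.permutation(normal_idx)[:n_each],
    ])
    keep = rng.permutation(keep)
    return keep[validation_n:], keep[:validation_n]


@dataclass(frozen=True)
class PretextRunConfig:
    """Desk-scale defaults; the full-scale schedule in the study used 50
    epochs with task-specific batch sizes (32/60/24/64) at 256x256."""

    task: str = "binary"
    epochs: int = 3
    batch_size: int = 16
    lr: float = 1e-3
    lr_decay_base: float = 0.96
    l2: float = 1e-6
    image_size: int = 64
    base_channels: int = 8
    corruption: CorruptionConfig = CorruptionConfig(n_swaps=10, patch_h=8, patch_w=8)
    temperature: float = 0.1
    n_regions: int = 20
    region_size: int = 3
    augment_views: bool = True
    #: geometric augmentation of classification-pretext slices; on small
    #: slice pools this discourages shortcut features (weak labels are
    #: invariant under the segmentation-style geometric chain)
    augment_slices: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.task not in PRETEXT_TASKS:
            raise ValueError(f"unknown pretext task '{self.task}'")
        for v in (self.epochs, self.batch_size, self.image_size, self.base_channels):
            if v < 1:
                raise ValueError("hyperparameters must be positive")


class PretextPretrainer:
    """Trains one pretext task and emits a transferable checkpoint.

    Fitted attribute ``checkpoint_`` holds the backbone-rooted weights with
    task and transfer-scope metadata; ``history_`` the per-epoch loss trace.
    """

    def __init__(self, config: PretextRunConfig, init_checkpoint: Checkpoint | None = None):
        self.config = config
        self.init_checkpoint = init_checkpoint

    def get_params(self, deep: bool = True) -> dict:
        return {"config": self.config, "init_checkpoint": self.init_checkpoint}

    def set_params(self, **params) -> "PretextPretrainer":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    # ------------------------------------------------------------------
    def fit(self, dataset: SliceDataset, val_dataset: SliceDataset | None = None):
        cfg = self.config
        task = cfg.task
        if task in _CLASSIFICATION and not dataset.has_weak_labels():
            raise ValueError(f"task '{task}' needs slice-level weak labels")
        if task == "local" and self.init_checkpoint is None:
            raise ValueError(
                "the local contrastive task must be initialized from a "
                "global contrastive checkpoint"
            )
        spec = UNetSpec(base_channels=cfg.base_channels)
        rng = np.random.default_rng(cfg.seed)
        trainer = {
            "restoration": self._fit_restoration,
            "global": self._fit_global,
            "local": self._fit_local,
            "binary": self._fit_classification,
            "multilabel_ce": self._fit_classification,
            "multilabel_dl": self._fit_classification,
        }[task]
        net, history = trainer(dataset, spec, rng)
        self.history_ = history
        self.checkpoint_ = Checkpoint(
            state=backbone_state(net),
            meta={
                "task": task,
                "transfer_scope": TASK_SCOPES[task].value,
                "unet_spec": asdict(spec),
                "loss_trace": history,
            },
        )
        return self

    # ------------------------------------------------------------------
    def _epochs(self, n: int, rng, opt):
        cfg = self.config
        for epoch in range(cfg.epochs):
            opt.set_epoch(epoch)
            yield epoch, [
                idx
                for idx in np.array_split(
                    rng.permutation(n), max(1, n // cfg.batch_size)
                )
                if len(idx)
            ]

    def _fit_restoration(self, dataset, spec, rng):
        cfg = self.config
        net = build_unet(spec, seed=cfg.seed)
        opt = Adam(net, lr=cfg.lr, l2=cfg.l2, lr_decay_base=cfg.lr_decay_base)
        imgs = dataset.images
        history = []
        for _epoch, batches in self._epochs(len(imgs), rng, opt):
            losses_epoch = []
            for idx in batches:
                originals = imgs[idx]
                corrupted = np.stack(
                    [corrupt_context(im, cfg.corruption, seed=rng) for im in originals]
                )
                out = net(corrupted[:, None].astype(np.float32), training=True)
                loss, dout = losses.restoration_loss_grad(out, originals[:, None])
                net.zero_grad()
                net.backward(dout.astype(np.float32))
                opt.step()
                losses_epoch.append(loss)
            history.append(float(np.mean(losses_epoch)))
        return net, history

    def _fit_global(self, dataset, spec, rng):
        cfg = self.config
        backbone = build_unet(spec, seed=cfg.seed)
        bott = spec.bottleneck_channels
        head = MLPProjectionHead((bott, bott, max(bott // 4, 8)),
                                 np.random.default_rng(cfg.seed + 1))
        net = EncoderWithHead(backbone, head)
        opt = Adam(net, lr=cfg.lr, l2=cfg.l2, lr_decay_base=cfg.lr_decay_base)
        imgs = dataset.images
        tg = AugmentationSpec.global_default(out_size=cfg.image_size) if cfg.augment_views else None
        ccfg = losses.ContrastiveConfig(temperature=cfg.temperature)
        history = []
        for _epoch, batches in self._epochs(len(imgs), rng, opt):
            losses_epoch = []
            for idx in batches:
                views, pairing = _augmented_views(imgs[idx], tg, augment_global, rng)
                z = net(views[:, None].astype(np.float32), training=True)
                loss, dz = losses.global_nce_loss_grad(z, ccfg, pairing)
                net.zero_grad()
                net.backward(dz.astype(np.float32))
                opt.step()
                losses_epoch.append(loss / len(views))
            history.append(float(np.mean(losses_epoch)))
        return backbone, history

    def _fit_local(self, dataset, spec, rng):
        cfg = self.config
        source = build_unet(spec, seed=cfg.seed)
        transfer_weights(self.init_checkpoint, source, TransferScope.ENCODER_ONLY)
        net = build_partial_decoder(source, seed=cfg.seed + 1)
        # the encoder stays frozen: only the partial decoder and head learn
        opt = Adam(net, lr=cfg.lr, l2=cfg.l2, lr_decay_base=cfg.lr_decay_base,
                   frozen_prefixes=("backbone.enc.",))
        imgs = dataset.images
        tl = AugmentationSpec.local_default(out_size=cfg.image_size) if cfg.augment_views else None
        ccfg = losses.ContrastiveConfig(temperature=cfg.temperature)
        rcfg = losses.RegionConfig(n_regions=cfg.n_regions, region_size=cfg.region_size)
        history = []
        for _epoch, batches in self._epochs(len(imgs), rng, opt):
            losses_epoch = []
            for idx in batches:
                views, _ = _augmented_views(imgs[idx], tl, augment_local, rng)
                fmaps = net(views[:, None].astype(np.float32), training=True)
                dmaps = np.zeros_like(fmaps)
                total = 0.0
                n_pairs = len(views) // 2
                for j in range(n_pairs):
                    corners = losses.sample_regions(
                        fmaps.shape[2:], rcfg, rng
                    )
                    lval, d1, d2 = losses.local_nce_loss_grad(
                        fmaps[2 * j], fmaps[2 * j + 1], rcfg, ccfg, corners=corners
                    )
                    total += lval
                    dmaps[2 * j] = d1 / n_pairs
                    dmaps[2 * j + 1] = d2 / n_pairs
                net.zero_grad()
                net.backward(dmaps.astype(np.float32))
                opt.step()
                losses_epoch.append(total / max(n_pairs, 1))
            history.append(float(np.mean(losses_epoch)))
        return net.backbone, history

    def _fit_classification(self, dataset, spec, rng):
        cfg = self.config
        task = cfg.task
        backbone = build_unet(spec, seed=cfg.seed)
        bott = spec.bottleneck_channels
        n_out = 2 if task == "binary" else 7
        head = ClassifierHead((bott, 2 * bott, max(bott // 2, 8), n_out),
                              np.random.default_rng(cfg.seed + 1))
        net = EncoderWithHead(backbone, head)
        opt = Adam(net, lr=cfg.lr, l2=cfg.l2, lr_decay_base=cfg.lr_decay_base)
        imgs = dataset.images
        weak = dataset.weak_labels
        if task == "binary":
            targets = weak[:, 1].astype(int)
            class_weights = None
        else:
            targets = weak.astype(np.float64)
            freq = targets.mean(axis=0)
            inv = 1.0 / np.clip(freq, 1e-3, None)
            class_weights = inv / inv.mean()  # inverse frequency, mean 1
        aug_spec = AugmentationSpec.segmentation_default(out_size=cfg.image_size)
        history = []
        for _epoch, batches in self._epochs(len(imgs), rng, opt):
            losses_epoch = []
            for idx in batches:
                batch_imgs = imgs[idx]
                if cfg.augment_slices:
                    batch_imgs = np.stack(
                        [_augment_image_only(im, aug_spec, rng) for im in batch_imgs]
                    )
                logits = net(batch_imgs[:, None].astype(np.float32), training=True)
                if task == "binary":
                    loss, dlogits = losses.softmax_ce_loss_grad(logits, targets[idx])
                elif task == "multilabel_ce":
                    loss, dlogits = losses.weighted_bce_loss_grad(
                        logits, targets[idx], class_weights
                    )
                else:  # multilabel_dl
                    q = 1.0 / (1.0 + np.exp(-logits))
                    loss, dq = losses.multilabel_dice_loss_grad(q, targets[idx])
                    dlogits = dq * q * (1 - q)
                net.zero_grad()
                net.backward(dlogits.astype(np.float32))
                opt.step()
                losses_epoch.append(loss)
            history.append(float(np.mean(losses_epoch)))
        return backbone, history


def _augment_image_only(image, spec, rng):
    from .preprocess import augment_seg

    out, _ = augment_seg(image, np.zeros_like(image, dtype=np.uint8), spec, seed=rng)
    return out


def _augmented_views(images, spec, augmenter, rng):
    if spec is None:
        # no augmentation: both views identical (degenerate, for smoke tests)
        views = np.repeat(images, 2, axis=0)
        return views, np.arange(len(views)) ^ 1
    views = []
    for img in images:
        views.append(augmenter(img, spec, seed=rng))
        views.append(augmenter(img, spec, seed=rng))
    return np.stack(views), np.arange(2 * len(images)) ^ 1


def run_pretext(
    task: str,
    dataset: SliceDataset,
    config: PretextRunConfig | None = None,
    init_checkpoint: Checkpoint | None = None,
) -> Checkpoint:
    """Train one pretext task on a slice dataset and return its checkpoint."""
    if config is None:
        config = PretextRunConfig(task=task)
    elif config.task != task:
        raise ValueError(f"config.task '{config.task}' != requested task '{task}'")
    trainer = PretextPretrainer(config, init_checkpoint=init_checkpoint)
    trainer.fit(dataset)
    return trainer.checkpoint_
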