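"""Fine-tuning stage: training the 2D U-Net for hemorrhage segmentation.

Two supervision modes are provided, matching the study design:

* ``ich_only`` — train on hemorrhage-containing slices only, plain Dice loss;
* ``mixed``   — all hemorrhage slices plus ``normal_slice_multiplier`` times
  as many hemorrhage-free slices (sampled once, without replacement), with
  empty-ground-truth slices down-weighted by ``alpha`` in the loss.

The estimator can start from a fresh network or from a pretext checkpoint
copied in under a :class:`~ichseg.unet.TransferScope`; transferred weights
are never frozen.  Inference is slice-by-slice: each slice is windowed,
resized to the training resolution, passed through the network, and the
sigmoid map is resized back to the native grid before thresholding
(default 0.5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from . import losses
from .data import volumes_to_dataset
from .nn import Adam, Checkpoint, recalibrate_batchnorm
from .phantom import HUVolume, LabeledVolume
from .preprocess import (
    AugmentationSpec,
    SEGMENTATION_WINDOW,
    WindowSpec,
    augment_seg,
    resize_image,
    window_rescale,
)
from .unet import TransferScope, UNet, UNetSpec, build_unet, transfer_weights

__all__ = [
    "FinetuneConfig",
    "ICHSegmenter",
    "select_training_slices",
    "finetune",
    "predict_volume",
]


@dataclass(frozen=True)
class FinetuneConfig:
    """Fine-tuning hyper-parameters.

    Full-scale runs in the study used 100 epochs / batch 16 (smaller
    dataset) or 40 epochs / batch 32 (larger dataset); the defaults here
    are the desk-scale profile used with the phantom generator.
    """

    mode: str = "mixed"
    normal_slice_multiplier: int = 2
    alpha: float = 0.2
    epochs: int = 10
    batch_size: int = 16
    lr: float = 1e-3
    lr_decay_base: float = 0.96
    l2: float = 1e-6
    threshold: float = 0.5
    image_size: int = 64
    base_channels: int = 8
    augment: bool = True
    redraw_normals_each_epoch: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("ich_only", "mixed"):
            raise ValueError("mode must be 'ich_only' or 'mixed'")
        if self.normal_slice_multiplier < 0:
            raise ValueError("normal_slice_multiplier must be >= 0")
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must be in [0, 1]")


def select_training_slices(
    volumes: list[LabeledVolume],
    mode: str = "mixed",
    normal_slice_multiplier: int = 2,
    seed: int = 0,
) -> list[tuple[str, int]]:
    """Pick training slices from a fold-train split.

    ``ich_only`` returns every hemorrhage slice; ``mixed`` adds
    ``multiplier * n_ich`` hemorrhage-free slices sampled uniformly without
    replacement (capped at availability, with a warning).  Pure function of
    (split, parameters, seed).
    """
    ich, normal = [], []
    for lv in volumes:
        present = lv.ich_mask.reshape(-1, lv.volume.n_slices).any(axis=0)
        for z in range(lv.volume.n_slices):
            (ich if present[z] else normal).append((lv.volume.volume_id, z))
    if not ich:
        raise ValueError("training split contains no hemorrhage slices")
    if mode == "ich_only":
        return ich
    rng = np.random.default_rng(seed)
    n_want = normal_slice_multiplier * len(ich)
    if n_want > len(normal):
        warnings.warn(
            f"requested {n_want} normal slices but only {len(normal)} available; using all"
        )
        n_want = len(normal)
    pick = rng.choice(len(normal), size=n_want, replace=False) if n_want else []
    return ich + [normal[i] for i in sorted(pick)]


class ICHSegmenter(BaseEstimator):
    """Slice-wise U-Net hemorrhage segmenter (sklearn-style estimator).

    Parameters mirror :class:`FinetuneConfig`; ``init_checkpoint`` plus
    ``transfer_scope`` seed the network from a pretext task.  Fitted
    attributes: ``net_`` (the trained U-Net), ``history_`` (per-epoch mean
    training loss), ``selected_slices_``.
    """

    def __init__(
        self,
        mode: str = "mixed",
        normal_slice_multiplier: int = 2,
        alpha: float = 0.2,
        epochs: int = 10,
        batch_size: int = 16,
        lr: float = 1e-3,
        lr_decay_base: float = 0.96,
        l2: float = 1e-6,
        threshold: float = 0.5,
        image_size: int = 64,
        base_channels: int = 8,
        augment: bool = True,
        redraw_normals_each_epoch: bool = False,
        init_checkpoint: Checkpoint | None = None,
        transfer_scope: str | TransferScope | None = None,
        window: WindowSpec = SEGMENTATION_WINDOW,
        seed: int = 0,
    ):
        self.mode = mode
        self.normal_slice_multiplier = normal_slice_multiplier
        self.alpha = alpha
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.lr_decay_base = lr_decay_base
        self.l2 = l2
        self.threshold = threshold
        self.image_size = image_size
        self.base_channels = base_channels
        self.augment = augment
        self.redraw_normals_each_epoch = redraw_normals_each_epoch
        self.init_checkpoint = init_checkpoint
        self.transfer_scope = transfer_scope
        self.window = window
        self.seed = seed

    # ------------------------------------------------------------------
    def _build_net(self) -> UNet:
        spec = UNetSpec(base_channels=self.base_channels)
        net = build_unet(spec, seed=self.seed)
        if self.init_checkpoint is not None:
            scope = self.transfer_scope
            if scope is None:
                scope = self.init_checkpoint.meta.get("transfer_scope")
            if scope is None:
                raise ValueError("init_checkpoint given but no transfer scope")
            if isinstance(scope, str):
                scope = TransferScope(scope)
            transfer_weights(self.init_checkpoint, net, scope)
        return net

    def fit(self, volumes: list[LabeledVolume], y=None) -> "ICHSegmenter":
        cfg = FinetuneConfig(
            mode=self.mode,
            normal_slice_multiplier=self.normal_slice_multiplier,
            alpha=self.alpha,
            epochs=self.epochs,
            batch_size=self.batch_size,
            lr=self.lr,
            lr_decay_base=self.lr_decay_base,
            l2=self.l2,
            threshold=self.threshold,
            image_size=self.image_size,
            base_channels=self.base_channels,
            augment=self.augment,
            redraw_normals_each_epoch=self.redraw_normals_each_epoch,
            seed=self.seed,
        )
        ds = volumes_to_dataset(volumes, window=self.window, out_size=self.image_size)
        index = {(v, int(z)): i for i, (v, z) in enumerate(zip(ds.volume_ids, ds.slice_indices))}
        rng = np.random.default_rng(self.seed)
        mix_cfg = losses.MixedLossConfig(alpha=self.alpha)
        net = self._build_net()
        opt = Adam(net, lr=self.lr, l2=self.l2, lr_decay_base=self.lr_decay_base)
        aug_spec = AugmentationSpec.segmentation_default(out_size=self.image_size)

        selection = select_training_slices(
            volumes, cfg.mode, cfg.normal_slice_multiplier, seed=self.seed
        )
        self.selected_slices_ = list(selection)
        history = []
        for epoch in range(self.epochs):
            if self.redraw_normals_each_epoch and cfg.mode == "mixed" and epoch > 0:
                selection = select_training_slices(
                    volumes, cfg.mode, cfg.normal_slice_multiplier, seed=self.seed + epoch
                )
            idx = np.array([index[key] for key in selection])
            order = rng.permutation(len(idx))
            epoch_losses = []
            opt.set_epoch(epoch)
            for start in range(0, len(order), self.batch_size):
                batch = idx[order[start : start + self.batch_size]]
                imgs = ds.images[batch]
                msks = ds.masks[batch]
                if self.augment:
                    pairs = [
                        augment_seg(im, mk, aug_spec, seed=rng)
                        for im, mk in zip(imgs, msks)
                    ]
                    imgs = np.stack([p[0] for p in pairs])
                    msks = np.stack([p[1] for p in pairs])
                x = imgs[:, None].astype(np.float32)
                t = msks[:, None].astype(np.float32)
                logits = net(x, training=True)
                p = 1.0 / (1.0 + np.exp(-logits))
                if cfg.mode == "mixed":
                    loss, dp = losses.mixed_dice_loss_grad(p, t, mix_cfg)
                else:
                    loss, dp = losses.dice_loss_grad(p, t)
                dlogits = (dp * p * (1.0 - p)).astype(np.float32)
                net.zero_grad()
                net.backward(dlogits)
                opt.step()
                epoch_losses.append(loss)
            history.append(float(np.mean(epoch_losses)))
        # precise-BN pass: set running statistics to dataset statistics under
        # the final weights (short schedules leave the momentum averages stale)
        calib_idx = np.array([index[key] for key in selection])
        calib_batches = [
            ds.images[calib_idx[s : s + self.batch_size]][:, None].astype(np.float32)
            for s in range(0, len(calib_idx), self.batch_size)
        ]
        recalibrate_batchnorm(net, calib_batches)
        self.net_ = net
        self.history_ = history
        self.config_ = cfg
        return self

    # ------------------------------------------------------------------
    def predict_proba_volume(self, volume: HUVolume | LabeledVolume) -> np.ndarray:
        """Per-voxel sigmoid probabilities on the volume's native grid."""
        if isinstance(volume, LabeledVolume):
            volume = volume.volume
        if not hasattr(self, "net_"):
            raise RuntimeError("estimator is not fitted")
        win = window_rescale(volume.voxels, self.window)
        native = win.shape[:2]
        probs = np.zeros(win.shape, dtype=np.float32)
        nz = win.shape[2]
        bs = max(1, self.batch_size)
        resized = np.stack(
            [resize_image(win[:, :, z], self.image_size, order=1) for z in range(nz)]
        )
        for start in range(0, nz, bs):
            x = resized[start : start + bs][:, None].astype(np.float32)
            p = self.net_.predict_proba(x)[:, 0]
            for k in range(p.shape[0]):
                pm = p[k]
                if pm.shape != native:
                    zoom_back = resize_image(pm, native[0], order=1)
                    probs[:, :, start + k] = zoom_back
                else:
                    probs[:, :, start + k] = pm
        return probs

    def predict(self, volume: HUVolume | LabeledVolume, threshold: float | None = None):
        """Binary mask: sigmoid probability map thresholded at ``threshold``."""
        t = self.threshold if threshold is None else threshold
        return _apply_threshold(self.predict_proba_volume(volume), t)


def _apply_threshold(probs: np.ndarray, t: float) -> np.ndarray:
    # degenerate endpoints: t=1 keeps nothing, t=0 keeps everything
    if t >= 1.0:
        return (probs > 1.0).astype(np.uint8)
    return (probs >= t).astype(np.uint8)


def finetune(
    init: Checkpoint | None,
    volumes: list[LabeledVolume],
    config: FinetuneConfig = FinetuneConfig(),
    transfer_scope: str | TransferScope | None = None,
) -> ICHSegmenter:
    """Functional wrapper: fit an :class:`ICHSegmenter` on a training split."""
    est = ICHSegmenter(
        mode=config.mode,
        normal_slice_multiplier=config.normal_slice_multiplier,
        alpha=config.alpha,
        epochs=config.epochs,
        batch_size=config.batch_size,
        lr=config.lr,
        lr_decay_base=config.lr_decay_base,
        l2=config.l2,
        threshold=config.threshold,
        image_size=config.image_size,
        base_channels=config.base_channels,
        augment=config.augment,
        redraw_normals_each_epoch=config.redraw_normals_each_epoch,
        init_checkpoint=init,
        transfer_scope=transfer_scope,
        seed=config.seed,
    )
    return est.fit(volumes)


def predict_volume(
    model: ICHSegmenter,
    volume: HUVolume | LabeledVolume,
    threshold: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """(binary mask, probability map) for one volume."""
    probs = model.predict_proba_volume(volume)
    t = model.threshold if threshold is None else threshold
    return _apply_threshold(probs, t), probs
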