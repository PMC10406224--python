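"""Experiment orchestration and volume I/O.

:func:`run_experiment` wires the two-stage workflow together: Stage 1
optionally pre-trains a pretext task on a separate unlabeled (or weakly
labeled) phantom pool; Stage 2 fine-tunes the segmentation U-Net per
cross-validation fold from that initialization and evaluates volume-wise.
Each method sees exactly the labels its supervision level permits —
self-supervised stages receive datasets whose mask/weak-label accessors are
locked, and the audit log of label reads is part of the result bundle.

Randomness is controlled by one global seed fanned out per stage as
``crc32(stage_name) XOR seed`` (mod 2^31), so adding or reordering stages
does not shift any other stage's stream.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

import nibabel as nib

from .data import volumes_to_dataset
from .evaluate import (
    MetricConfig,
    confusion_counts,
    make_report,
    stratified_volume_folds,
    volume_metrics,
    MethodReport,
)
from .finetune import FinetuneConfig, ICHSegmenter
from .icm import CavityMasker, ICMConfig, apply_icm
from .phantom import HUVolume, PhantomConfig, generate_dataset
from .pretext import PRETEXT_TASKS, PretextPretrainer, PretextRunConfig

__all__ = [
    "ExperimentConfig",
    "run_experiment",
    "stage_seed",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
]

_SELF_SUPERVISED = ("restoration", "global", "local")
_BASELINES = ("ich_only", "mixed")


def stage_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed: crc32 of the stage name XOR the global seed, < 2^31."""
    return (zlib.crc32(stage.encode()) ^ (global_seed & 0x7FFFFFFF)) % 2**31


@dataclass(frozen=True)
class ExperimentConfig:
    phantom: PhantomConfig = PhantomConfig()
    n_volumes: int = 12
    n_pretext_volumes: int = 12
    k_folds: int = 3
    methods: tuple[str, ...] = ("ich_only", "mixed")
    finetune: FinetuneConfig = FinetuneConfig(epochs=3)
    pretext: PretextRunConfig = PretextRunConfig(epochs=2)
    use_icm: bool = False
    icm: ICMConfig = ICMConfig(epochs=2)
    n_icm_volumes: int = 4
    seed: int = 0

    def __post_init__(self):
        for m in self.methods:
            if m not in _BASELINES + PRETEXT_TASKS:
                raise ValueError(f"unknown method '{m}'")

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _balanced_indices(volumes, seed: int) -> np.ndarray:
    """Class-balanced slice indices computed from volume metadata (dataset
    curation happens before any supervision restriction applies)."""
    flags = np.concatenate([lv.weak_labels[:, 1] for lv in volumes])
    ich = np.flatnonzero(flags == 1)
    normal = np.flatnonzero(flags == 0)
    n = min(len(ich), len(normal))
    rng = np.random.default_rng(seed)
    keep = np.concatenate([rng.permutation(ich)[:n], rng.permutation(normal)[:n]])
    return rng.permutation(keep)


def run_experiment(config: ExperimentConfig, out_dir: str | Path | None = None) -> dict:
    """Run the configured methods end-to-end; returns a result bundle with
    one method report per method, shared fold assignments, the label-access
    audit, and the config hash stamped on every artifact."""
    seed = config.seed
    volumes, manifest = generate_dataset(
        config.phantom, config.n_volumes, seed=stage_seed(seed, "labeled_data")
    )
    folds = stratified_volume_folds(manifest, config.k_folds, seed=stage_seed(seed, "folds"))
    by_id = {lv.volume.volume_id: lv for lv in volumes}

    needs_pretext = [m for m in config.methods if m in PRETEXT_TASKS]
    pretext_ckpts: dict[str, object] = {}
    audits: dict[str, dict] = {}
    if needs_pretext:
        pvols, _ = generate_dataset(
            config.phantom, config.n_pretext_volumes, seed=stage_seed(seed, "pretext_data")
        )
        pds_full = volumes_to_dataset(pvols, out_size=config.pretext.image_size)
        keep = _balanced_indices(pvols, stage_seed(seed, "balance"))
        pds_full = pds_full.subset(keep)
        for task in needs_pretext:
            if task in _SELF_SUPERVISED:
                ds = pds_full.restricted(allow_masks=False, allow_weak_labels=False)
            else:
                ds = pds_full.restricted(allow_masks=False, allow_weak_labels=True)
            ds.audit.update({"mask_reads": 0, "weak_label_reads": 0})
            init = None
            if task == "local":
                if "global" not in pretext_ckpts:
                    gcfg = _task_config(config.pretext, "global", stage_seed(seed, "pretext:global"))
                    gtrainer = PretextPretrainer(gcfg)
                    gtrainer.fit(pds_full.restricted(False, False))
                    pretext_ckpts["global"] = gtrainer.checkpoint_
                init = pretext_ckpts["global"]
            cfg = _task_config(config.pretext, task, stage_seed(seed, f"pretext:{task}"))
            trainer = PretextPretrainer(cfg, init_checkpoint=init)
            trainer.fit(ds)
            pretext_ckpts[task] = trainer.checkpoint_
            audits[task] = dict(ds.audit)

    masker = None
    if config.use_icm:
        icm_vols, _ = generate_dataset(
            config.phantom, config.n_icm_volumes, seed=stage_seed(seed, "icm_data")
        )
        masker = CavityMasker(config.icm).fit(icm_vols)

    reports: dict[str, MethodReport] = {}
    for method in config.methods:
        rows = []
        for fold in range(config.k_folds):
            train = [by_id[v] for v in folds.train_volumes(fold)]
            test = [by_id[v] for v in folds.test_volumes(fold)]
            fc = config.finetune
            est = ICHSegmenter(
                mode="ich_only" if method == "ich_only" else "mixed",
                normal_slice_multiplier=fc.normal_slice_multiplier,
                alpha=fc.alpha,
                epochs=fc.epochs,
                batch_size=fc.batch_size,
                lr=fc.lr,
                lr_decay_base=fc.lr_decay_base,
                l2=fc.l2,
                threshold=fc.threshold,
                image_size=fc.image_size,
                base_channels=fc.base_channels,
                augment=fc.augment,
                init_checkpoint=pretext_ckpts.get(method),
                seed=stage_seed(seed, f"finetune:{method}:{fold}"),
            )
            est.fit(train)
            for lv in test:
                pred = est.predict(lv)
                if masker is not None:
                    pred = apply_icm(pred, masker.predict(lv))
                d, p, r = volume_metrics(confusion_counts(pred, lv.ich_mask), MetricConfig())
                rows.append(
                    {"volume_id": lv.volume.volume_id, "fold": fold,
                     "dice": d, "precision": p, "recall": r}
                )
        report = make_report(pd.DataFrame(rows), manifest, method=method)
        reports[method] = report

    bundle = {
        "config_hash": config.config_hash(),
        "seed": seed,
        "fold_assignment": {k: int(v) for k, v in sorted(folds.assignment.items())},
        "label_audit": audits,
        "methods": {
            m: {"summary": r.summary} for m, r in sorted(reports.items())
        },
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "summary.json").write_text(json.dumps(bundle, indent=2, sort_keys=True))
        for m, r in reports.items():
            r.rows.to_csv(out / f"rows_{m}.csv", index=False)
    bundle["reports"] = reports
    return bundle


def _task_config(base: PretextRunConfig, task: str, seed: int) -> PretextRunConfig:
    return PretextRunConfig(
        task=task,
        epochs=base.epochs,
        batch_size=base.batch_size,
        lr=base.lr,
        lr_decay_base=base.lr_decay_base,
        l2=base.l2,
        image_size=base.image_size,
        base_channels=base.base_channels,
        corruption=base.corruption,
        temperature=base.temperature,
        n_regions=base.n_regions,
        region_size=base.region_size,
        augment_views=base.augment_views,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def write_volume(volume: HUVolume, path: str | Path) -> None:
    """HU volume to NIfTI with voxel spacing on the affine diagonal."""
    affine = np.diag([*volume.spacing, 1.0])
    img = nib.Nifti1Image(volume.voxels.astype(np.float32), affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def read_volume(path: str | Path) -> HUVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float32)
    if np.isnan(data).any():
        raise ValueError(f"NaN voxels in {path}")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise ValueError(f"missing or invalid spacing in {path}")
    return HUVolume(data, tuple(float(z) for z in zooms), Path(path).stem.split(".")[0])


def write_mask(mask: np.ndarray, spacing, path: str | Path) -> None:
    affine = np.diag([*spacing, 1.0])
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine)
    img.header.set_zooms(spacing)
    nib.save(img, str(path))


def read_mask(path: str | Path) -> np.ndarray:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    uniq = np.unique(data)
    if not np.isin(uniq, (0, 1)).all():
        raise ValueError(f"mask {path} is not binary")
    return data.astype(np.uint8)
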