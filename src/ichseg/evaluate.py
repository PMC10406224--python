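"""Volume-wise evaluation: epsilon-stabilized Dice/precision/recall,
stratified volume-level cross-validation, dual-subset reporting, and
pairwise Welch t-tests between methods.

Metrics are aggregated over whole volumes (TP/FP/FN summed across all
slices of a scan) rather than per slice, and stabilized with an additive
epsilon (default 1) so that a hemorrhage-free volume with no detections
scores 1.0 on all three metrics:

    Dice      = (2 TP + eps) / (2 TP + FP + FN + eps)
    Precision = (TP + eps) / (TP + FP + eps)
    Recall    = (TP + eps) / (TP + FN + eps)

Reports state mean +- SD on two subsets — all volumes and hemorrhage
volumes only — because the all-volumes average rewards methods that simply
detect nothing on healthy scans.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConfusionCounts",
    "MetricConfig",
    "FoldAssignment",
    "MethodReport",
    "confusion_counts",
    "volume_metrics",
    "stratified_volume_folds",
    "make_report",
    "welch_pairwise",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int

    def __post_init__(self):
        if self.tp < 0 or self.fp < 0 or self.fn < 0:
            raise ValueError("counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


@dataclass(frozen=True)
class MetricConfig:
    epsilon: float = 1.0

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")


def confusion_counts(pred: np.ndarray, gt: np.ndarray) -> ConfusionCounts:
    """Voxelwise TP/FP/FN summed over the whole volume."""
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    p = pred.astype(bool)
    g = gt.astype(bool)
    return ConfusionCounts(
        tp=int(np.sum(p & g)), fp=int(np.sum(p & ~g)), fn=int(np.sum(~p & g))
    )


def volume_metrics(
    counts: ConfusionCounts, config: MetricConfig = MetricConfig()
) -> tuple[float, float, float]:
    """(Dice, precision, recall) with epsilon stabilization; each in (0, 1]."""
    eps = config.epsilon
    dice = (2 * counts.tp + eps) / (2 * counts.tp + counts.fp + counts.fn + eps)
    precision = (counts.tp + eps) / (counts.tp + counts.fp + eps)
    recall = (counts.tp + eps) / (counts.tp + counts.fn + eps)
    return float(dice), float(precision), float(recall)


@dataclass(frozen=True)
class FoldAssignment:
    """Partition of volumes into k folds; all slices of a volume share its fold."""

    assignment: dict[str, int]
    k: int

    def fold_of(self, volume_id: str) -> int:
        return self.assignment[volume_id]

    def test_volumes(self, fold: int) -> list[str]:
        return [v for v, f in self.assignment.items() if f == fold]

    def train_volumes(self, fold: int) -> list[str]:
        return [v for v, f in self.assignment.items() if f != fold]


def stratified_volume_folds(
    manifest: pd.DataFrame, k: int, seed: int = 0
) -> FoldAssignment:
    """Stratified k-fold split at the volume level.

    Hemorrhage volumes are spread across folds as evenly as possible (round
    robin over a shuffled order), then hemorrhage-free volumes fill the
    folds up so that fold sizes differ by at most one.  Deterministic for a
    given seed; requires at least k hemorrhage volumes.
    """
    if "volume_id" not in manifest or "ich" not in manifest:
        raise ValueError("manifest needs 'volume_id' and 'ich' columns")
    rng = np.random.default_rng(seed)
    ich_ids = list(manifest.loc[manifest["ich"].astype(bool), "volume_id"])
    normal_ids = list(manifest.loc[~manifest["ich"].astype(bool), "volume_id"])
    if len(ich_ids) < k:
        raise ValueError(f"need at least k={k} hemorrhage volumes, have {len(ich_ids)}")
    rng.shuffle(ich_ids)
    rng.shuffle(normal_ids)
    fold_order = rng.permutation(k)
    assignment: dict[str, int] = {}
    for pos, vid in enumerate(ich_ids + normal_ids):
        assignment[vid] = int(fold_order[pos % k])
    return FoldAssignment(assignment=assignment, k=k)


@dataclass
class MethodReport:
    """Per-volume metric rows plus mean +- SD summaries on the two subsets."""

    method: str
    rows: pd.DataFrame  # columns: volume_id, ich, dice, precision, recall, [subtypes]
    summary: dict = field(default_factory=dict)

    def subset(self, ich_only: bool) -> pd.DataFrame:
        return self.rows[self.rows["ich"].astype(bool)] if ich_only else self.rows


_METRICS = ("dice", "precision", "recall")


def make_report(
    rows: pd.DataFrame, manifest: pd.DataFrame | None = None, method: str = ""
) -> MethodReport:
    """Aggregate pooled per-volume metric rows into a method report.

    ``rows`` must contain volume_id, dice, precision, recall and (directly
    or via ``manifest``) the ich flag and subtype flags.  Summaries use the
    population SD convention (a single volume reports sigma = 0).
    """
    rows = rows.copy()
    if manifest is not None:
        meta_cols = [c for c in manifest.columns if c not in rows.columns]
        rows = rows.merge(manifest[["volume_id"] + meta_cols], on="volume_id", how="left")
    if rows["volume_id"].duplicated().any():
        raise ValueError("each volume must contribute exactly one row")
    summary: dict = {}
    for name, sub in (("all_volumes", rows), ("ich_volumes", rows[rows["ich"].astype(bool)])):
        summary[name] = {
            m: {
                "mean": float(sub[m].mean()) if len(sub) else float("nan"),
                "sd": float(sub[m].std(ddof=0)) if len(sub) else float("nan"),
                "n": int(len(sub)),
            }
            for m in _METRICS
        }
    subtype_cols = [c for c in ("iph", "ivh", "sah", "sdh", "edh") if c in rows.columns]
    per_subtype = {}
    for c in subtype_cols:
        sub = rows[rows[c].astype(bool)]
        per_subtype[c] = {
            "n": int(len(sub)),
            "dice_mean": float(sub["dice"].mean()) if len(sub) else float("nan"),
        }
    if per_subtype:
        summary["per_subtype"] = per_subtype
    return MethodReport(method=method, rows=rows, summary=summary)


def _welch_p(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("Welch test needs at least two observations per sample")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        # degenerate: identical constants are indistinguishable
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def welch_pairwise(metric_rows: dict[str, pd.DataFrame], metric: str = "dice") -> pd.DataFrame:
    """Two-sided Welch t-test p-values for every pair of methods.

    ``metric_rows`` maps a method name to its per-volume rows.  Returns a
    symmetric DataFrame with p = 1 on the diagonal.
    """
    methods = list(metric_rows)
    if len(methods) < 2:
        raise ValueError("need at least two methods to compare")
    pmat = pd.DataFrame(np.ones((len(methods), len(methods))), index=methods, columns=methods)
    for i, mi in enumerate(methods):
        for j in range(i + 1, len(methods)):
            mj = methods[j]
            p = _welch_p(metric_rows[mi][metric].to_numpy(), metric_rows[mj][metric].to_numpy())
            pmat.loc[mi, mj] = p
            pmat.loc[mj, mi] = p
    return pmat
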