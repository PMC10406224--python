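"""Training objectives: Dice, weighted mixed Dice, contrastive (NT-Xent)
global and local losses, restoration MSE, and the classification losses.

Every loss is exposed as a pure value function on numpy arrays; the
functions used inside training loops also have ``*_grad`` companions that
return ``(value, gradient)`` analytically, so the compact NN core needs no
autograd.  Conventions:

* Dice losses operate on sigmoid probabilities ``p`` in [0, 1] against
  binary targets ``t``; a symmetric smoothing constant ``s`` (default 1, the
  conventional V-Net-style smooth term) keeps the empty/empty case at
  0/0 -> 0 loss and, crucially, gives empty-ground-truth slices a non-
  vanishing gradient (with s ~ 0 an empty slice has loss ~ 1 but gradient
  ~ s/(sum p^2)^2, i.e. no suppression signal at all, and the down-weighted
  normal slices of the mixed loss would be training no-ops).
* Contrastive losses use temperature-scaled cosine similarity; the global
  loss sums the anchor cross-entropies over all 2N views of the batch, the
  local loss over the 2*N_r sampled region descriptors of a view pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MixedLossConfig",
    "ContrastiveConfig",
    "RegionConfig",
    "dice_loss",
    "dice_loss_grad",
    "mixed_dice_loss",
    "mixed_dice_loss_grad",
    "global_nce_loss",
    "global_nce_loss_grad",
    "sample_regions",
    "local_nce_loss",
    "local_nce_loss_grad",
    "restoration_loss",
    "restoration_loss_grad",
    "multilabel_dice_loss",
    "multilabel_dice_loss_grad",
    "weighted_bce_loss",
    "weighted_bce_loss_grad",
    "binary_ce_loss",
    "softmax_ce_loss_grad",
]

DEFAULT_SMOOTHING = 1.0


@dataclass(frozen=True)
class MixedLossConfig:
    """alpha down-weights slices whose ground truth is empty (default 0.2)."""

    alpha: float = 0.2
    smoothing: float = DEFAULT_SMOOTHING

    def __post_init__(self):
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if self.smoothing < 0:
            raise ValueError("smoothing must be >= 0")


@dataclass(frozen=True)
class ContrastiveConfig:
    temperature: float = 0.1

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")


@dataclass(frozen=True)
class RegionConfig:
    """Region sampling for the local loss: n_regions squares of side region_size."""

    n_regions: int = 20
    region_size: int = 3

    def __post_init__(self):
        if self.n_regions < 1 or self.region_size < 1:
            raise ValueError("n_regions and region_size must be >= 1")


# ---------------------------------------------------------------------------
# Dice family
# ---------------------------------------------------------------------------

def _check_shapes(a, b):
    if np.shape(a) != np.shape(b):
        raise ValueError(f"shape mismatch: {np.shape(a)} vs {np.shape(b)}")


def dice_loss(p: np.ndarray, t: np.ndarray, smoothing: float = DEFAULT_SMOOTHING) -> float:
    """Soft Dice loss  1 - (2<p,t> + s) / (|p|^2 + |t|^2 + s)  over all pixels."""
    p = np.asarray(p, dtype=np.float64)
    t = np.asarray(t, dtype=np.float64)
    _check_shapes(p, t)
    num = 2.0 * np.sum(p * t) + smoothing
    den = np.sum(p * p) + np.sum(t * t) + smoothing
    return float(1.0 - num / den)


def dice_loss_grad(p, t, smoothing=DEFAULT_SMOOTHING):
    p = np.asarray(p, dtype=np.float64)
    t = np.asarray(t, dtype=np.float64)
    _check_shapes(p, t)
    num = 2.0 * np.sum(p * t) + smoothing
    den = np.sum(p * p) + np.sum(t * t) + smoothing
    grad = -(2.0 * t * den - num * 2.0 * p) / den**2
    return float(1.0 - num / den), grad


def _per_slice_dice(p, t, smoothing):
    n = p.shape[0]
    pf = p.reshape(n, -1)
    tf = t.reshape(n, -1)
    num = 2.0 * np.sum(pf * tf, axis=1) + smoothing
    den = np.sum(pf * pf, axis=1) + np.sum(tf * tf, axis=1) + smoothing
    return num, den, pf, tf


def mixed_dice_loss(p_batch, t_batch, config: MixedLossConfig = MixedLossConfig()) -> float:
    """Mean over slices of the Dice loss, down-weighted by ``alpha`` on
    slices whose ground truth is entirely empty."""
    p = np.asarray(p_batch, dtype=np.float64)
    t = np.asarray(t_batch, dtype=np.float64)
    _check_shapes(p, t)
    num, den, _, tf = _per_slice_dice(p, t, config.smoothing)
    losses = 1.0 - num / den
    weights = np.where(tf.sum(axis=1) > 0, 1.0, config.alpha)
    return float(np.mean(weights * losses))


def mixed_dice_loss_grad(p_batch, t_batch, config: MixedLossConfig = MixedLossConfig()):
    p = np.asarray(p_batch, dtype=np.float64)
    t = np.asarray(t_batch, dtype=np.float64)
    _check_shapes(p, t)
    n = p.shape[0]
    num, den, pf, tf = _per_slice_dice(p, t, config.smoothing)
    losses = 1.0 - num / den
    weights = np.where(tf.sum(axis=1) > 0, 1.0, config.alpha)
    gf = -(2.0 * tf * den[:, None] - num[:, None] * 2.0 * pf) / (den**2)[:, None]
    grad = (weights[:, None] * gf / n).reshape(p.shape)
    return float(np.mean(weights * losses)), grad


# ---------------------------------------------------------------------------
# Contrastive family
# ---------------------------------------------------------------------------

def _cosine_matrix(z: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    norms = np.linalg.norm(z, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero-norm embedding: cosine similarity undefined")
    u = z / norms[:, None]
    return u @ u.T, u, norms


def _pairing_partner(n_views: int, pairing=None) -> np.ndarray:
    if pairing is not None:
        partner = np.asarray(pairing, dtype=int)
    else:
        partner = np.arange(n_views) ^ 1  # (0,1), (2,3), ...
    idx = np.arange(n_views)
    if n_views % 2 or np.any(partner[partner] != idx) or np.any(partner == idx):
        raise ValueError("pairing must be a fixed-point-free involution on 2N views")
    return partner


def _nce_core(z, tau, pairing):
    """Shared NT-Xent machinery: loss summed over all anchors + gradient wrt z."""
    z = np.asarray(z, dtype=np.float64)
    m = z.shape[0]
    partner = _pairing_partner(m, pairing)
    sim, u, norms = _cosine_matrix(z)
    s = sim / tau
    np.fill_diagonal(s, -np.inf)  # anchor never compared with itself
    smax = s.max(axis=1, keepdims=True)
    e = np.exp(s - smax)
    logz = np.log(e.sum(axis=1)) + smax[:, 0]
    pos = s[np.arange(m), partner]
    loss = float(np.sum(logz - pos))
    softmax = e / e.sum(axis=1, keepdims=True)
    ds = softmax.copy()
    ds[np.arange(m), partner] -= 1.0
    ds /= tau
    ds = ds + ds.T  # sim(i,k) feeds both anchors i and k
    du = ds @ u
    # back through the row normalization u_i = z_i / |z_i|
    dz = (du - u * np.sum(du * u, axis=1, keepdims=True)) / norms[:, None]
    return loss, dz


def global_nce_loss(
    embeddings: np.ndarray,
    config: ContrastiveConfig = ContrastiveConfig(),
    pairing=None,
) -> float:
    """NT-Xent over 2N view embeddings: for each anchor, the cross-entropy of
    picking its positive partner among the 2N-1 other views, summed over all
    anchors.  Default pairing is (0,1), (2,3), ...; scale-invariant in the
    embeddings (cosine similarity)."""
    loss, _ = _nce_core(embeddings, config.temperature, pairing)
    return loss


def global_nce_loss_grad(embeddings, config=ContrastiveConfig(), pairing=None):
    return _nce_core(embeddings, config.temperature, pairing)


def sample_regions(
    map_shape: tuple[int, int],
    regions: RegionConfig,
    rng: np.random.Generator,
    max_tries: int = 1000,
) -> np.ndarray:
    """Sample ``n_regions`` pairwise non-overlapping KxK top-left corners
    uniformly on an H x W feature map; returns an (n_regions, 2) array."""
    h, w = map_shape
    k = regions.region_size
    if regions.n_regions * k * k > h * w:
        raise ValueError("requested regions exceed the feature-map area")
    if k > h or k > w:
        raise ValueError("region larger than the feature map")
    chosen: list[tuple[int, int]] = []
    tries = 0
    while len(chosen) < regions.n_regions:
        if tries >= max_tries:
            raise RuntimeError("could not place non-overlapping regions")
        tries += 1
        r = int(rng.integers(0, h - k + 1))
        c = int(rng.integers(0, w - k + 1))
        if all(abs(r - r0) >= k or abs(c - c0) >= k for r0, c0 in chosen):
            chosen.append((r, c))
    return np.array(chosen, dtype=int)


def _region_descriptors(fmap, corners, k):
    """(C, H, W) map -> (n_regions, K*K*C) flattened descriptors."""
    descs = [fmap[:, r : r + k, c : c + k].reshape(-1) for r, c in corners]
    return np.stack(descs)


def local_nce_loss(
    f1: np.ndarray,
    f2: np.ndarray,
    regions: RegionConfig = RegionConfig(),
    config: ContrastiveConfig = ContrastiveConfig(),
    seed: int = 0,
    corners: np.ndarray | None = None,
) -> float:
    """Local contrastive loss between two view feature maps (C, H, W).

    N_r non-overlapping KxK regions are sampled once (seeded); the same
    locations are read from both maps.  Positives are the same location
    across views; negatives are all other sampled regions from both views.
    With a single region there are no negatives and the loss is 0.
    """
    loss, _, _ = _local_nce_core(f1, f2, regions, config, seed, corners)
    return loss


def local_nce_loss_grad(f1, f2, regions=RegionConfig(), config=ContrastiveConfig(),
                        seed=0, corners=None):
    loss, d1, d2 = _local_nce_core(f1, f2, regions, config, seed, corners)
    return loss, d1, d2


def _local_nce_core(f1, f2, regions, config, seed, corners):
    f1 = np.asarray(f1, dtype=np.float64)
    f2 = np.asarray(f2, dtype=np.float64)
    _check_shapes(f1, f2)
    if f1.ndim != 3:
        raise ValueError("feature maps must be (C, H, W)")
    k = regions.region_size
    if corners is None:
        corners = sample_regions(f1.shape[1:], regions, np.random.default_rng(seed))
    nr = len(corners)
    if nr == 1:
        return 0.0, np.zeros_like(f1), np.zeros_like(f2)
    d1 = _region_descriptors(f1, corners, k)
    d2 = _region_descriptors(f2, corners, k)
    # interleave so the default involution pairs same-location descriptors
    z = np.empty((2 * nr, d1.shape[1]), dtype=np.float64)
    z[0::2] = d1
    z[1::2] = d2
    loss, dz = _nce_core(z, config.temperature, None)
    g1 = np.zeros_like(f1)
    g2 = np.zeros_like(f2)
    c = f1.shape[0]
    for j, (r, col) in enumerate(corners):
        g1[:, r : r + k, col : col + k] += dz[2 * j].reshape(c, k, k)
        g2[:, r : r + k, col : col + k] += dz[2 * j + 1].reshape(c, k, k)
    return loss, g1, g2


# ---------------------------------------------------------------------------
# Restoration and classification losses
# ---------------------------------------------------------------------------

def restoration_loss(x_restored, x_original) -> float:
    """Mean squared error between the restored and the original image."""
    a = np.asarray(x_restored, dtype=np.float64)
    b = np.asarray(x_original, dtype=np.float64)
    _check_shapes(a, b)
    return float(np.mean((a - b) ** 2))


def restoration_loss_grad(x_restored, x_original):
    a = np.asarray(x_restored, dtype=np.float64)
    b = np.asarray(x_original, dtype=np.float64)
    _check_shapes(a, b)
    diff = a - b
    return float(np.mean(diff**2)), 2.0 * diff / diff.size


def multilabel_dice_loss(q, y, smoothing: float = DEFAULT_SMOOTHING) -> float:
    """Dice loss over the 7-way sigmoid outputs, batch-flattened."""
    return dice_loss(np.asarray(q).reshape(-1), np.asarray(y).reshape(-1), smoothing)


def multilabel_dice_loss_grad(q, y, smoothing: float = DEFAULT_SMOOTHING):
    q = np.asarray(q, dtype=np.float64)
    loss, grad = dice_loss_grad(q.reshape(-1), np.asarray(y).reshape(-1), smoothing)
    return loss, grad.reshape(q.shape)


_CLIP = 1e-7


def weighted_bce_loss(q, y, class_weights=None) -> float:
    """Mean over samples and classes of w_c * BCE(q_c, y_c)."""
    q = np.clip(np.asarray(q, dtype=np.float64), _CLIP, 1 - _CLIP)
    y = np.asarray(y, dtype=np.float64)
    _check_shapes(q, y)
    w = np.ones(q.shape[-1]) if class_weights is None else np.asarray(class_weights, dtype=np.float64)
    if np.any(w <= 0):
        raise ValueError("class weights must be positive")
    bce = -(y * np.log(q) + (1 - y) * np.log(1 - q))
    return float(np.mean(bce * w))


def weighted_bce_loss_grad(q_logits, y, class_weights=None):
    """Value and gradient with respect to the *logits* (sigmoid fused in)."""
    z = np.asarray(q_logits, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    _check_shapes(z, y)
    q = 1.0 / (1.0 + np.exp(-z))
    w = np.ones(z.shape[-1]) if class_weights is None else np.asarray(class_weights, dtype=np.float64)
    loss = weighted_bce_loss(q, y, w)
    grad = w * (q - y) / z.size
    return loss, grad


def binary_ce_loss(probs, labels) -> float:
    """Mean negative log-probability of the true class (softmax outputs)."""
    p = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    if not np.allclose(p.sum(axis=-1), 1.0, atol=1e-5):
        raise ValueError("rows must be softmax outputs summing to 1")
    picked = np.clip(p[np.arange(len(labels)), labels], _CLIP, 1.0)
    return float(np.mean(-np.log(picked)))


def softmax_ce_loss_grad(logits, labels):
    """Cross-entropy value and gradient with respect to the logits."""
    z = np.asarray(logits, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    zmax = z.max(axis=1, keepdims=True)
    e = np.exp(z - zmax)
    p = e / e.sum(axis=1, keepdims=True)
    n = len(labels)
    loss = float(np.mean(-np.log(np.clip(p[np.arange(n), labels], _CLIP, 1.0))))
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n
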