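"""Training and evaluation: dice loss, online augmentation, Adam-based
training, and DSC / ASSD evaluation with manual-vs-automated comparison.

Two overlap/distance metrics quantify segmentation quality:

* DSC(X, Y) = 2|X ∩ Y| / (|X| + |Y|) — the Dice similarity coefficient.
* ASSD — the average symmetric surface distance between the boundary
  point sets of the two masks.  The symmetric average is computed as
  (Σ_i d_i + Σ_j d_j*) / (N_seg + N_gt), i.e. pooling nearest-surface
  distances from both directions; a literal "paired" variant
  (1/N)·Σ(d_i + d_i*) is available for surfaces of equal size.

Evaluation applies the post-processing chain (0.5 threshold, largest
connected component, hole filling) before computing metrics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.stats import linregress

from .nn import autograd as F
from .nn.autograd import Tensor
from .nn.layers import Module
from .nn.models import fuse, predict
from .nn.optim import Adam
from .phantom import BScan
from .postprocess import clean_mask

__all__ = [
    "TrainConfig", "EvalReport", "dice_score", "assd", "dice_loss",
    "augment", "train", "evaluate", "compare_manual_auto", "surface_points",
]

logger = logging.getLogger(__name__)
_saturation_warned = False


@dataclass
class TrainConfig:
    """Hyper-parameters for :func:`train`.

    Augmentation follows the online policy of random rotations within
    ±``rotation_deg``, random horizontal flips, and photometric
    brightness/contrast jitter on the image only.
    """

    epochs: int = 20
    batch_size: int = 4
    learning_rate: float = 3e-3
    seed: int = 0
    augment: bool = True
    rotation_deg: float = 10.0
    flip_prob: float = 0.5
    jitter_strength: float = 0.1

    def validate(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0 <= self.flip_prob <= 1:
            raise ValueError("flip_prob must lie in [0, 1]")
        if self.rotation_deg < 0:
            raise ValueError("rotation_deg must be non-negative")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class EvalReport:
    """Per-image and aggregate DSC / ASSD statistics."""

    per_image: list = field(default_factory=list)  # (id, dsc, assd_px)

    @property
    def dsc_values(self) -> np.ndarray:
        return np.array([r[1] for r in self.per_image])

    @property
    def assd_values(self) -> np.ndarray:
        return np.array([r[2] for r in self.per_image])

    @property
    def dsc_mean(self) -> float:
        return float(self.dsc_values.mean())

    @property
    def dsc_sd(self) -> float:
        return float(self.dsc_values.std(ddof=1)) if len(self.per_image) > 1 else 0.0

    @property
    def dsc_max(self) -> float:
        return float(self.dsc_values.max())

    @property
    def assd_mean(self) -> float:
        return float(self.assd_values.mean())

    @property
    def assd_sd(self) -> float:
        return float(self.assd_values.std(ddof=1)) if len(self.per_image) > 1 else 0.0

    def summary(self) -> dict:
        return {
            "n": len(self.per_image),
            "dsc_mean": self.dsc_mean, "dsc_sd": self.dsc_sd,
            "dsc_max": self.dsc_max,
            "assd_mean": self.assd_mean, "assd_sd": self.assd_sd,
        }


# ---------------------------------------------------------------------- #
# metrics


def _as_bool_mask(m: np.ndarray, name: str) -> np.ndarray:
    m = np.asarray(m)
    if m.ndim != 2:
        raise ValueError(f"{name} must be 2-D")
    if not np.isin(m, (0, 1)).all():
        raise ValueError(f"{name} values must be exactly 0 or 1")
    return m.astype(bool)


def dice_score(X: np.ndarray, Y: np.ndarray) -> float:
    """Dice similarity coefficient 2|X∩Y|/(|X|+|Y|); two empty masks are
    in perfect agreement by convention (returns 1.0)."""
    X = _as_bool_mask(X, "X")
    Y = _as_bool_mask(Y, "Y")
    if X.shape != Y.shape:
        raise ValueError(f"shape mismatch: {X.shape} vs {Y.shape}")
    denom = int(X.sum()) + int(Y.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((X & Y).sum()) / denom


def surface_points(m: np.ndarray) -> np.ndarray:
    """(row, col) coordinates of boundary pixels: foreground pixels with
    at least one background 4-neighbour (image border counts as
    background)."""
    m = _as_bool_mask(m, "mask")
    interior = ndimage.binary_erosion(
        m, structure=ndimage.generate_binary_structure(2, 1), border_value=0)
    return np.argwhere(m & ~interior)


def assd(X: np.ndarray, Y: np.ndarray, paired: bool = False) -> float:
    """Average symmetric surface distance in pixels.

    Default: pooled symmetric average (Σd_i + Σd_j*)/(N_X + N_Y) over
    Euclidean nearest-boundary distances in both directions.  With
    ``paired=True`` the per-index sum (1/N)Σ(d_i + d_i*) is used, which
    requires both surfaces to have the same number of points.
    """
    sx = surface_points(X)
    sy = surface_points(Y)
    if len(sx) == 0 or len(sy) == 0:
        raise ValueError("assd requires two non-empty masks")
    if np.asarray(X).shape != np.asarray(Y).shape:
        raise ValueError("shape mismatch between masks")
    d_xy = cKDTree(sy).query(sx)[0]  # each X surface point -> nearest Y
    d_yx = cKDTree(sx).query(sy)[0]
    if paired:
        if len(sx) != len(sy):
            raise ValueError(
                "paired ASSD is only defined for surfaces of equal size "
                f"(got {len(sx)} and {len(sy)})")
        return float(np.mean(d_xy + d_yx))
    return float((d_xy.sum() + d_yx.sum()) / (len(sx) + len(sy)))


def dice_loss(p, Y, smooth: float = 1.0):
    """1 − soft Dice, with probabilities replacing set indicators and a
    smoothing constant stabilizing empty masks.

    Accepts numpy arrays (returns a float) or an autograd ``Tensor``
    probability map (returns a scalar ``Tensor`` for backprop).
    """
    if isinstance(p, Tensor):
        yt = Tensor(np.asarray(Y, dtype=float))
        if p.shape != yt.shape:
            raise ValueError(f"shape mismatch: {p.shape} vs {yt.shape}")
        inter = (p * yt).sum()
        denom = p.sum() + yt.sum() + smooth
        return 1.0 - (2.0 * inter + smooth) / denom
    p = np.asarray(p, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if p.shape != Y.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {Y.shape}")
    inter = (p * Y).sum()
    return float(1.0 - (2.0 * inter + smooth) / (p.sum() + Y.sum() + smooth))


# ---------------------------------------------------------------------- #
# augmentation


def augment(
    b: BScan,
    m: np.ndarray,
    seed: int,
    rotation_deg: float = 10.0,
    flip_prob: float = 0.5,
    jitter_strength: float = 0.1,
) -> tuple[BScan, np.ndarray]:
    """Seeded online augmentation: one random rotation within
    ±``rotation_deg`` and an optional horizontal flip applied identically
    to image and mask (nearest-neighbour for the mask, which therefore
    stays strictly binary); brightness/contrast jitter on the image only.
    Saturation jitter is a no-op on single-channel data and is logged
    once.
    """
    global _saturation_warned
    rng = np.random.default_rng(seed)
    img = b.pixels.copy()
    mask = _as_bool_mask(m, "mask").astype(np.uint8)
    background = float(img.min())

    angle = rng.uniform(-rotation_deg, rotation_deg)
    if angle != 0.0:
        img = ndimage.rotate(img, angle, reshape=False, order=1,
                             mode="constant", cval=background)
        mask = ndimage.rotate(mask, angle, reshape=False, order=0,
                              mode="constant", cval=0)
    if rng.random() < flip_prob:
        img = img[:, ::-1].copy()
        mask = mask[:, ::-1].copy()
    if jitter_strength > 0:
        img = img + rng.uniform(-jitter_strength, jitter_strength)
        factor = 1.0 + rng.uniform(-jitter_strength, jitter_strength)
        img = (img - img.mean()) * factor + img.mean()
        if not _saturation_warned:
            logger.info("saturation jitter skipped: undefined for "
                        "single-channel images")
            _saturation_warned = True
    img = np.clip(img, 0.0, 1.0)
    return (BScan(img, axial_scale=b.axial_scale, orientation=b.orientation),
            mask.astype(np.uint8))


# ---------------------------------------------------------------------- #
# training / evaluation


def train(
    model: Module,
    dataset: list[tuple[BScan, np.ndarray]],
    cfg: TrainConfig,
) -> tuple[Module, list[float]]:
    """Train a segmentation model with Adam on the dice loss.

    Returns ``(model, loss_history)`` where ``loss_history`` holds the
    mean dice loss of each epoch.  Fully reproducible given ``cfg.seed``.
    """
    cfg.validate()
    if not dataset:
        raise ValueError("training dataset is empty")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    model.train()
    history: list[float] = []
    n = len(dataset)
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):
            batch = [dataset[i] for i in order[start:start + cfg.batch_size]]
            imgs, masks = [], []
            for bscan, mask in batch:
                if cfg.augment:
                    bscan, mask = augment(
                        bscan, mask, seed=int(rng.integers(2**31 - 1)),
                        rotation_deg=cfg.rotation_deg,
                        flip_prob=cfg.flip_prob,
                        jitter_strength=cfg.jitter_strength)
                imgs.append(bscan.pixels)
                masks.append(mask)
            x = Tensor(np.stack(imgs)[:, None])
            y = np.stack(masks)[:, None].astype(float)
            p = model(x)
            loss = dice_loss(p, y)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(loss.item())
        history.append(float(np.mean(epoch_losses)))
        logger.info("epoch %d/%d: dice loss %.4f",
                    _epoch + 1, cfg.epochs, history[-1])
    return model, history


def predict_probability(
    models: Module | list[Module], image: np.ndarray
) -> np.ndarray:
    """Probability map from one model, or the late fusion (mean) of two."""
    if isinstance(models, Module):
        return predict(models, image)
    if len(models) == 1:
        return predict(models[0], image)
    if len(models) != 2:
        raise ValueError("fusion is defined for exactly two models")
    return fuse(predict(models[0], image), predict(models[1], image))


def evaluate(
    models: Module | list[Module],
    dataset: list[tuple[BScan, np.ndarray]],
    threshold: float = 0.5,
) -> EvalReport:
    """Evaluate one model (or the fusion of two) on (B-scan, ground truth)
    pairs.  Predictions are post-processed (threshold, largest component,
    hole fill) before DSC and ASSD are computed; an image on which a
    metric fails is excluded with a logged warning."""
    if not dataset:
        raise ValueError("evaluation dataset is empty")
    report = EvalReport()
    for i, (bscan, gt) in enumerate(dataset):
        prob = predict_probability(models, bscan.pixels)
        pred = clean_mask(prob, threshold=threshold)
        try:
            d = dice_score(pred, gt)
            a = assd(pred, gt)
        except ValueError as err:
            logger.warning("image %d excluded from evaluation: %s", i, err)
            continue
        report.per_image.append((i, d, a))
    if not report.per_image:
        raise ValueError("no image could be evaluated")
    return report


def compare_manual_auto(pairs) -> tuple[float, float, float]:
    """Ordinary least-squares comparison of manual vs automated thickness
    measurements (µm): returns ``(slope, intercept, pearson_r)``."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) < 3:
        raise ValueError("need at least 3 (manual, auto) pairs")
    manual, auto = arr[:, 0], arr[:, 1]
    if np.ptp(manual) == 0 or np.ptp(auto) == 0:
        raise ValueError("degenerate variance in measurement pairs")
    fit = linregress(manual, auto)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue)
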