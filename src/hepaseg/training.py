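"""Training: composite losses, adaptive weight boosting, schedules, drivers.

The vessel network trains with a weighted combination of cross-entropy, soft
Dice and focal losses (weights 0.2 / 0.6 / 0.2); the lobule network with
cross-entropy + Dice at 0.5 / 0.5.  Class imbalance is handled by adaptive
weight boosting: every 15 epochs, per-class loss weights of foreground
classes are multiplied by 1.3 / 1.2 / 1.1 when the class-wise validation
Dice falls in [0, 0.3) / [0.3, 0.5) / [0.5, 0.7), and left unchanged at 0.7
or above.  The learning rate follows cosine annealing
η_t = η_min + ½(η_max − η_min)(1 + cos(tπ/T)) from η_max = 5·10⁻⁴; the
optimizer is Adam with weight decay 2·10⁻⁴, batch size 8, up to 250 epochs
with early stopping after 20 stagnant validation epochs.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import metrics as _metrics
from .unet_models import UNet, UNetConfig, build_model
from .wsi_patching import DatasetSplit, LabelMask

__all__ = [
    "LossWeights", "VESSEL_LOSS_WEIGHTS", "LOBULE_LOSS_WEIGHTS",
    "BoostPolicy", "ClassWeights", "LRScheduleParams", "AugmentConfig",
    "TrainConfig", "cosine_lr", "boost_weights", "composite_loss",
    "softmax", "augment", "flip_pair", "rotate_pair", "train_model",
    "cross_validate",
]

_GAMMA = 2.0       # focal focusing parameter
_DICE_EPS = 1e-5   # soft-Dice smoothing
_P_MIN = 1e-7      # probability clip for logarithms


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LossWeights:
    """Mixing fractions of the composite loss; must sum to 1."""

    w_ce: float
    w_dice: float
    w_focal: float = 0.0

    def __post_init__(self) -> None:
        if min(self.w_ce, self.w_dice, self.w_focal) < 0:
            raise ValueError("loss weights must be nonnegative")
        if abs(self.w_ce + self.w_dice + self.w_focal - 1.0) > 1e-6:
            raise ValueError("loss weights must sum to 1")


VESSEL_LOSS_WEIGHTS = LossWeights(0.2, 0.6, 0.2)
LOBULE_LOSS_WEIGHTS = LossWeights(0.5, 0.5, 0.0)


@dataclass(frozen=True)
class BoostPolicy:
    """Adaptive weight-boosting schedule keyed to class-wise Dice scores."""

    period_epochs: int = 15
    thresholds: tuple[float, float, float] = (0.3, 0.5, 0.7)
    factors: tuple[float, float, float] = (1.3, 1.2, 1.1)
    weight_cap: float = 10.0

    def __post_init__(self) -> None:
        t, f = self.thresholds, self.factors
        if not (0 < t[0] < t[1] < t[2] < 1):
            raise ValueError("thresholds must be strictly increasing in (0,1)")
        if not (f[0] > f[1] > f[2] > 1):
            raise ValueError("factors must be strictly decreasing, all > 1")
        if self.period_epochs < 1 or self.weight_cap <= 0:
            raise ValueError("invalid boosting policy")


@dataclass
class ClassWeights:
    """Per-class loss weights; background (class 0) is never boosted."""

    values: np.ndarray
    epoch_updated: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if (self.values <= 0).any():
            raise ValueError("class weights must be positive")

    @classmethod
    def uniform(cls, n_classes: int) -> "ClassWeights":
        return cls(np.ones(n_classes))


@dataclass(frozen=True)
class LRScheduleParams:
    """Cosine annealing parameters (η_max at t=0, η_min at t=T)."""

    eta_max: float = 5e-4
    eta_min: float = 0.0
    T: int = 250

    def __post_init__(self) -> None:
        if not 0 <= self.eta_min < self.eta_max:
            raise ValueError("need 0 <= eta_min < eta_max")
        if self.T < 1:
            raise ValueError("T must be >= 1")


@dataclass(frozen=True)
class AugmentConfig:
    """Geometric + intensity augmentation applied to training pairs."""

    flip: bool = True
    rotate: bool = True
    intensity: bool = True
    angles: tuple[int, ...] = (30, 60, 90, 120, 150, 180, 270)


@dataclass(frozen=True)
class TrainConfig:
    """Full training configuration for one model."""

    model: UNetConfig
    epochs: int = 250
    batch_size: int = 8
    lr: LRScheduleParams = field(default_factory=LRScheduleParams)
    weight_decay: float = 2e-4
    patience: int = 20
    augment: AugmentConfig | None = field(default_factory=AugmentConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patience >= self.epochs and self.epochs > 1:
            object.__setattr__(self, "patience", self.epochs - 1)
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("invalid training configuration")


# ---------------------------------------------------------------------------
# schedules and boosting
# ---------------------------------------------------------------------------


def cosine_lr(t: int, p: LRScheduleParams) -> float:
    """Learning rate at epoch t: η_min + ½(η_max−η_min)(1 + cos(tπ/T))."""
    if not 0 <= t <= p.T:
        raise ValueError(f"epoch {t} outside [0, {p.T}]")
    return p.eta_min + 0.5 * (p.eta_max - p.eta_min) * (1 + np.cos(t * np.pi / p.T))


def boost_weights(w: ClassWeights, dice_by_class: dict[int, float],
                  policy: BoostPolicy, epoch: int) -> ClassWeights:
    """Multiply struggling foreground-class weights by the policy factors.

    Dice in [0, t1) → ×f1, [t1, t2) → ×f2, [t2, t3) → ×f3, ≥ t3 unchanged
    (defaults: <0.3 ×1.3, <0.5 ×1.2, <0.7 ×1.1).  Background is excluded;
    results are capped at ``policy.weight_cap``.  Weights never decrease.
    """
    if epoch % policy.period_epochs != 0:
        raise ValueError(
            f"boosting runs every {policy.period_epochs} epochs, got epoch {epoch}"
        )
    values = w.values.copy()
    t1, t2, t3 = policy.thresholds
    f1, f2, f3 = policy.factors
    for c in range(1, len(values)):
        if c not in dice_by_class:
            raise KeyError(f"class {c} missing from dice map")
        d = dice_by_class[c]
        if not 0 <= d <= 1:
            raise ValueError(f"dice for class {c} outside [0, 1]: {d}")
        if d < t1:
            values[c] *= f1
        elif d < t2:
            values[c] *= f2
        elif d < t3:
            values[c] *= f3
        values[c] = min(values[c], policy.weight_cap)
    return ClassWeights(values, epoch_updated=epoch)


# ---------------------------------------------------------------------------
# composite loss
# ---------------------------------------------------------------------------


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _as_target(target, n_classes: int, shape: tuple[int, int]) -> np.ndarray:
    grid = target.grid if isinstance(target, LabelMask) else np.asarray(target)
    if grid.shape != shape:
        raise ValueError(f"target shape {grid.shape} != scores {shape}")
    if grid.max(initial=0) >= n_classes:
        raise ValueError("target contains labels outside the score channels")
    return grid.astype(np.int64)


def composite_loss(scores: np.ndarray, target, cw: ClassWeights,
                   lw: LossWeights) -> float:
    """w_CE·CE + w_Dice·(1 − soft Dice) + w_Focal·Focal on probability maps.

    ``scores`` are per-pixel class probabilities (C, H, W) or (B, C, H, W);
    each component is class-weighted by ``cw`` (Dice averages over foreground
    classes only).  Nonnegative; 0 for a perfect hard prediction.
    """
    loss, _ = _loss_and_grad_probs(scores, target, cw, lw, need_grad=False)
    return loss


def _loss_and_grad_probs(scores: np.ndarray, target, cw: ClassWeights,
                         lw: LossWeights, need_grad: bool = True
                         ) -> tuple[float, np.ndarray | None]:
    p = np.asarray(scores, dtype=np.float64)
    batched = p.ndim == 4
    if not batched:
        p = p[None]
    hw = p.shape[2:]
    if batched:
        if isinstance(target, (list, tuple)):
            tgt = np.stack([_as_target(t, p.shape[1], hw) for t in target])
        else:
            tgt = np.asarray(target, dtype=np.int64)
        if tgt.shape != (p.shape[0],) + hw:
            raise ValueError(f"target shape {tgt.shape} != scores {p.shape}")
    else:
        tgt = _as_target(target, p.shape[1], hw)[None]
    B, C, H, W = p.shape
    if len(cw.values) != C:
        raise ValueError("class-weight length does not match score channels")
    w = cw.values
    onehot = np.zeros_like(p)
    np.put_along_axis(onehot, tgt[:, None], 1.0, axis=1)
    pix_w = w[tgt]                                    # (B,H,W)
    W_sum = pix_w.sum()
    p_t = np.clip(np.take_along_axis(p, tgt[:, None], axis=1)[:, 0], _P_MIN, 1.0)
    log_pt = np.log(p_t)

    ce = float((pix_w * -log_pt).sum() / W_sum)
    focal = float((pix_w * (1 - p_t) ** _GAMMA * -log_pt).sum() / W_sum)

    fg = slice(1, C)
    n_c = (p[:, fg] * onehot[:, fg]).sum(axis=(0, 2, 3))
    s_c = p[:, fg].sum(axis=(0, 2, 3)) + onehot[:, fg].sum(axis=(0, 2, 3))
    d_c = (2 * n_c + _DICE_EPS) / (s_c + _DICE_EPS)
    w_fg = w[1:]
    dice_loss = float(1.0 - (w_fg * d_c).sum() / w_fg.sum())

    loss = lw.w_ce * ce + lw.w_dice * dice_loss + lw.w_focal * focal
    if not need_grad:
        return loss, None

    # gradient w.r.t. probabilities (chained to logits by the caller)
    dl_dp = np.zeros_like(p)
    # CE: d/dp_t of -w log p_t
    grad_pt = lw.w_ce * pix_w * (-1.0 / p_t) / W_sum
    # focal: d/dp_t of w (1-p_t)^γ (-log p_t)
    grad_pt += lw.w_focal * pix_w * (
        _GAMMA * (1 - p_t) ** (_GAMMA - 1) * log_pt - (1 - p_t) ** _GAMMA / p_t
    ) / W_sum
    idx = tgt[:, None]
    np.put_along_axis(dl_dp, idx, grad_pt[:, None], axis=1)
    # dice: dD_c/dp_c,i = (2 g (s+ε) − (2n+ε)) / (s+ε)²
    denom = (s_c + _DICE_EPS) ** 2
    coeff = -lw.w_dice * w_fg / w_fg.sum()            # d loss / d D_c
    dD = (2 * onehot[:, fg] * (s_c + _DICE_EPS)[None, :, None, None]
          - (2 * n_c + _DICE_EPS)[None, :, None, None]) / denom[None, :, None, None]
    dl_dp[:, fg] += coeff[None, :, None, None] * dD
    if not batched:
        dl_dp = dl_dp[0]
    return loss, dl_dp


def _loss_and_grad_logits(logits: np.ndarray, targets: np.ndarray,
                          cw: ClassWeights, lw: LossWeights
                          ) -> tuple[float, np.ndarray]:
    """Composite loss on logits with gradient chained through softmax."""
    p = softmax(logits.astype(np.float64), axis=1)
    loss, dl_dp = _loss_and_grad_probs(p, targets, cw, lw)
    inner = (dl_dp * p).sum(axis=1, keepdims=True)
    dlogits = p * (dl_dp - inner)
    return loss, dlogits.astype(np.float32)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------


def flip_pair(image: np.ndarray, grid: np.ndarray, axis: int
              ) -> tuple[np.ndarray, np.ndarray]:
    return np.flip(image, axis=axis).copy(), np.flip(grid, axis=axis).copy()


def rotate_pair(image: np.ndarray, grid: np.ndarray, angle: float
                ) -> tuple[np.ndarray, np.ndarray]:
    """Rotate an image/mask pair jointly; the mask is resampled nearest.

    Multiples of 90° are exact grid rotations; other angles use bilinear
    resampling for the image and nearest-neighbour (order 0) for the mask, so
    no interpolation-invented labels can appear.
    """
    if angle % 90 == 0:
        k = int(angle // 90) % 4
        return np.rot90(image, k).copy(), np.rot90(grid, k).copy()
    from skimage.transform import rotate as _rot

    img = _rot(image.astype(float), angle, mode="edge", order=1,
               preserve_range=True)
    msk = _rot(grid.astype(float), angle, mode="constant", cval=0, order=0,
               preserve_range=True)
    return img.astype(image.dtype), msk.astype(grid.dtype)


def augment(image: np.ndarray, mask: LabelMask, config: AugmentConfig,
            seed: int) -> tuple[np.ndarray, LabelMask]:
    """Random flips, rotations and intensity jitter for one training pair.

    The same geometric transform is applied to image and mask; intensity
    transforms touch the image only.  Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    img, grid = np.asarray(image), mask.grid
    if config.flip:
        if rng.random() < 0.5:
            img, grid = flip_pair(img, grid, axis=0)
        if rng.random() < 0.5:
            img, grid = flip_pair(img, grid, axis=1)
    if config.rotate and rng.random() < 0.5:
        angle = config.angles[rng.integers(len(config.angles))]
        img, grid = rotate_pair(img, grid, angle)
    if config.intensity:
        img = img.astype(float)
        img = (img - img.mean()) * rng.uniform(0.9, 1.1) + img.mean() \
            + rng.uniform(-20, 20)
        img = np.clip(img, 0, 255).astype(np.uint8)
    return img, LabelMask(grid, mask.palette, mask.pixel_size_um)


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------


class _Adam:
    """Adam with L2 weight decay."""

    def __init__(self, model: UNet, weight_decay: float = 0.0,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = model.parameters()
        self.wd, self.betas, self.eps = weight_decay, betas, eps
        self.m = [np.zeros_like(layer.params[k]) for layer, k in self.params]
        self.v = [np.zeros_like(layer.params[k]) for layer, k in self.params]
        self.t = 0

    def step(self, lr: float) -> None:
        b1, b2 = self.betas
        self.t += 1
        for i, (layer, k) in enumerate(self.params):
            g = layer.grads.get(k)
            if g is None:
                continue
            g = g + self.wd * layer.params[k]
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            layer.params[k] = (
                layer.params[k] - lr * mhat / (np.sqrt(vhat) + self.eps)
            ).astype(np.float32)


# ---------------------------------------------------------------------------
# training drivers
# ---------------------------------------------------------------------------


def _to_batch(images: list[np.ndarray]) -> np.ndarray:
    return np.stack([
        (np.asarray(im).astype(np.float32) / 255.0).transpose(2, 0, 1)
        for im in images
    ])


def _val_metrics(model: UNet, patches, ids, cw, lw, batch_size: int
                 ) -> tuple[float, dict[int, float]]:
    """Validation loss and per-class Dice of argmax predictions."""
    C = model.config.n_classes
    losses, inter, sums = [], np.zeros(C), np.zeros(C)
    for start in range(0, len(ids), batch_size):
        chunk = ids[start:start + batch_size]
        x = _to_batch([patches[i][0] for i in chunk])
        t = np.stack([patches[i][1].grid for i in chunk]).astype(np.int64)
        logits = model.forward(x)
        loss, _ = _loss_and_grad_probs(softmax(logits), t, cw, lw,
                                       need_grad=False)
        losses.append(loss * len(chunk))
        pred = logits.argmax(axis=1)
        for c in range(C):
            P, G = pred == c, t == c
            inter[c] += np.logical_and(P, G).sum()
            sums[c] += P.sum() + G.sum()
    with np.errstate(invalid="ignore"):
        dice = np.where(sums > 0, 2 * inter / sums, 1.0)
    return float(np.sum(losses) / len(ids)), {c: float(dice[c]) for c in range(C)}


def train_model(patches, split: DatasetSplit, config: TrainConfig,
                policy: BoostPolicy | None = None,
                loss_weights: LossWeights = VESSEL_LOSS_WEIGHTS,
                fold: int = 0) -> tuple[UNet, pd.DataFrame]:
    """Train one network on a fold's train/validation split.

    ``patches`` is an indexable of (RGB image, LabelMask) pairs; ids come
    from the split.  Records per-epoch train/val loss, per-class validation
    Dice, learning rate and class weights; keeps the best-validation-loss
    checkpoint and stops after ``config.patience`` stagnant epochs.  Passing
    a :class:`BoostPolicy` enables adaptive weight boosting; ``None`` trains
    with fixed uniform class weights (the standard loss).
    """
    train_ids, val_ids = split.train_val(fold)
    if not train_ids or not val_ids:
        raise ValueError("training and validation sets must be nonempty")
    rng = np.random.default_rng(config.seed)
    model = build_model(config.model, seed=int(rng.integers(2 ** 31)))
    cw = ClassWeights.uniform(config.model.n_classes)
    opt = _Adam(model, weight_decay=config.weight_decay)
    history: list[dict] = []
    best_loss, best_state, stagnant = np.inf, model.state_dict(), 0

    for epoch in range(1, config.epochs + 1):
        lr = cosine_lr(min(epoch - 1, config.lr.T), config.lr)
        order = rng.permutation(train_ids)
        epoch_losses = []
        for start in range(0, len(order), config.batch_size):
            chunk = order[start:start + config.batch_size]
            imgs, grids = [], []
            for i in chunk:
                img, msk = patches[i]
                if config.augment is not None:
                    img, msk = augment(img, msk, config.augment,
                                       int(rng.integers(2 ** 31)))
                imgs.append(img)
                grids.append(msk.grid)
            x = _to_batch(imgs)
            t = np.stack(grids).astype(np.int64)
            logits = model.forward(x)
            loss, dlogits = _loss_and_grad_logits(logits, t, cw, loss_weights)
            model.backward(dlogits)
            opt.step(lr)
            epoch_losses.append(loss)

        val_loss, val_dice = _val_metrics(model, patches, val_ids, cw,
                                          loss_weights, config.batch_size)
        history.append({
            "epoch": epoch,
            "train_loss": float(np.mean(epoch_losses)),
            "val_loss": val_loss,
            "lr": lr,
            **{f"val_dice_{c}": val_dice[c] for c in sorted(val_dice)},
            **{f"class_weight_{c}": cw.values[c] for c in range(len(cw.values))},
        })
        if policy is not None and epoch % policy.period_epochs == 0:
            cw = boost_weights(cw, val_dice, policy, epoch)
        if val_loss < best_loss - 1e-7:
            best_loss, best_state, stagnant = val_loss, model.state_dict(), 0
            best_state = {k: v.copy() for k, v in best_state.items()}
        else:
            stagnant += 1
            if stagnant >= config.patience:
                break

    model.load_state_dict(best_state)
    return model, pd.DataFrame(history)


def cross_validate(patches, split: DatasetSplit, config: TrainConfig,
                   policy: BoostPolicy | None = None,
                   loss_weights: LossWeights = VESSEL_LOSS_WEIGHTS
                   ) -> tuple[list[dict], dict]:
    """Train each fold independently and aggregate as mean ± SD over folds.

    Each fold's report holds the per-class validation Dice of the fold's best
    model; the aggregate maps class index to (mean, sample SD) over folds.
    """
    if split.k < 2:
        raise ValueError("need at least 2 folds")
    fold_reports = []
    for fold in range(split.k):
        cfg = replace(config, seed=config.seed + fold)
        model, _ = train_model(patches, split, cfg, policy, loss_weights, fold)
        _, val_ids = split.train_val(fold)
        cw = ClassWeights.uniform(config.model.n_classes)
        _, val_dice = _val_metrics(model, patches, val_ids, cw, loss_weights,
                                   config.batch_size)
        fold_reports.append({"fold": fold, "val_dice": val_dice})
    C = config.model.n_classes
    aggregate = {}
    for c in range(C):
        vals = np.array([r["val_dice"][c] for r in fold_reports])
        aggregate[c] = (float(vals.mean()),
                        float(vals.std(ddof=1)) if len(vals) > 1 else 0.0)
    return fold_reports, aggregate
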