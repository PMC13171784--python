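"""Segmentation quality metrics: Dice, IoU, TPR, ASSD and confusion matrices.

All overlap metrics operate on binary one-vs-rest masks; class-wise variants
apply them to each palette label of a :class:`~hepaseg.wsi_patching.LabelMask`.
The average symmetric surface distance (ASSD) is the mean bidirectional
nearest-boundary distance, converted to micrometres through the mask's pixel
size, so boundary errors can be compared with typical structure dimensions
(the relative-error ratio).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .wsi_patching import LabelMask

__all__ = [
    "dice", "iou", "tpr", "assd", "boundary_points", "confusion_matrix",
    "relative_error", "MetricsReport", "evaluate_masks",
]


def _check_shapes(P: np.ndarray, G: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    P = np.asarray(P, dtype=bool)
    G = np.asarray(G, dtype=bool)
    if P.shape != G.shape:
        raise ValueError(f"shape mismatch {P.shape} vs {G.shape}")
    return P, G


def dice(P: np.ndarray, G: np.ndarray) -> float:
    """Dice similarity 2|P∩G| / (|P|+|G|); 1.0 when both masks are empty."""
    P, G = _check_shapes(P, G)
    denom = P.sum() + G.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(P, G).sum() / denom)


def iou(P: np.ndarray, G: np.ndarray) -> float:
    """Jaccard index |P∩G| / |P∪G|; 1.0 when both masks are empty."""
    P, G = _check_shapes(P, G)
    union = np.logical_or(P, G).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(P, G).sum() / union)


def tpr(P: np.ndarray, G: np.ndarray) -> float:
    """Recall TP/(TP+FN); NaN sentinel when the ground truth is empty."""
    P, G = _check_shapes(P, G)
    positives = G.sum()
    if positives == 0:
        return float("nan")
    return float(np.logical_and(P, G).sum() / positives)


def boundary_points(mask: np.ndarray) -> np.ndarray:
    """(N, 2) row/col coordinates of boundary pixels of a binary mask.

    A foreground pixel is boundary if any 4-neighbour is background (pixels on
    the image edge count their out-of-bounds neighbours as background).
    """
    m = np.asarray(mask, dtype=bool)
    padded = np.pad(m, 1, constant_values=False)
    interior = (
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    return np.argwhere(m & ~interior)


def assd(P: np.ndarray, G: np.ndarray, pixel_size_um: float = 1.0) -> float:
    """Average symmetric surface distance between two binary masks, in µm.

    Mean of (a) average nearest-boundary distance from every boundary point of
    P to the boundary of G and (b) the reverse direction.  Distances are
    Euclidean between pixel centers.  NaN sentinel (with a warning) if either
    mask has no boundary.
    """
    sp = boundary_points(P)
    sg = boundary_points(G)
    if len(sp) == 0 or len(sg) == 0:
        warnings.warn("ASSD undefined for an empty surface", stacklevel=2)
        return float("nan")
    d_pg = cKDTree(sg).query(sp)[0]
    d_gp = cKDTree(sp).query(sg)[0]
    return float(0.5 * (d_pg.mean() + d_gp.mean()) * pixel_size_um)


def confusion_matrix(pred: LabelMask, gt: LabelMask) -> np.ndarray:
    """Row-normalized confusion matrix in percent.

    Entry (i, j) is the percentage of true-class-i pixels predicted as class
    j; each row with any true pixels sums to 100, rows of absent classes are
    NaN.
    """
    if pred.palette.labels != gt.palette.labels:
        raise ValueError("prediction and ground-truth palettes differ")
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {gt.shape}")
    C = pred.palette.n_classes
    counts = np.zeros((C, C), dtype=np.int64)
    idx = gt.grid.astype(np.int64) * C + pred.grid.astype(np.int64)
    np.add.at(counts.reshape(-1), idx.reshape(-1), 1)
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * counts / row_sums
    pct[row_sums[:, 0] == 0] = np.nan
    return pct


def relative_error(assd_um: float, reference_diameter_um: float) -> float:
    """Boundary error as a percentage of a typical structure dimension."""
    if reference_diameter_um <= 0:
        raise ValueError("reference diameter must be positive")
    if assd_um < 0:
        raise ValueError("ASSD must be nonnegative")
    return 100.0 * assd_um / reference_diameter_um


@dataclass
class MetricsReport:
    """Per-class DSC/IoU/TPR/ASSD plus a row-normalized confusion matrix."""

    class_names: tuple[str, ...]
    dsc: dict[str, float]
    iou: dict[str, float]
    tpr: dict[str, float]
    assd_um: dict[str, float]
    confusion_pct: np.ndarray

    def foreground_mean(self, metric: str = "dsc") -> float:
        """Mean of a metric over foreground classes, NaN sentinels excluded."""
        vals = [getattr(self, metric)[n] for n in self.class_names[1:]]
        vals = [v for v in vals if not np.isnan(v)]
        return float(np.mean(vals)) if vals else float("nan")


def evaluate_masks(pred: LabelMask, gt: LabelMask) -> MetricsReport:
    """Full per-class evaluation of a predicted mask against ground truth."""
    names = gt.palette.names
    d, j, t, a = {}, {}, {}, {}
    for lab, name in zip(gt.palette.labels, names):
        P, G = pred.binary(lab), gt.binary(lab)
        d[name] = dice(P, G)
        j[name] = iou(P, G)
        t[name] = tpr(P, G)
        if P.any() and G.any():
            a[name] = assd(P, G, gt.pixel_size_um)
        else:
            a[name] = float("nan")
    return MetricsReport(names, d, j, t, a, confusion_matrix(pred, gt))
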