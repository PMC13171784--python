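"""Tiled whole-slide inference: overlapping prediction, blending, stitching.

Large images are segmented tile by tile at the network's input size; tiles
overlap (default 50%) and their per-class score maps are averaged wherever
tiles overlap, which suppresses boundary artifacts.  The blended score
mosaic is then collapsed to labels by per-pixel argmax (ties toward the
lowest label) and can be composited over the histology as a colored overlay.
When the vessel and lobule views are merged, vessel labels take precedence —
central veins sit inside lobules.
"""

from __future__ import annotations

import numpy as np

from .unet_models import UNet, image_to_input
from .wsi_patching import ClassPalette, LabelMask

__all__ = ["tile_origins", "tiled_predict", "stitch_labels", "overlay",
           "merge_vessel_lobule", "COMBINED_PALETTE"]

#: Palette of the combined whole-slide view (vessels over lobules).
COMBINED_PALETTE = ClassPalette(
    (
        (0, "background", (0, 0, 0)),
        (1, "portal_vein", (0, 0, 255)),
        (2, "central_vein", (0, 255, 0)),
        (3, "artery", (255, 0, 0)),
        (4, "bile_duct", (128, 0, 128)),
        (5, "lobule", (255, 255, 0)),
    )
)


def _axis_origins(extent: int, patch: int, stride: int) -> list[int]:
    """Tile start positions covering [0, extent) with the last tile shifted
    inward so coverage is complete."""
    if extent <= patch:
        return [0]
    origins = list(range(0, extent - patch + 1, stride))
    if origins[-1] != extent - patch:
        origins.append(extent - patch)
    return origins


def tile_origins(shape: tuple[int, int], patch_size: int,
                 overlap_frac: float) -> list[tuple[int, int]]:
    """(row, col) origins of overlapping tiles fully covering the image."""
    if not 0 <= overlap_frac <= 0.5:
        raise ValueError("overlap_frac must be in [0, 0.5]")
    stride = max(1, int(round(patch_size * (1 - overlap_frac))))
    H, W = shape
    return [(r, c) for r in _axis_origins(H, patch_size, stride)
            for c in _axis_origins(W, patch_size, stride)]


def _predict_tile(model, tile: np.ndarray) -> np.ndarray:
    """(H, W, 3) tile → (C, H, W) scores; accepts a UNet or any callable."""
    if isinstance(model, UNet):
        return model.forward(image_to_input(tile))[0]
    return np.asarray(model(tile))


def tiled_predict(model, image: np.ndarray, patch_size: int,
                  overlap_frac: float = 0.5) -> np.ndarray:
    """Per-class score mosaic for a large image via overlapping tiles.

    Tiles are placed at stride ``patch_size·(1−overlap_frac)`` with edge
    tiles shifted inward; per-pixel scores are averaged over all covering
    tiles (order-independent).  Images smaller than one patch are predicted
    on a single centered zero-padded tile and cropped back.
    """
    image = np.asarray(image)
    H, W = image.shape[:2]
    if H < patch_size or W < patch_size:
        pad_r, pad_c = max(0, patch_size - H), max(0, patch_size - W)
        top, left = pad_r // 2, pad_c // 2
        padded = np.zeros((max(H, patch_size), max(W, patch_size), 3),
                          dtype=image.dtype)
        padded[top:top + H, left:left + W] = image
        scores = tiled_predict(model, padded, patch_size, overlap_frac)
        return scores[:, top:top + H, left:left + W]
    origins = tile_origins((H, W), patch_size, overlap_frac)
    acc = cnt = None
    for r, c in origins:
        s = _predict_tile(model, image[r:r + patch_size, c:c + patch_size])
        if acc is None:
            acc = np.zeros((s.shape[0], H, W), dtype=np.float64)
            cnt = np.zeros((H, W), dtype=np.int32)
        acc[:, r:r + patch_size, c:c + patch_size] += s
        cnt[r:r + patch_size, c:c + patch_size] += 1
    return acc / cnt


def stitch_labels(scores: np.ndarray, palette: ClassPalette,
                  pixel_size_um: float) -> LabelMask:
    """Collapse a (C, H, W) score mosaic to labels by per-pixel argmax.

    Ties break toward the lowest label.  NaN scores (uncovered pixels) raise
    a coverage-gap error.
    """
    scores = np.asarray(scores)
    if np.isnan(scores).any():
        raise ValueError("score mosaic has coverage gaps (NaN scores)")
    if scores.shape[0] != palette.n_classes:
        raise ValueError("score channels do not match the palette")
    return LabelMask(scores.argmax(axis=0).astype(np.uint8), palette,
                     pixel_size_um)


def merge_vessel_lobule(vessel: LabelMask, lobule: LabelMask) -> LabelMask:
    """Combined whole-slide view; vessel labels win where both are nonzero."""
    if vessel.shape != lobule.shape:
        raise ValueError("vessel and lobule masks differ in shape")
    grid = np.where(lobule.grid > 0, COMBINED_PALETTE.label_of("lobule"), 0)
    grid = np.where(vessel.grid > 0, vessel.grid, grid)
    return LabelMask(grid.astype(np.uint8), COMBINED_PALETTE,
                     vessel.pixel_size_um)


def overlay(image: np.ndarray, mask: LabelMask, alpha: float = 0.5
            ) -> np.ndarray:
    """Tint foreground classes over the histology with opacity ``alpha``.

    Background pixels are unchanged; a foreground pixel becomes
    ``(1−α)·image + α·palette_color``, rounded to uint8.
    """
    image = np.asarray(image)
    if image.shape[:2] != mask.shape:
        raise ValueError("image and mask dimensions differ")
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must be in [0, 1]")
    colors = mask.palette.colors[mask.grid].astype(float)
    fg = (mask.grid > 0)[..., None]
    blended = np.where(fg, (1 - alpha) * image.astype(float) + alpha * colors,
                       image.astype(float))
    return np.floor(blended + 0.5).astype(np.uint8)
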