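"""Patch extraction, mask encoding and dataset splitting for whole-slide images.

Large GS-PSR liver slides are processed as non-overlapping square patches
(1024 px for the vessel task, 2048 px for the lobule task, both divisible by
2^5 to match the segmentation network's five resolution levels).  Annotation
masks travel as integer label grids (:class:`LabelMask`) with a
:class:`ClassPalette` mapping labels to names and display colors; RGB-painted
masks are converted with :func:`encode_mask` / :func:`decode_mask`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

# ---------------------------------------------------------------------------
# Palettes and label masks
# ---------------------------------------------------------------------------

#: Reference scan resolution, micrometres per pixel (227 nm/pixel).
DEFAULT_PIXEL_SIZE_UM = 0.227

#: Network input sizes must be divisible by 2**DEPTH_LEVELS.
DEPTH_LEVELS = 5
SIZE_DIVISOR = 2 ** DEPTH_LEVELS


@dataclass(frozen=True)
class ClassPalette:
    """Mapping between integer labels, class names and RGB display colors.

    Labels must be consecutive integers starting at 0, and label 0 is always
    background.  Colors must be pairwise distinct so that RGB-painted masks
    decode unambiguously.
    """

    entries: tuple[tuple[int, str, tuple[int, int, int]], ...]

    def __post_init__(self) -> None:
        labels = [e[0] for e in self.entries]
        if labels != list(range(len(labels))):
            raise ValueError(f"labels must be consecutive from 0, got {labels}")
        colors = [tuple(e[2]) for e in self.entries]
        if len(set(colors)) != len(colors):
            raise ValueError("palette colors must be pairwise distinct")
        if self.entries[0][1].lower() != "background":
            raise ValueError("label 0 must be named 'background'")

    @property
    def labels(self) -> tuple[int, ...]:
        return tuple(e[0] for e in self.entries)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(e[1] for e in self.entries)

    @property
    def colors(self) -> np.ndarray:
        """(C, 3) uint8 array of RGB colors indexed by label."""
        return np.array([e[2] for e in self.entries], dtype=np.uint8)

    @property
    def n_classes(self) -> int:
        return len(self.entries)

    def label_of(self, name: str) -> int:
        for lab, nm, _ in self.entries:
            if nm == name:
                return lab
        raise KeyError(name)

    def to_json(self) -> str:
        return json.dumps(
            [{"label": l, "name": n, "color": list(c)} for l, n, c in self.entries]
        )

    @classmethod
    def from_json(cls, text: str) -> "ClassPalette":
        data = json.loads(text)
        return cls(tuple((d["label"], d["name"], tuple(d["color"])) for d in data))


#: Five-class palette for the vessel segmentation task.
VESSEL_PALETTE = ClassPalette(
    (
        (0, "background", (0, 0, 0)),
        (1, "portal_vein", (0, 0, 255)),
        (2, "central_vein", (0, 255, 0)),
        (3, "artery", (255, 0, 0)),
        (4, "bile_duct", (128, 0, 128)),
    )
)

#: Binary palette for the lobule detection task (lobule painted yellow).
LOBULE_PALETTE = ClassPalette(
    (
        (0, "background", (0, 0, 0)),
        (1, "lobule", (255, 255, 0)),
    )
)


@dataclass
class LabelMask:
    """Integer label grid with its palette and physical pixel size (µm/px)."""

    grid: np.ndarray
    palette: ClassPalette
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2 or self.grid.size == 0:
            raise ValueError("grid must be a non-empty 2-D array")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        bad = np.setdiff1d(np.unique(self.grid), np.array(self.palette.labels))
        if bad.size:
            raise ValueError(f"grid contains non-palette labels {bad.tolist()}")
        self.grid = self.grid.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape  # type: ignore[return-value]

    def binary(self, label: int) -> np.ndarray:
        """One-vs-rest boolean mask for a single class label."""
        return self.grid == label


def encode_mask(rgb_annotation: np.ndarray, palette: ClassPalette,
                pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM) -> LabelMask:
    """Convert an RGB-painted annotation into an integer :class:`LabelMask`.

    Matching is exact (tolerance 0): every pixel color must equal one palette
    color.  Unmatched colors raise with the offending colors and their counts.
    """
    rgb = np.asarray(rgb_annotation)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("annotation must be an H×W×3 RGB array")
    colors = palette.colors.astype(np.int32)
    flat = rgb.reshape(-1, 3).astype(np.int32)
    # exact match against each palette color
    grid = np.full(flat.shape[0], -1, dtype=np.int32)
    for lab, color in enumerate(colors):
        grid[np.all(flat == color, axis=1)] = lab
    if (grid < 0).any():
        bad, counts = np.unique(flat[grid < 0], axis=0, return_counts=True)
        desc = ", ".join(
            f"{tuple(int(v) for v in c)}×{int(n)}" for c, n in zip(bad[:5], counts[:5])
        )
        raise ValueError(f"{int((grid < 0).sum())} pixels with non-palette colors: {desc}")
    return LabelMask(grid.reshape(rgb.shape[:2]), palette, pixel_size_um)


def decode_mask(mask: LabelMask) -> np.ndarray:
    """Render a label mask back to its RGB palette colors (H×W×3 uint8)."""
    return mask.palette.colors[mask.grid]


# ---------------------------------------------------------------------------
# Patch extraction
# ---------------------------------------------------------------------------


@dataclass
class PatchGrid:
    """Non-overlapping patch tiling anchored at the image top-left corner.

    ``origins`` are 0-based (row, col) corners in level-0 coordinates; each
    patch occupies the half-open window ``[r, r+ps) × [c, c+ps)``.
    """

    patch_size_px: int
    origins: list[tuple[int, int]]
    source_dims: tuple[int, int]

    def __post_init__(self) -> None:
        if self.patch_size_px % SIZE_DIVISOR != 0:
            raise ValueError(
                f"patch_size {self.patch_size_px} not divisible by {SIZE_DIVISOR}"
            )

    def __len__(self) -> int:
        return len(self.origins)


def extract_patches(image: np.ndarray, patch_size_px: int
                    ) -> tuple[PatchGrid, list[np.ndarray]]:
    """Cut an image into non-overlapping ``patch_size_px`` square tiles.

    The grid is anchored at the top-left corner; edge remainders smaller than
    one patch are dropped.  Stitching the returned patches back by origin
    reproduces the cropped source bit-exactly.
    """
    image = np.asarray(image)
    if patch_size_px % SIZE_DIVISOR != 0:
        raise ValueError(f"patch_size must be divisible by {SIZE_DIVISOR}")
    H, W = image.shape[:2]
    if H < patch_size_px or W < patch_size_px:
        raise ValueError(
            f"image {H}×{W} smaller than one {patch_size_px}px patch"
        )
    ps = patch_size_px
    origins = [(r * ps, c * ps) for r in range(H // ps) for c in range(W // ps)]
    patches = [image[r:r + ps, c:c + ps].copy() for r, c in origins]
    return PatchGrid(ps, origins, (H, W)), patches


def stitch_patches(grid: PatchGrid, patches: Sequence[np.ndarray]) -> np.ndarray:
    """Reassemble extracted patches into the cropped source mosaic."""
    ps = grid.patch_size_px
    rows = max(r for r, _ in grid.origins) + ps
    cols = max(c for _, c in grid.origins) + ps
    first = np.asarray(patches[0])
    out = np.zeros((rows, cols) + first.shape[2:], dtype=first.dtype)
    for (r, c), patch in zip(grid.origins, patches):
        out[r:r + ps, c:c + ps] = patch
    return out


# ---------------------------------------------------------------------------
# Dataset splitting
# ---------------------------------------------------------------------------


@dataclass
class DatasetSplit:
    """Held-out test identifiers plus k cross-validation folds."""

    test_ids: list[int]
    fold_ids: list[list[int]]
    seed: int

    @property
    def k(self) -> int:
        return len(self.fold_ids)

    def train_val(self, fold: int) -> tuple[list[int], list[int]]:
        """Training ids (all other folds) and validation ids for one fold."""
        val = self.fold_ids[fold]
        train = [i for j, f in enumerate(self.fold_ids) if j != fold for i in f]
        return train, val

    def to_json(self) -> str:
        return json.dumps(
            {"seed": self.seed, "test_ids": self.test_ids, "fold_ids": self.fold_ids}
        )

    @classmethod
    def from_json(cls, text: str) -> "DatasetSplit":
        d = json.loads(text)
        return cls(d["test_ids"], d["fold_ids"], d["seed"])


def split_dataset(n: int, test_frac: float = 0.10, k: int = 5,
                  seed: int = 0) -> DatasetSplit:
    """Random test / k-fold partition of ``n`` patch identifiers.

    Test size is ``ceil(n·test_frac)`` (7,272 patches at 10% gives 728); the
    remainder is split into k folds differing in size by at most one, larger
    folds first.  Identical seeds give identical splits.
    """
    if not 0 < test_frac < 1:
        raise ValueError("test_frac must be in (0, 1)")
    if k < 2:
        raise ValueError("need at least 2 folds")
    n_test = math.ceil(n * test_frac)
    if n <= k or n - n_test < k:
        raise ValueError(f"n={n} too small for test_frac={test_frac}, k={k}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    test_ids = sorted(int(i) for i in perm[:n_test])
    rest = perm[n_test:]
    m = len(rest)
    base, extra = divmod(m, k)
    folds: list[list[int]] = []
    pos = 0
    for f in range(k):
        size = base + (1 if f < extra else 0)  # larger folds first
        folds.append(sorted(int(i) for i in rest[pos:pos + size]))
        pos += size
    return DatasetSplit(test_ids, folds, seed)


# ---------------------------------------------------------------------------
# Disk I/O: images, masks, manifests
# ---------------------------------------------------------------------------


def read_image(path: str | Path) -> np.ndarray:
    """Read a flat RGB TIFF/PNG image as an H×W×3 uint8 array."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[..., :3]
    return arr


def save_patch(path: str | Path, patch: np.ndarray) -> None:
    """Write a patch as lossless (zlib) TIFF."""
    tifffile.imwrite(Path(path), np.asarray(patch), compression="zlib")


def save_mask(path: str | Path, mask: LabelMask) -> None:
    """Write a mask as single-channel integer TIFF plus a JSON palette sidecar."""
    path = Path(path)
    tifffile.imwrite(path, mask.grid, compression="zlib")
    sidecar = {"palette": json.loads(mask.palette.to_json()),
               "pixel_size_um": mask.pixel_size_um}
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def load_mask(path: str | Path) -> LabelMask:
    """Read a mask written by :func:`save_mask` (TIFF + JSON sidecar)."""
    path = Path(path)
    grid = tifffile.imread(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    palette = ClassPalette.from_json(json.dumps(sidecar["palette"]))
    return LabelMask(grid, palette, sidecar["pixel_size_um"])


def patch_name(slide: str, origin: tuple[int, int]) -> str:
    return f"{slide}_{origin[0]}_{origin[1]}.tiff"


def save_patch_set(out_dir: str | Path, slide: str, grid: PatchGrid,
                   patches: Sequence[np.ndarray],
                   masks: Sequence[LabelMask] | None = None) -> list[Path]:
    """Write per-patch TIFFs named ``{slide}_{row}_{col}.tiff`` (+ mask pairs)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for i, (origin, patch) in enumerate(zip(grid.origins, patches)):
        p = out_dir / patch_name(slide, origin)
        save_patch(p, patch)
        written.append(p)
        if masks is not None:
            save_mask(out_dir / ("mask_" + patch_name(slide, origin)), masks[i])
    return written
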