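"""Shared fixtures: synthetic tissue fields and vessel training windows."""

from __future__ import annotations

import numpy as np
import pytest

import hepaseg as hs

FIELD_PX = 1024
PIXEL_SIZE_UM = 2.0  # coarse scan so one field holds several lobules


@pytest.fixture(scope="session")
def tissue_field():
    """One deterministic 1024² synthetic GS-PSR field with ground truth."""
    params = hs.TissueParams(height_px=FIELD_PX, width_px=FIELD_PX,
                             pixel_size_um=PIXEL_SIZE_UM, seed=5)
    image, vessel_mask, lobule_mask, records = hs.generate_tissue(params)
    return {"params": params, "image": image, "vessel_mask": vessel_mask,
            "lobule_mask": lobule_mask, "records": records}


def vessel_windows(seed: int, window: int = 64, per_class: int = 2):
    """Crop windows centered on planted vessels, one list of (image, mask)."""
    params = hs.TissueParams(height_px=FIELD_PX, width_px=FIELD_PX,
                             pixel_size_um=PIXEL_SIZE_UM, seed=seed)
    image, vessel_mask, _, records = hs.generate_tissue(params)
    by_cls: dict[str, list] = {}
    for r in records:
        if r.class_name != "lobule":
            by_cls.setdefault(r.class_name, []).append(r)
    chosen = [by_cls[c][i] for i in range(per_class)
              for c in ("portal_vein", "central_vein", "artery", "bile_duct")]
    pairs = []
    for r in chosen:
        cy, cx = int(r.centroid[0]), int(r.centroid[1])
        y0 = min(max(cy - window // 2, 0), FIELD_PX - window)
        x0 = min(max(cx - window // 2, 0), FIELD_PX - window)
        pairs.append((
            image[y0:y0 + window, x0:x0 + window],
            hs.LabelMask(vessel_mask.grid[y0:y0 + window, x0:x0 + window],
                         vessel_mask.palette, PIXEL_SIZE_UM),
        ))
    return pairs


@pytest.fixture(scope="session")
def vessel_patch_pairs():
    """Eight 64² vessel windows covering all four vessel classes."""
    return vessel_windows(seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
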