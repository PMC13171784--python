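"""Synthetic GS-PSR porcine liver histology with exact ground truth.

Generates RGB patches/mosaics that emulate glutamine-synthetase (GS) stained,
Picro-Sirius-Red (PSR) counterstained porcine liver: polygonal lobules
(400–1,000 µm) bounded by red collagen septa, portal triads (portal vein
>80 µm thin-walled, artery 10–90 µm thick-walled, bile duct 10–30 µm) at
lobule corners, and thin-walled central veins (30–60 µm) with a brown GS
halo at lobule centers.  Every placed structure's true class, center and
diameter are returned as :class:`~hepaseg.morphometry.StructureRecord`\\ s,
with lobule Feret diameters computed analytically from the cell polygons, so
downstream morphometry can be validated against planted truth.

Lobule tessellation is a seeded jittered hexagonal point process whose
Voronoi diagram (closed by mirror points, so cells are clipped exactly at
the image border) is offset inward by half the septum width; the removed
band is the collagen septum.  Artifacts — tears, folds and uneven staining —
can be injected into the image only, leaving the truth masks untouched.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import Voronoi
from shapely.geometry import Polygon, box as shapely_box
from skimage import draw

from .morphometry import StructureRecord
from .wsi_patching import (
    DEFAULT_PIXEL_SIZE_UM, LOBULE_PALETTE, VESSEL_PALETTE, LabelMask,
)

__all__ = ["TissueParams", "ArtifactSpec", "generate_tissue", "inject_artifacts"]

# stain color means (RGB): pale pink parenchyma, PSR-red septa, dark red
# vessel walls, brown GS halo, near-white lumina and glass
_PARENCHYMA = np.array([232.0, 190.0, 200.0])
_SEPTUM = np.array([190.0, 60.0, 70.0])
_WALL = np.array([150.0, 30.0, 40.0])
_HALO = np.array([150.0, 100.0, 60.0])
_LUMEN = np.array([246.0, 241.0, 243.0])
_GLASS = np.array([246.0, 246.0, 244.0])

# fraction of the outer diameter taken up by the vessel wall: portal veins
# thin-walled, arteries thick muscular, bile ducts epithelium-lined
_WALL_FRACTION = {"portal_vein": 0.08, "artery": 0.35,
                  "bile_duct": 0.25, "central_vein": 0.10}


@dataclass(frozen=True)
class TissueParams:
    """Geometry, staining and placement parameters of the synthetic tissue.

    Diameter ranges are in micrometres and follow the anatomical criteria of
    GS-PSR porcine liver; counts of ``None`` mean "one per available site"
    (one central vein per lobule, one portal vein / artery / bile duct per
    portal-triad site).
    """

    height_px: int = 1024
    width_px: int = 1024
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    lobule_diameter_um: tuple[float, float] = (400.0, 1000.0)
    septum_width_um: float = 30.0
    portal_vein_diameter_um: tuple[float, float] = (80.0, 160.0)
    artery_diameter_um: tuple[float, float] = (10.0, 90.0)
    bile_duct_diameter_um: tuple[float, float] = (10.0, 30.0)
    central_vein_diameter_um: tuple[float, float] = (30.0, 60.0)
    n_portal: int | None = None
    n_artery: int | None = None
    n_bile_duct: int | None = None
    n_central: int | None = None
    color_jitter_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        ranges = [self.lobule_diameter_um, self.portal_vein_diameter_um,
                  self.artery_diameter_um, self.bile_duct_diameter_um,
                  self.central_vein_diameter_um]
        for lo, hi in ranges:
            if not 0 < lo <= hi:
                raise ValueError("diameter ranges must be positive with lo <= hi")
        if self.septum_width_um <= 0 or self.pixel_size_um <= 0:
            raise ValueError("septum width and pixel size must be positive")
        min_extent_um = min(self.height_px, self.width_px) * self.pixel_size_um
        if min_extent_um < 2 * self.lobule_diameter_um[0]:
            raise ValueError(
                f"field of {min_extent_um:.0f} µm is smaller than two lobule "
                f"diameters ({2 * self.lobule_diameter_um[0]:.0f} µm)"
            )


@dataclass(frozen=True)
class ArtifactSpec:
    """Which preparation artifacts to inject and how severely (0–1)."""

    kinds: tuple[str, ...] = ("tear", "fold", "uneven_staining")
    severity: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.severity <= 1.0:
            raise ValueError("severity must be in [0, 1]")


# ---------------------------------------------------------------------------
# lobule tessellation
# ---------------------------------------------------------------------------


def _lobule_centers(p: TissueParams, rng: np.random.Generator) -> np.ndarray:
    """Jittered hexagonal seed points (x=col, y=row) in pixels."""
    lo, hi = p.lobule_diameter_um
    # caliper diameter of a Voronoi hexagon is ~1.15x the point spacing;
    # keep spacing away from the range ends so jitter and the septum erosion
    # leave every cell inside the requested diameter range
    spacing_um = rng.uniform(lo + 0.25 * (hi - lo), lo + 0.55 * (hi - lo)) / 1.15
    s = spacing_um / p.pixel_size_um
    dy = s * np.sqrt(3) / 2
    pts = []
    row = 0
    y = -s
    while y < p.height_px + s:
        x0 = -s + (s / 2 if row % 2 else 0.0)
        x = x0
        while x < p.width_px + s:
            pts.append((x, y))
            x += s
        y += dy
        row += 1
    pts = np.asarray(pts, dtype=float)
    pts += rng.uniform(-0.08 * s, 0.08 * s, size=pts.shape)
    # keep in-box centers only; mirror points close the border cells
    inside = ((pts[:, 0] >= 0) & (pts[:, 0] < p.width_px)
              & (pts[:, 1] >= 0) & (pts[:, 1] < p.height_px))
    return pts[inside]


def _voronoi_cells(centers: np.ndarray, H: int, W: int) -> list[Polygon]:
    """Finite Voronoi cells clipped exactly at the image border.

    Mirror points across all four image edges make the border itself a cell
    boundary.  Each in-box cell is built directly as the intersection of the
    frame with the bisector half-planes of its neighbours (exact for the few
    dozen lobules per field).
    """
    mirrored = [centers]
    for axis, bound in ((0, W), (1, H)):
        for edge in (0.0, float(bound)):
            m = centers.copy()
            m[:, axis] = 2 * edge - m[:, axis]
            mirrored.append(m)
    cloud = np.vstack(mirrored)
    frame = shapely_box(0, 0, W, H)
    diag = float(np.hypot(W, H))
    cells = []
    for i, c in enumerate(centers):
        if not (0 <= c[0] <= W and 0 <= c[1] <= H):
            continue
        d2 = ((cloud - c) ** 2).sum(axis=1)
        d2[i] = np.inf
        poly = frame
        for j in np.argsort(d2)[:16]:
            if not np.isfinite(d2[j]) or d2[j] < 1e-12:
                continue
            mid = 0.5 * (c + cloud[j])
            n = cloud[j] - c                    # outward normal of the bisector
            n = n / np.linalg.norm(n)
            t = np.array([-n[1], n[0]])
            half = Polygon([mid + diag * t, mid - diag * t,
                            mid - diag * t - diag * n,
                            mid + diag * t - diag * n])
            poly = poly.intersection(half)
            if poly.is_empty:
                break
        if not poly.is_empty and poly.area >= 4:
            cells.append(poly)
    return cells


def _polygon_feret(poly: Polygon) -> tuple[float, float]:
    """Analytic (major, minor) caliper diameters of a convex polygon, px."""
    pts = np.asarray(poly.convex_hull.exterior.coords[:-1], dtype=float)
    diff = pts[:, None, :] - pts[None, :, :]
    major = float(np.sqrt((diff ** 2).sum(-1)).max())
    edges = np.roll(pts, -1, axis=0) - pts
    lengths = np.sqrt((edges ** 2).sum(-1))
    keep = lengths > 1e-12
    normals = np.stack([-edges[keep, 1], edges[keep, 0]], 1) / lengths[keep, None]
    d = np.abs(((pts[None, :, :] - pts[keep][:, None, :])
                * normals[:, None, :]).sum(-1))
    minor = float(d.max(axis=1).min())
    return major, minor


def _rasterize(poly: Polygon, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = np.asarray(poly.exterior.coords).T
    return draw.polygon(ys, xs, shape=shape)


# ---------------------------------------------------------------------------
# vessel placement
# ---------------------------------------------------------------------------


def _pick_sites(sites: list, n: int | None, rng: np.random.Generator,
                what: str) -> list:
    if n is None:
        return sites
    if n > len(sites):
        raise ValueError(
            f"infeasible packing: requested {n} {what} but only "
            f"{len(sites)} feasible sites"
        )
    idx = rng.choice(len(sites), size=n, replace=False)
    return [sites[i] for i in sorted(idx)]


class _Placer:
    """Tracks placed disks and rejects overlapping placements."""

    def __init__(self, H: int, W: int):
        self.H, self.W = H, W
        self.placed: list[tuple[float, float, float]] = []  # (y, x, r)

    def try_add(self, y: float, x: float, r: float, margin: float = 3.0) -> bool:
        if not (r + 1 <= x < self.W - r - 1 and r + 1 <= y < self.H - r - 1):
            return False
        for py, px_, pr in self.placed:
            if (py - y) ** 2 + (px_ - x) ** 2 < (pr + r + margin) ** 2:
                return False
        self.placed.append((y, x, r))
        return True


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------


def generate_tissue(params: TissueParams
                    ) -> tuple[np.ndarray, LabelMask, LabelMask,
                               list[StructureRecord]]:
    """Generate one synthetic GS-PSR field with exact ground truth.

    Returns the RGB image, the 5-class vessel mask, the binary lobule mask
    and one :class:`StructureRecord` per planted structure (lobule Feret
    diameters are analytic polygon calipers; vessel Feret diameters are the
    planted disk diameters).  Deterministic under ``params.seed``.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    H, W = p.height_px, p.width_px
    px = p.pixel_size_um
    shape = (H, W)

    centers = _lobule_centers(p, rng)
    cells = _voronoi_cells(centers, H, W)
    half_septum_px = 0.5 * p.septum_width_um / px

    lobule_grid = np.zeros(shape, dtype=np.uint8)
    records: list[StructureRecord] = []
    interiors: list[Polygon] = []
    border = shapely_box(0, 0, W, H).exterior
    for cell in cells:
        interior = cell.buffer(-half_septum_px)
        if interior.is_empty or interior.area < 9:
            continue
        if interior.geom_type != "Polygon":
            interior = max(interior.geoms, key=lambda g: g.area)
        rr, cc = _rasterize(interior, shape)
        if rr.size == 0:
            continue
        lobule_grid[rr, cc] = 1
        major_px, minor_px = _polygon_feret(interior)
        cy, cx = float(np.mean(rr)), float(np.mean(cc))
        records.append(StructureRecord(
            class_name="lobule",
            pixel_count=int(rr.size),
            area_um2=float(rr.size) * px * px,
            centroid=(cy, cx),
            feret_major_um=major_px * px,
            feret_minor_um=minor_px * px,
            clipped=cell.exterior.distance(border) < 1e-6,
        ))
        interiors.append(interior)

    vessel_grid = np.zeros(shape, dtype=np.uint8)
    placer = _Placer(H, W)
    vessels: list[tuple[str, float, float, float]] = []  # class, y, x, d_um

    # central veins at lobule centers
    central_sites = []
    for interior in interiors:
        c = interior.representative_point()
        room_px = interior.exterior.distance(c)
        central_sites.append((c.y, c.x, room_px))
    for (y, x, room_px) in _pick_sites(central_sites, p.n_central, rng,
                                       "central veins"):
        d_um = rng.uniform(*p.central_vein_diameter_um)
        r = 0.5 * d_um / px
        if r + 3 > room_px:  # halo and vein must stay inside the lobule
            d_um = p.central_vein_diameter_um[0]
            r = 0.5 * d_um / px
        if r + 3 <= room_px and placer.try_add(y, x, r):
            vessels.append(("central_vein", y, x, d_um))

    # portal triads (portal vein + artery + bile duct) at lobule corners
    raw_vertices = _triad_vertices(centers, H, W)
    min_sep = (p.portal_vein_diameter_um[1] + p.artery_diameter_um[1]) / px
    triad_sites: list[tuple[float, float]] = []
    for vy, vx in raw_vertices:
        if all((vy - ty) ** 2 + (vx - tx) ** 2 >= min_sep ** 2
               for ty, tx in triad_sites):
            triad_sites.append((vy, vx))
    triad_specs = [("portal_vein", p.portal_vein_diameter_um, p.n_portal),
                   ("artery", p.artery_diameter_um, p.n_artery),
                   ("bile_duct", p.bile_duct_diameter_um, p.n_bile_duct)]
    for offset_sign, (cls, rng_um, n) in enumerate(triad_specs):
        chosen = _pick_sites(list(triad_sites), n, rng, cls.replace("_", " ") + "s")
        for (vy, vx) in chosen:
            d_um = rng.uniform(*rng_um)
            r = 0.5 * d_um / px
            if offset_sign == 0:
                y, x = vy, vx
            else:
                # artery on one side of the portal vein, bile duct opposite
                theta = rng.uniform(0, 2 * np.pi)
                sign = 1.0 if offset_sign == 1 else -1.0
                gap = (0.5 * p.portal_vein_diameter_um[1] / px) + r + 5
                y = vy + sign * gap * np.sin(theta)
                x = vx + sign * gap * np.cos(theta)
            if placer.try_add(y, x, r):
                vessels.append((cls, y, x, d_um))
            elif n is not None:
                raise ValueError(
                    f"infeasible packing: could not place requested {cls}"
                )

    for cls, y, x, d_um in vessels:
        r = 0.5 * d_um / px
        rr, cc = draw.disk((y, x), max(r, 1.0), shape=shape)
        vessel_grid[rr, cc] = VESSEL_PALETTE.label_of(cls)
        records.append(StructureRecord(
            class_name=cls,
            pixel_count=int(rr.size),
            area_um2=float(rr.size) * px * px,
            centroid=(float(y), float(x)),
            feret_major_um=d_um,
            feret_minor_um=d_um,
        ))

    image = _paint(p, rng, lobule_grid, vessels)
    vessel_mask = LabelMask(vessel_grid, VESSEL_PALETTE, px)
    lobule_mask = LabelMask(lobule_grid, LOBULE_PALETTE, px)
    return image, vessel_mask, lobule_mask, records


def _triad_vertices(centers: np.ndarray, H: int, W: int) -> list[tuple[float, float]]:
    """Voronoi vertices (lobule corners) strictly inside the image."""
    if len(centers) < 4:
        return []
    vor = Voronoi(centers)
    out = []
    for vx, vy in vor.vertices:
        if 0 < vx < W and 0 < vy < H:
            out.append((float(vy), float(vx)))
    return out


def _paint(p: TissueParams, rng: np.random.Generator, lobule_grid: np.ndarray,
           vessels: list[tuple[str, float, float, float]]) -> np.ndarray:
    """Render the stained image from the planted geometry."""
    H, W = lobule_grid.shape
    shape = (H, W)
    px = p.pixel_size_um
    img = np.empty((H, W, 3), dtype=float)
    img[:] = _PARENCHYMA
    img[lobule_grid == 0] = _SEPTUM
    # brown GS halo of perivenous hepatocytes around central veins
    for cls, y, x, d_um in vessels:
        if cls != "central_vein":
            continue
        r = 0.5 * d_um / px
        rr, cc = draw.disk((y, x), 2.2 * r, shape=shape)
        img[rr, cc] = 0.35 * img[rr, cc] + 0.65 * _HALO
    # vessel walls and lumina
    for cls, y, x, d_um in vessels:
        r = max(0.5 * d_um / px, 1.0)
        wall = max(1.0, _WALL_FRACTION[cls] * 2 * r)
        rr, cc = draw.disk((y, x), r, shape=shape)
        img[rr, cc] = _WALL
        if r - wall >= 1.0:
            rr, cc = draw.disk((y, x), r - wall, shape=shape)
            img[rr, cc] = _LUMEN
    img += rng.normal(0.0, p.color_jitter_sd, size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# artifact injection
# ---------------------------------------------------------------------------


def inject_artifacts(image: np.ndarray, spec: ArtifactSpec,
                     seed: int = 0) -> np.ndarray:
    """Inject preparation artifacts into the image (truth masks untouched).

    tear: glass-colored rip polyline across the tissue; fold: darkened
    duplicated band; uneven_staining: smooth multiplicative gain field.
    Severity 0 returns the image unchanged.
    """
    out = np.asarray(image).astype(float).copy()
    known = {"tear", "fold", "uneven_staining"}
    unknown = set(spec.kinds) - known
    if unknown:
        raise ValueError(f"unknown artifact kind(s): {sorted(unknown)}")
    if spec.severity == 0:
        return out.astype(np.uint8)
    rng = np.random.default_rng(seed)
    H, W = out.shape[:2]
    for kind in spec.kinds:
        if kind == "uneven_staining":
            field_ = gaussian_filter(rng.standard_normal((H, W)),
                                     sigma=min(H, W) / 6.0)
            field_ /= max(np.abs(field_).max(), 1e-9)
            gain = 1.0 + 0.6 * spec.severity * field_
            out *= gain[..., None]
        elif kind == "tear":
            width = max(3, int(round(0.03 * spec.severity * min(H, W))))
            xs = np.linspace(0, W - 1, 16)
            x0 = rng.uniform(0.2, 0.8) * W
            ys = np.clip(
                H * 0.5
                + (xs - x0) * rng.uniform(-0.4, 0.4)
                + np.cumsum(rng.normal(0, 0.02 * H, size=xs.size)),
                0, H - 1,
            )
            canvas = np.zeros((H, W), dtype=bool)
            for i in range(len(xs) - 1):
                rr, cc = draw.line(int(ys[i]), int(xs[i]),
                                   int(ys[i + 1]), int(xs[i + 1]))
                canvas[rr, cc] = True
            from scipy.ndimage import binary_dilation
            from skimage.morphology import disk

            canvas = binary_dilation(canvas, disk(width))
            out[canvas] = _GLASS
        elif kind == "fold":
            band_w = max(4, int(round(0.10 * spec.severity * min(H, W))))
            r0 = int(rng.uniform(0.1, 0.8) * (H - band_w))
            shift = band_w
            src = np.roll(out, shift, axis=0)
            out[r0:r0 + band_w] = 0.65 * src[r0:r0 + band_w]
    return np.clip(out, 0, 255).astype(np.uint8)
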