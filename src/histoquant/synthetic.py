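"""Seeded synthetic-histology scene generators with pixel-level ground truth.

Four staining scenarios are emulated, one per validation experiment:

``cv_necrosis``
    Cresyl-violet cortex: dense violet Nissl texture (intact) against pale,
    sparsely textured necrotic patches. Ground truth is the necrosis mask.
``hemorrhage``
    Scattered micro-hemorrhages: clumps of discrete red-cell blobs on violet
    tissue. Ground truth is the set of red pixels; the manual proxy is the
    per-clump convex hull, which deliberately includes the gaps between
    blood-cell clusters — a human outlining the involved tissue volume.
``ihc_microglia``
    DAB-brown microglial somata on a pale blue counterstain; ``bushy``
    (large) and ``amoeboid`` (smaller) morphology presets whose soma areas
    straddle the 40 vs 25 um^2 minimum-size settings.
``silver``
    Near-achromatic gray silver deposits, optionally concentrated in a
    designated subregion of the ROI.

Every generator is a pure function of (params, seed): regeneration with the
same arguments is bit-identical. Each scene carries truth masks, manual
annotation proxies, and a parameter echo sufficient to reproduce it.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from shapely.geometry import MultiPoint, Polygon
from skimage import draw as skdraw

from . import palettes
from .image_model import (
    CalibratedImage,
    RegionAnnotation,
    write_geojson,
    write_tiff,
)

__all__ = [
    "SceneParams",
    "SyntheticScene",
    "make_cv_necrosis_scene",
    "make_hemorrhage_scene",
    "make_ihc_scene",
    "make_silver_scene",
    "make_scene",
    "BUSHY_SOMA_RADIUS_UM",
    "AMOEBOID_SOMA_RADIUS_UM",
]

SCENARIOS = ("cv_necrosis", "hemorrhage", "ihc_microglia", "silver")

#: soma radius ranges (um) for the two microglial morphology presets.
#: bushy somata are generated at >= 1.5x the 40 um^2 cortex minimum size so
#: size-filtered counts can recover ground truth exactly; amoeboid somata
#: fall between the 25 um^2 and 40 um^2 settings.
BUSHY_SOMA_RADIUS_UM = (4.4, 6.0)  # areas ~61-113 um^2
AMOEBOID_SOMA_RADIUS_UM = (3.3, 3.6)  # areas ~34-41 um^2, median ~37


@dataclass(frozen=True)
class SceneParams:
    """Generator knobs; scenario-specific fields are ignored elsewhere."""

    scenario: str
    width_px: int = 512
    height_px: int = 512
    mpp: float = 1.0
    noise_amplitude: float = 3.0

    # cv_necrosis
    necrosis_fraction: float = 0.3
    necrosis_blob_scale_px: float = 60.0  # correlation length of patch shapes

    # hemorrhage
    hemorrhage_fraction: float = 0.001354  # whole-hemisphere study regime
    n_clumps: int = 5
    n_blobs_per_clump: int | None = None  # overrides the area quota if set
    blob_radius_px: tuple[float, float] = (1.5, 2.8)
    gap_scale: float = 1.0  # 0 = solid bleeds, >0 = gappy red-cell clusters

    # ihc_microglia
    n_cells: int = 30
    morphology: str = "bushy"
    soma_radius_um: tuple[float, float] | None = None  # default per morphology

    # silver
    concentration_factor: float = 5.0
    deposit_density: float = 0.006  # deposits per px^2 outside the subregion
    deposit_radius_px: tuple[float, float] = (1.0, 1.6)
    subregion_um: tuple[float, float] = (200.0, 200.0)  # rostral field size
    subregion_origin_px: tuple[int, int] | None = None  # default: top-right
    roi_margin_px: int = 10

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("scene dimensions must be positive")
        if not (self.mpp > 0):
            raise ValueError("mpp must be positive")
        if self.noise_amplitude < 0:
            raise ValueError("noise amplitude must be non-negative")
        if not (0.0 <= self.necrosis_fraction <= 1.0):
            raise ValueError("necrosis_fraction must lie in [0, 1]")
        if not (0.0 <= self.hemorrhage_fraction <= 1.0):
            raise ValueError("hemorrhage_fraction must lie in [0, 1]")
        if self.n_cells < 0 or self.n_clumps < 0:
            raise ValueError("counts must be non-negative")
        if self.morphology not in ("bushy", "amoeboid"):
            raise ValueError(f"unknown morphology {self.morphology!r}")
        if self.concentration_factor < 1.0:
            raise ValueError("concentration_factor must be >= 1")

    def soma_radius_range_um(self) -> tuple[float, float]:
        if self.soma_radius_um is not None:
            return self.soma_radius_um
        return (
            BUSHY_SOMA_RADIUS_UM
            if self.morphology == "bushy"
            else AMOEBOID_SOMA_RADIUS_UM
        )


@dataclass
class SyntheticScene:
    """A generated image plus the ground truth needed to score algorithms."""

    image: CalibratedImage
    truth_masks: dict[str, np.ndarray]
    manual_proxies: list[RegionAnnotation]
    params: SceneParams
    seed: int
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, mask in self.truth_masks.items():
            if mask.shape != self.image.shape:
                raise ValueError(f"truth mask {name!r} does not match the image")

    def proxy_area_um2(self) -> float:
        """Total manual-proxy polygon area in square microns."""
        mpp = self.image.mpp
        return sum(a.area_px2 for a in self.manual_proxies) * mpp * mpp

    def truth_area_um2(self, name: str) -> float:
        return float(self.truth_masks[name].sum()) * self.image.mpp**2

    def write(self, out_dir: str | Path, stem: str = "scene") -> None:
        """Write image TIFF, truth-mask TIFFs, proxy GeoJSON, and params."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_tiff(self.image, out / f"{stem}.tif")
        import tifffile

        for name, mask in self.truth_masks.items():
            tifffile.imwrite(out / f"{stem}.truth.{name}.tif",
                             mask.astype(np.uint8) * 255)
        if self.manual_proxies:
            write_geojson(self.manual_proxies, out / f"{stem}.proxies.geojson")
        echo = dataclasses.asdict(self.params)
        echo["seed"] = self.seed
        for key, val in self.extras.items():
            if isinstance(val, (int, float, str, list, dict)):
                echo[f"extra_{key}"] = val
        (out / f"{stem}.params.json").write_text(json.dumps(echo, indent=1) + "\n")


# ---------------------------------------------------------------------------
# drawing helpers
# ---------------------------------------------------------------------------

def _flat_canvas(params: SceneParams, rgb: tuple[int, int, int]) -> np.ndarray:
    canvas = np.empty((params.height_px, params.width_px, 3), dtype=np.float64)
    canvas[:] = rgb
    return canvas


def _scatter_disks(
    canvas: np.ndarray,
    rows: np.ndarray,
    cols: np.ndarray,
    radii: np.ndarray,
    rgb: tuple[int, int, int],
    out_mask: np.ndarray | None = None,
    alpha: float = 1.0,
) -> None:
    """Paint filled disks; optionally accumulate them into a boolean mask."""
    shape = canvas.shape[:2]
    color = np.asarray(rgb, dtype=np.float64)
    for r, c, rad in zip(rows, cols, radii):
        rr, cc = skdraw.disk((r, c), rad, shape=shape)
        if alpha >= 1.0:
            canvas[rr, cc] = color
        else:
            canvas[rr, cc] = (1 - alpha) * canvas[rr, cc] + alpha * color
        if out_mask is not None:
            out_mask[rr, cc] = True


def _granules(
    rng: np.random.Generator,
    canvas: np.ndarray,
    region: np.ndarray,
    density: float,
    radius_range: tuple[float, float],
    rgb: tuple[int, int, int],
) -> None:
    """Scatter small textural disks with centers inside ``region``."""
    idx = np.flatnonzero(region.ravel())
    if idx.size == 0 or density <= 0:
        return
    n = int(round(density * idx.size))
    if n == 0:
        return
    pick = rng.choice(idx, size=n, replace=True)
    rows, cols = np.unravel_index(pick, region.shape)
    radii = rng.uniform(*radius_range, size=n)
    _scatter_disks(canvas, rows, cols, radii, rgb)


def _finish(canvas: np.ndarray, rng: np.random.Generator,
            params: SceneParams) -> CalibratedImage:
    """Add clipped Gaussian channel noise and quantize to 8 bits."""
    if params.noise_amplitude > 0:
        canvas = canvas + rng.normal(0.0, params.noise_amplitude, canvas.shape)
    pixels = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)
    return CalibratedImage(pixels=pixels, mpp=params.mpp)


def _hull_annotation(rows: np.ndarray, cols: np.ndarray, label: str,
                     pad_px: float = 0.5) -> RegionAnnotation | None:
    """Convex hull of pixel centers, padded to the outer pixel boundary.

    Emulates a hand-drawn outline around a cluster: the hull spans gaps
    between its member pixels, so its area is >= the pixel count whenever the
    cluster is non-convex or gappy.
    """
    if rows.size < 3:
        return None
    pts = MultiPoint([(c + 0.5, r + 0.5) for r, c in zip(rows, cols)])
    hull = pts.convex_hull.buffer(pad_px, quad_segs=2)
    if not isinstance(hull, Polygon) or hull.area <= 0:
        return None
    hull = hull.simplify(0.2)
    return RegionAnnotation(vertices=tuple(hull.exterior.coords)[:-1], label=label)


def _mask_component_hulls(mask: np.ndarray, label: str,
                          close_radius: int = 3) -> list[RegionAnnotation]:
    """Manual-annotation proxy: morphological closing, then one convex hull
    per connected clump of the closed mask."""
    if not mask.any():
        return []
    closed = ndi.binary_closing(mask, structure=_disk_structure(close_radius))
    labeled, n = ndi.label(closed)
    out = []
    for i in range(1, n + 1):
        rows, cols = np.nonzero(labeled == i)
        ann = _hull_annotation(rows, cols, label)
        if ann is not None:
            out.append(ann)
    return out


def _disk_structure(radius: int) -> np.ndarray:
    y, x = np.ogrid[-radius:radius + 1, -radius:radius + 1]
    return (x * x + y * y) <= radius * radius


# ---------------------------------------------------------------------------
# scenario generators
# ---------------------------------------------------------------------------

def make_cv_necrosis_scene(params: SceneParams, seed: int) -> SyntheticScene:
    """Cresyl-violet cortex with pale necrotic patches.

    The necrosis mask is a thresholded smoothed Gaussian field, so the
    requested area fraction is hit to within the quantile's raster
    resolution (well inside +-2%). Intact and necrotic tissue differ in both
    mean color (violet vs pale pink) and texture (dense dark Nissl granules
    vs sparse faint remnants), so a texture-aware classifier has signal
    beyond a plain color threshold.
    """
    if params.scenario != "cv_necrosis":
        raise ValueError("params.scenario must be 'cv_necrosis'")
    if params.necrosis_fraction > 0.95:
        raise ValueError(
            "necrosis fractions > 0.95 leave no intact tissue to train on"
        )
    rng = np.random.default_rng(seed)
    h, w = params.height_px, params.width_px

    frac = params.necrosis_fraction
    if frac <= 0:
        mask = np.zeros((h, w), dtype=bool)
    else:
        field_ = ndi.gaussian_filter(
            rng.standard_normal((h, w)), sigma=params.necrosis_blob_scale_px
        )
        thr = np.quantile(field_, 1.0 - frac)
        mask = field_ >= thr

    canvas = _flat_canvas(params, palettes.CV_VIOLET_BG)
    canvas[mask] = palettes.NECROSIS_BG
    # dense Nissl texture on intact tissue, sparse faint texture on necrosis
    _granules(rng, canvas, ~mask, density=0.020, radius_range=(1.0, 2.0),
              rgb=palettes.CV_NISSL_GRANULE)
    _granules(rng, canvas, mask, density=0.004, radius_range=(0.8, 1.5),
              rgb=palettes.NECROSIS_GRANULE)

    proxies = _mask_component_hulls(mask, "necrosis_manual", close_radius=5)
    return SyntheticScene(
        image=_finish(canvas, rng, params),
        truth_masks={"necrosis": mask},
        manual_proxies=proxies,
        params=params,
        seed=seed,
    )


def make_hemorrhage_scene(params: SceneParams, seed: int) -> SyntheticScene:
    """Micro-hemorrhages as clumped red-cell blobs on violet tissue.

    Red pixels (the truth mask) occupy ``hemorrhage_fraction`` of the frame;
    the manual proxy is one convex hull per clump and therefore includes the
    gaps between blood-cell clusters, reproducing by construction the
    mechanism behind the negative bias of pixel-exact automated areas.
    """
    if params.scenario != "hemorrhage":
        raise ValueError("params.scenario must be 'hemorrhage'")
    if params.hemorrhage_fraction > 0.05:
        raise ValueError("hemorrhage fraction above 5% is out of the "
                         "micro-hemorrhage regime")
    rng = np.random.default_rng(seed)
    h, w = params.height_px, params.width_px
    canvas = _flat_canvas(params, palettes.CV_VIOLET_BG)
    _granules(rng, canvas, np.ones((h, w), dtype=bool), density=0.012,
              radius_range=(1.0, 2.0), rgb=palettes.CV_NISSL_GRANULE)

    mask = np.zeros((h, w), dtype=bool)
    target_px = int(round(params.hemorrhage_fraction * h * w))
    proxies: list[RegionAnnotation] = []
    n_clumps = params.n_clumps if target_px > 0 or params.n_blobs_per_clump else 0

    # clump centers kept apart so per-clump hulls stay distinct
    centers: list[tuple[float, float]] = []
    margin = 0.08 * min(h, w) + 10
    min_sep = 0.25 * min(h, w)
    guard = 0
    while len(centers) < n_clumps and guard < 10_000:
        guard += 1
        cand = (rng.uniform(margin, h - margin), rng.uniform(margin, w - margin))
        if all((cand[0] - r) ** 2 + (cand[1] - c) ** 2 >= min_sep**2
               for r, c in centers):
            centers.append(cand)
    r_lo, r_hi = params.blob_radius_px
    mean_blob_px = np.pi * ((r_lo + r_hi) / 2.0) ** 2

    for ci, (cr, cc) in enumerate(centers):
        quota = max(1, target_px // max(1, n_clumps))
        clump_mask = np.zeros((h, w), dtype=bool)
        if params.gap_scale <= 0 and params.n_blobs_per_clump is None:
            # solid bleed: a single disk of the quota area
            rad = max(1.0, np.sqrt(quota / np.pi))
            _scatter_disks(canvas, np.array([cr]), np.array([cc]),
                           np.array([rad]), palettes.RBC_RED, clump_mask)
        else:
            spread = ((r_lo + r_hi) / 2.0) * (1.0 + 2.5 * params.gap_scale)
            if params.n_blobs_per_clump is not None:
                n_blobs = params.n_blobs_per_clump
            else:
                n_blobs = max(1, int(np.ceil(quota / mean_blob_px)))
            rows = np.clip(rng.normal(cr, spread * np.sqrt(n_blobs) / 2,
                                      n_blobs), 1, h - 2)
            cols = np.clip(rng.normal(cc, spread * np.sqrt(n_blobs) / 2,
                                      n_blobs), 1, w - 2)
            radii = rng.uniform(r_lo, r_hi, size=n_blobs)
            _scatter_disks(canvas, rows, cols, radii, palettes.RBC_RED,
                           clump_mask)
        mask |= clump_mask
        rr, cc2 = np.nonzero(clump_mask)
        ann = _hull_annotation(rr, cc2, f"hemorrhage_manual_{ci}")
        if ann is not None:
            proxies.append(ann)

    return SyntheticScene(
        image=_finish(canvas, rng, params),
        truth_masks={"hemorrhage_rbc": mask},
        manual_proxies=proxies,
        params=params,
        seed=seed,
    )


def make_ihc_scene(params: SceneParams, seed: int) -> SyntheticScene:
    """DAB-labeled microglial somata on a pale blue counterstain.

    Somata are non-overlapping disks (rejection-sampled centers with a
    clearance margin), so the truth mask has exactly ``n_cells`` connected
    components. Bushy cells additionally get faint process strokes rendered
    below the default segmentation threshold: they shape the picture, not
    the countable objects. Per-cell centroids and areas land in
    ``extras['cells']``.
    """
    if params.scenario != "ihc_microglia":
        raise ValueError("params.scenario must be 'ihc_microglia'")
    rng = np.random.default_rng(seed)
    h, w = params.height_px, params.width_px
    r_lo_um, r_hi_um = params.soma_radius_range_um()
    r_hi_px = r_hi_um / params.mpp

    canvas = _flat_canvas(params, palettes.IHC_COUNTERSTAIN)
    mask = np.zeros((h, w), dtype=bool)

    # rejection-sample non-overlapping centers with a smoothing-safe margin
    clearance = 2.0 * r_hi_px + 8.0
    margin = r_hi_px + 3.0
    if 2 * margin >= min(h, w):
        raise ValueError("scene too small for the requested soma size")
    centers: list[tuple[float, float]] = []
    attempts = 0
    max_attempts = 400 * max(1, params.n_cells)
    while len(centers) < params.n_cells:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"could not pack {params.n_cells} non-overlapping cells into "
                f"a {w}x{h} px scene"
            )
        cand = (rng.uniform(margin, h - margin), rng.uniform(margin, w - margin))
        if all((cand[0] - r) ** 2 + (cand[1] - c) ** 2 >= clearance**2
               for r, c in centers):
            centers.append(cand)

    cells = []
    for cr, cc in centers:
        r_px = rng.uniform(r_lo_um, r_hi_um) / params.mpp
        if params.morphology == "bushy":
            # faint thick processes radiating from the soma (sub-threshold DAB)
            n_proc = rng.integers(3, 6)
            angles = rng.uniform(0, 2 * np.pi, n_proc)
            for ang in angles:
                length = rng.uniform(1.2, 2.2) * r_px
                er = cr + length * np.sin(ang)
                ec = cc + length * np.cos(ang)
                rr, cc2 = skdraw.line(int(round(cr)), int(round(cc)),
                                      int(round(np.clip(er, 0, h - 1))),
                                      int(round(np.clip(ec, 0, w - 1))))
                for dr in (-1, 0, 1):
                    rrr = np.clip(rr + dr, 0, h - 1)
                    canvas[rrr, cc2] = (0.7 * canvas[rrr, cc2]
                                        + 0.3 * np.asarray(palettes.DAB_BROWN))
        soma = np.zeros((h, w), dtype=bool)
        _scatter_disks(canvas, np.array([cr]), np.array([cc]),
                       np.array([r_px]), palettes.DAB_BROWN, soma)
        mask |= soma
        area_um2 = float(soma.sum()) * params.mpp**2
        cells.append({"row": float(cr), "col": float(cc),
                      "radius_px": float(r_px), "area_um2": area_um2})

    proxies = []
    for i, cell in enumerate(cells):
        rr, cc2 = skdraw.disk((cell["row"], cell["col"]), cell["radius_px"],
                              shape=(h, w))
        ann = _hull_annotation(rr, cc2, f"cell_manual_{i}")
        if ann is not None:
            proxies.append(ann)

    return SyntheticScene(
        image=_finish(canvas, rng, params),
        truth_masks={"cell_nuclei": mask},
        manual_proxies=proxies,
        params=params,
        seed=seed,
        extras={"cells": cells, "n_cells": len(cells)},
    )


def make_silver_scene(params: SceneParams, seed: int) -> SyntheticScene:
    """Gray silver-stain deposits, concentrated in a designated subregion.

    The analysis ROI is the frame inset by ``roi_margin_px``; the subregion
    (default: top-right, emulating the rostral field) receives
    ``concentration_factor`` times the outside deposit density. Deposits are
    equal-RGB gray, so their chromaticity is achromatic up to the additive
    noise.
    """
    if params.scenario != "silver":
        raise ValueError("params.scenario must be 'silver'")
    rng = np.random.default_rng(seed)
    h, w = params.height_px, params.width_px
    m = params.roi_margin_px

    sub_w = int(round(params.subregion_um[0] / params.mpp))
    sub_h = int(round(params.subregion_um[1] / params.mpp))
    if params.subregion_origin_px is None:
        sx, sy = w - m - sub_w - 5, m + 5
    else:
        sx, sy = params.subregion_origin_px
    if sx < m or sy < m or sx + sub_w > w - m or sy + sub_h > h - m:
        raise ValueError("subregion does not fit inside the analysis ROI")

    roi = RegionAnnotation(
        vertices=((m, m), (w - m, m), (w - m, h - m), (m, h - m)),
        label="peduncle_roi",
    )
    sub = RegionAnnotation(
        vertices=((sx, sy), (sx + sub_w, sy), (sx + sub_w, sy + sub_h),
                  (sx, sy + sub_h)),
        label="rostral_subregion",
    )

    roi_mask = np.zeros((h, w), dtype=bool)
    roi_mask[m:h - m, m:w - m] = True
    sub_mask = np.zeros((h, w), dtype=bool)
    sub_mask[sy:sy + sub_h, sx:sx + sub_w] = True
    out_mask = roi_mask & ~sub_mask

    canvas = _flat_canvas(params, palettes.SILVER_BG)
    deposit = np.zeros((h, w), dtype=bool)

    def _drop(region: np.ndarray, density: float) -> None:
        idx = np.flatnonzero(region.ravel())
        n = int(round(density * idx.size))
        if n == 0 or idx.size == 0:
            return
        pick = rng.choice(idx, size=n, replace=True)
        rows, cols = np.unravel_index(pick, region.shape)
        radii = rng.uniform(*params.deposit_radius_px, size=n)
        _scatter_disks(canvas, rows, cols, radii, palettes.SILVER_GRAY, deposit)

    _drop(out_mask, params.deposit_density)
    _drop(sub_mask, params.deposit_density * params.concentration_factor)
    deposit &= roi_mask

    return SyntheticScene(
        image=_finish(canvas, rng, params),
        truth_masks={"silver_deposit": deposit},
        manual_proxies=[sub],
        params=params,
        seed=seed,
        extras={"roi": roi, "subregion": sub},
    )


_MAKERS = {
    "cv_necrosis": make_cv_necrosis_scene,
    "hemorrhage": make_hemorrhage_scene,
    "ihc_microglia": make_ihc_scene,
    "silver": make_silver_scene,
}


def make_scene(params: SceneParams, seed: int) -> SyntheticScene:
    """Dispatch to the scenario-specific generator."""
    return _MAKERS[params.scenario](params, seed)
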