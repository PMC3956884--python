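"""Core raster/annotation data model and color-space transforms.

Every downstream algorithm operates on a :class:`CalibratedImage` (8-bit RGB
raster plus a microns-per-pixel calibration) and, usually, one or more
:class:`RegionAnnotation` polygons delimiting regions of interest.

Conventions (used consistently across the package):

* pixel coordinates are 0-based, row-major, origin at the top-left corner;
  pixel ``(row, col)`` occupies the half-open square
  ``[col, col+1) x [row, row+1)`` with its center at ``(col+0.5, row+0.5)``;
* hue lives on a circular 0-1 scale with pure red at 0;
* saturation is ``1 - min(R,G,B)/mean(R,G,B)`` (0 for black/achromatic);
* intensity is the plain channel mean, on the 0-255 scale;
* optical density per channel is ``-log10(max(I, 1)/I0)`` with ``I0 = 255``.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
import tifffile
from shapely.geometry import Polygon, box, mapping, shape

__all__ = [
    "CalibratedImage",
    "RegionAnnotation",
    "RoiOutsideImageError",
    "rgb_to_hsi",
    "rgb_to_od",
    "polygon_area_um2",
    "rasterize_roi",
    "read_tiff",
    "write_tiff",
    "read_geojson",
    "write_geojson",
]

#: incident (background) intensity for optical-density computation
OD_I0 = 255.0
#: clamp applied to transmitted intensity before the log (avoids log of 0)
OD_EPS = 1.0


class RoiOutsideImageError(ValueError):
    """Raised when a polygon does not intersect the image frame at all.

    Distinct from an empty mask produced by a polygon that overlaps the frame
    but captures no pixel center.
    """


@dataclass(frozen=True)
class CalibratedImage:
    """8-bit RGB raster with a physical microns-per-pixel calibration."""

    pixels: np.ndarray  # (H, W, 3) uint8
    mpp: float  # microns per pixel, > 0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected (H, W, 3) raster, got shape {px.shape}")
        if px.dtype != np.uint8:
            if np.issubdtype(px.dtype, np.integer) and px.min() >= 0 and px.max() <= 255:
                px = px.astype(np.uint8)
            else:
                raise ValueError("pixel values must be 8-bit (0-255) integers")
        if px.size == 0:
            raise ValueError("image must contain at least one pixel")
        if not (self.mpp > 0):
            raise ValueError(f"mpp must be positive, got {self.mpp}")
        object.__setattr__(self, "pixels", px)

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def content_hash(self) -> str:
        """SHA-1 of pixel data + calibration; used as an identity token."""
        h = hashlib.sha1(self.pixels.tobytes())
        h.update(repr(float(self.mpp)).encode())
        return h.hexdigest()


@dataclass(frozen=True)
class RegionAnnotation:
    """A labeled, closed, simple polygon in pixel coordinates."""

    vertices: tuple[tuple[float, float], ...]
    label: str = ""

    def __post_init__(self) -> None:
        verts = tuple((float(x), float(y)) for x, y in self.vertices)
        if len(verts) < 3:
            raise ValueError("a polygon annotation needs at least 3 vertices")
        poly = Polygon(verts)
        if not poly.is_valid:
            raise ValueError(f"polygon {self.label!r} is invalid (self-intersecting?)")
        if poly.area <= 0:
            raise ValueError(f"polygon {self.label!r} has zero area")
        object.__setattr__(self, "vertices", verts)

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    @property
    def area_px2(self) -> float:
        """Shoelace area in squared pixels."""
        return float(self.polygon.area)


# ---------------------------------------------------------------------------
# color transforms
# ---------------------------------------------------------------------------

def rgb_to_hsi(rgb: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Convert RGB pixels to (hue, saturation, intensity).

    Accepts a single ``(3,)`` pixel or an ``(..., 3)`` array. Hue is on the
    circular 0-1 wheel with red at 0 (green at 1/3, blue at 2/3); achromatic
    pixels get hue 0 by convention. Saturation is ``1 - min/mean`` (0 for
    black). Intensity is the channel mean on the 0-255 scale.
    """
    arr = np.asarray(rgb, dtype=np.float64)
    scalar = arr.ndim == 1
    if arr.shape[-1] != 3:
        raise ValueError("last axis must hold the 3 RGB channels")
    arr = np.atleast_2d(arr)

    r, g, b = arr[..., 0], arr[..., 1], arr[..., 2]
    mx = arr.max(axis=-1)
    mn = arr.min(axis=-1)
    mean = arr.mean(axis=-1)
    delta = mx - mn

    with np.errstate(invalid="ignore", divide="ignore"):
        sat = np.where(mean > 0, 1.0 - mn / np.where(mean > 0, mean, 1.0), 0.0)

        hue6 = np.zeros_like(mx)
        chromatic = delta > 0
        d = np.where(chromatic, delta, 1.0)
        r_is_max = chromatic & (mx == r)
        g_is_max = chromatic & ~r_is_max & (mx == g)
        b_is_max = chromatic & ~r_is_max & ~g_is_max
        hue6 = np.where(r_is_max, ((g - b) / d) % 6.0, hue6)
        hue6 = np.where(g_is_max, (b - r) / d + 2.0, hue6)
        hue6 = np.where(b_is_max, (r - g) / d + 4.0, hue6)
    hue = (hue6 / 6.0) % 1.0

    if scalar:
        return float(hue[0]), float(sat[0]), float(mean[0])
    return hue, sat, mean


def rgb_to_od(rgb: np.ndarray, background_intensity: float = OD_I0) -> np.ndarray:
    """Per-channel optical density ``-log10(max(I, eps)/I0)``.

    ``eps = 1`` guards against log of zero, so a fully opaque pixel maps to
    ``log10(255) ~ 2.41`` per channel rather than infinity.
    """
    if not (background_intensity > 0):
        raise ValueError("background_intensity must be positive")
    arr = np.asarray(rgb, dtype=np.float64)
    od = -np.log10(np.maximum(arr, OD_EPS) / background_intensity)
    return np.maximum(od, 0.0)


# ---------------------------------------------------------------------------
# polygon geometry
# ---------------------------------------------------------------------------

def polygon_area_um2(roi: RegionAnnotation, mpp: float) -> float:
    """Shoelace polygon area converted to square microns."""
    if not (mpp > 0):
        raise ValueError("mpp must be positive")
    return roi.area_px2 * mpp * mpp


def rasterize_roi(roi: RegionAnnotation, image: CalibratedImage) -> np.ndarray:
    """Boolean mask of pixels whose center falls inside the polygon.

    Half-open convention: a center exactly on the polygon boundary is counted
    in when the interior lies below/right of it (top/left edges inclusive),
    implemented by nudging the sample point by +1e-9 in x and y.

    Raises :class:`RoiOutsideImageError` when the polygon does not intersect
    the image frame; an in-frame polygon too thin to capture any pixel center
    yields an ordinary all-False mask.
    """
    h, w = image.shape
    poly = roi.polygon
    frame = box(0.0, 0.0, float(w), float(h))
    if not poly.intersects(frame):
        raise RoiOutsideImageError(
            f"polygon {roi.label!r} lies entirely outside the {w}x{h} frame"
        )

    minx, miny, maxx, maxy = poly.bounds
    c0 = max(0, int(math.floor(minx)) - 1)
    c1 = min(w, int(math.ceil(maxx)) + 1)
    r0 = max(0, int(math.floor(miny)) - 1)
    r1 = min(h, int(math.ceil(maxy)) + 1)

    mask = np.zeros((h, w), dtype=bool)
    if c0 >= c1 or r0 >= r1:
        return mask
    cols, rows = np.meshgrid(np.arange(c0, c1), np.arange(r0, r1))
    eps = 1e-9
    xs = cols.ravel() + 0.5 + eps
    ys = rows.ravel() + 0.5 + eps
    inside = shapely.contains_xy(poly, xs, ys)
    mask[r0:r1, c0:c1] = inside.reshape(rows.shape)
    return mask


# ---------------------------------------------------------------------------
# I/O: TIFF rasters and GeoJSON annotations
# ---------------------------------------------------------------------------

def write_tiff(image: CalibratedImage, path: str | Path, sidecar: bool = True) -> None:
    """Write an RGB TIFF carrying mpp in its resolution tags.

    Resolution is stored as pixels-per-centimeter; a JSON sidecar
    (``<path>.mpp.json``) records mpp at full precision and wins over the
    tags when both are present at read time.
    """
    path = Path(path)
    px_per_cm = 10_000.0 / image.mpp
    tifffile.imwrite(
        path,
        image.pixels,
        photometric="rgb",
        resolution=(px_per_cm, px_per_cm),
        resolutionunit="CENTIMETER",
    )
    if sidecar:
        path.with_suffix(path.suffix + ".mpp.json").write_text(
            json.dumps({"mpp": image.mpp}) + "\n"
        )


def read_tiff(path: str | Path, mpp: float | None = None) -> CalibratedImage:
    """Read an RGB TIFF; mpp resolution order: argument > sidecar > tags."""
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        pixels = page.asarray()
        tag_mpp = None
        try:
            xres = page.tags["XResolution"].value
            unit = page.tags["ResolutionUnit"].value
            num, den = xres
            px_per_unit = num / den
            unit_um = {2: 25_400.0, 3: 10_000.0}.get(int(unit))
            if unit_um and px_per_unit > 0:
                tag_mpp = unit_um / px_per_unit
        except (KeyError, ZeroDivisionError, TypeError):
            tag_mpp = None
    if pixels.ndim == 3 and pixels.shape[2] == 4:  # drop alpha if present
        pixels = pixels[:, :, :3]
    sidecar = path.with_suffix(path.suffix + ".mpp.json")
    if mpp is None and sidecar.exists():
        mpp = float(json.loads(sidecar.read_text())["mpp"])
    if mpp is None:
        mpp = tag_mpp
    if mpp is None:
        raise ValueError(f"no mpp calibration found for {path}")
    return CalibratedImage(pixels=pixels, mpp=float(mpp))


def write_geojson(annotations: list[RegionAnnotation], path: str | Path) -> None:
    """Write annotations as a GeoJSON FeatureCollection (pixel coordinates)."""
    features = [
        {
            "type": "Feature",
            "geometry": mapping(a.polygon),
            "properties": {"label": a.label},
        }
        for a in annotations
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, indent=1)
        + "\n"
    )


def read_geojson(path: str | Path) -> list[RegionAnnotation]:
    """Read Polygon features back into :class:`RegionAnnotation` objects."""
    doc = json.loads(Path(path).read_text())
    out: list[RegionAnnotation] = []
    for feat in doc.get("features", []):
        geom = shape(feat["geometry"])
        if geom.geom_type != "Polygon":
            raise ValueError(f"unsupported geometry type {geom.geom_type!r}")
        label = str(feat.get("properties", {}).get("label", ""))
        out.append(
            RegionAnnotation(
                vertices=tuple(geom.exterior.coords)[:-1], label=label
            )
        )
    return out
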