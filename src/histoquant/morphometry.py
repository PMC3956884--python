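"""Nuclear morphometry: segmentation, size/shape filtering, cell density.

The pipeline mirrors the validated IHC workflow: deconvolve the DAB channel,
pre-smooth with a physical averaging radius, threshold, split touching
objects with a distance-transform watershed whose marker merging is governed
by a curvature threshold, then filter survivors by minimum nuclear size and
minimum elongation factor. Two region presets reflect the validated
settings: cortex (bushy microglia) keeps the 40 um^2 minimum size, the
cerebral peduncle (smaller amoeboid microglia) drops it to 25 um^2; both use
elongation 0.2 and curvature threshold 2.5.

Cell density uses the volumetric formula n / (ROI area x section thickness)
with the 40 um (0.040 mm) section thickness, yielding cells/mm^3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import gaussian
from skimage.measure import label as sk_label
from skimage.measure import regionprops
from skimage.morphology import h_maxima
from skimage.segmentation import watershed

from . import palettes
from .deconvolution import StainMatrix, deconvolve, normalize_stain_matrix
from .image_model import CalibratedImage, RegionAnnotation, polygon_area_um2

__all__ = [
    "MorphometryParams", "SegmentedObject", "CellDensityResult",
    "CORTEX_PRESET", "PEDUNCLE_PRESET", "default_ihc_stain_matrix",
    "segment_cells", "filter_objects", "class_intensity",
    "intensity_summary", "cell_density",
]

#: vibratome section thickness in mm (40 um), the density formula's divisor
SECTION_THICKNESS_MM = 0.040

#: h-maxima prominence per unit curvature threshold, in um. The vendor's
#: curvature semantics are unpublished; only the direction (lower threshold
#: splits more) is contractual, the scale is a package convention.
_CURVATURE_DEPTH_UM = 0.4


@dataclass(frozen=True)
class MorphometryParams:
    averaging_radius_um: float = 1.0
    segmentation_intensity_threshold: float = 0.5  # on DAB concentration
    curvature_threshold: float = 2.5
    min_nuclear_size_um2: float = 40.0
    min_elongation: float = 0.2
    cytoplasmic_rejection: bool = False
    rejection_rim_um: float = 0.5
    class_bounds: tuple[float, float] = (0.45, 0.9)  # 1+/2+ and 2+/3+ cuts

    def __post_init__(self) -> None:
        if self.min_nuclear_size_um2 <= 0:
            raise ValueError("min_nuclear_size_um2 must be positive")
        if not (0.0 < self.min_elongation <= 1.0):
            raise ValueError("min_elongation must lie in (0, 1]")
        if self.curvature_threshold < 0:
            raise ValueError("curvature_threshold must be >= 0")
        lo, hi = self.class_bounds
        if not (0.0 <= lo < hi):
            raise ValueError("class bounds must be ascending and non-negative")


#: validated settings for bushy cortical microglia
CORTEX_PRESET = MorphometryParams(min_nuclear_size_um2=40.0,
                                  min_elongation=0.2,
                                  curvature_threshold=2.5)
#: validated settings for the smaller amoeboid microglia of the peduncle
PEDUNCLE_PRESET = MorphometryParams(min_nuclear_size_um2=25.0,
                                    min_elongation=0.2,
                                    curvature_threshold=2.5)

PRESETS = {"cortex": CORTEX_PRESET, "peduncle": PEDUNCLE_PRESET}


@dataclass
class SegmentedObject:
    """One segmented cell with its morphometric measurements."""

    label: int
    coords: np.ndarray  # (n, 2) row/col pixel coordinates
    area_um2: float
    elongation: float  # minor/major axis ratio of the fitted ellipse, (0, 1]
    mean_concentration: float
    intensity_class: str = ""  # "", "1+", "2+" or "3+"


@dataclass(frozen=True)
class CellDensityResult:
    n_cells: int
    roi_area_mm2: float
    section_thickness_mm: float
    density_per_mm3: float


def default_ihc_stain_matrix() -> StainMatrix:
    """DAB + pale blue counterstain, third channel completed orthonormally."""
    return normalize_stain_matrix(
        [palettes.DAB_OD, palettes.IHC_COUNTERSTAIN_OD, None],
        names=("dab", "counterstain", "residual"),
    )


def segment_cells(
    image: CalibratedImage,
    roi_mask: np.ndarray,
    params: MorphometryParams = CORTEX_PRESET,
    stain_matrix: StainMatrix | None = None,
) -> list[SegmentedObject]:
    """Segment DAB-positive cells inside the ROI.

    Steps: color deconvolution (DAB channel) -> Gaussian pre-smoothing at
    the averaging radius -> concentration threshold -> distance-transform
    watershed, with candidate markers from h-maxima whose prominence depth
    grows with the curvature threshold (a higher threshold merges more
    aggressively) -> connected objects measured via second-moment ellipse
    fits. Optional cytoplasmic rejection erodes a rim before measuring.
    """
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != image.shape:
        raise ValueError("ROI mask shape does not match the image")
    if not roi_mask.any():
        raise ValueError("empty ROI")
    if stain_matrix is None:
        stain_matrix = default_ihc_stain_matrix()

    conc = deconvolve(image, roi_mask, stain_matrix).channel("dab")

    sigma_px = params.averaging_radius_um / image.mpp
    if sigma_px < 1.0:
        warnings.warn(
            "averaging radius below one pixel at this calibration; "
            "clamping to 1 px", stacklevel=2,
        )
        sigma_px = 1.0
    smoothed = gaussian(conc, sigma=sigma_px, preserve_range=True)

    binary = (smoothed > params.segmentation_intensity_threshold) & roi_mask
    if params.cytoplasmic_rejection:
        rim_px = max(1, int(round(params.rejection_rim_um / image.mpp)))
        binary = ndi.binary_erosion(binary, iterations=rim_px)
    if not binary.any():
        return []

    dist = ndi.distance_transform_edt(binary)
    h_px = max(_CURVATURE_DEPTH_UM * params.curvature_threshold / image.mpp,
               1e-6)
    peaks = h_maxima(dist, h_px)
    markers, n_markers = ndi.label(peaks)
    if n_markers == 0:
        labeled = sk_label(binary)
    else:
        labeled = watershed(-dist, markers=markers, mask=binary)

    objects: list[SegmentedObject] = []
    mpp2 = image.mpp**2
    for prop in regionprops(labeled, intensity_image=smoothed):
        major = prop.axis_major_length
        minor = prop.axis_minor_length
        elong = (minor / major) if major > 0 else 1.0
        objects.append(
            SegmentedObject(
                label=int(prop.label),
                coords=prop.coords,
                area_um2=float(prop.area) * mpp2,
                elongation=float(elong),
                mean_concentration=float(prop.intensity_mean),
            )
        )
    return objects


def filter_objects(
    objects: list[SegmentedObject],
    params: MorphometryParams,
) -> list[SegmentedObject]:
    """Keep objects meeting both the size and elongation minima."""
    return [
        o for o in objects
        if o.area_um2 >= params.min_nuclear_size_um2
        and o.elongation >= params.min_elongation
    ]


def class_intensity(
    objects: list[SegmentedObject],
    bounds: tuple[float, float] | None = None,
    params: MorphometryParams = CORTEX_PRESET,
) -> list[SegmentedObject]:
    """Assign 1+/2+/3+ intensity classes by mean concentration.

    Bands are half-open, upper-exclusive: 1+ below the first bound, 2+ in
    [first, second), 3+ at or above the second.
    """
    lo, hi = bounds if bounds is not None else params.class_bounds
    if not (lo < hi):
        raise ValueError("class bounds overlap")
    out = []
    for o in objects:
        if o.mean_concentration < lo:
            cls = "1+"
        elif o.mean_concentration < hi:
            cls = "2+"
        else:
            cls = "3+"
        out.append(replace_class(o, cls))
    return out


def replace_class(obj: SegmentedObject, cls: str) -> SegmentedObject:
    return SegmentedObject(
        label=obj.label, coords=obj.coords, area_um2=obj.area_um2,
        elongation=obj.elongation, mean_concentration=obj.mean_concentration,
        intensity_class=cls,
    )


def intensity_summary(objects: list[SegmentedObject]) -> dict:
    """API (average positive intensity), mean OD, and per-class percentages."""
    n = len(objects)
    if n == 0:
        return {"n": 0, "api": 0.0, "mean_od": 0.0,
                "pct_1plus": 0.0, "pct_2plus": 0.0, "pct_3plus": 0.0}
    concs = np.array([o.mean_concentration for o in objects])
    counts = {c: sum(1 for o in objects if o.intensity_class == c)
              for c in ("1+", "2+", "3+")}
    return {
        "n": n,
        "api": float(concs.mean()),
        "mean_od": float(concs.mean()),
        "pct_1plus": 100.0 * counts["1+"] / n,
        "pct_2plus": 100.0 * counts["2+"] / n,
        "pct_3plus": 100.0 * counts["3+"] / n,
    }


def cell_density(
    n_cells: int,
    roi: RegionAnnotation | float,
    mpp: float | None = None,
    section_thickness_mm: float = SECTION_THICKNESS_MM,
) -> CellDensityResult:
    """Volumetric cell density: n / (ROI area [mm^2] x thickness [mm]).

    ``roi`` may be a polygon annotation (with ``mpp`` for calibration) or a
    precomputed ROI area in um^2.
    """
    if n_cells < 0:
        raise ValueError("cell count must be >= 0")
    if isinstance(roi, RegionAnnotation):
        if mpp is None:
            raise ValueError("mpp is required with a polygon ROI")
        area_um2 = polygon_area_um2(roi, mpp)
    else:
        area_um2 = float(roi)
    if area_um2 <= 0:
        raise ValueError("ROI area must be positive")
    area_mm2 = area_um2 * 1e-6
    density = n_cells / (area_mm2 * section_thickness_mm)
    return CellDensityResult(
        n_cells=int(n_cells),
        roi_area_mm2=area_mm2,
        section_thickness_mm=section_thickness_mm,
        density_per_mm3=density,
    )
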