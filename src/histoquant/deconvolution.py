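"""Color deconvolution into stain channels and OD / %Pos quantification.

Stain amounts add linearly in optical-density space, so a pixel's OD triple
is a non-negative mixture over up to three stain OD unit vectors. Inverting
the stain matrix recovers per-stain concentrations; small negative
concentrations from noisy pixels are clamped to zero with the clamp
magnitude recorded rather than silently discarded.

Quantification follows the two whole-slide metrics: the percentage of
analyzed pixels whose concentration clears a positivity threshold (%Pos),
and the product of the mean positive OD with that percentage (OD x %Pos).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .image_model import CalibratedImage, rgb_to_od

__all__ = ["StainMatrix", "DeconvolutionResult", "StainQuantification",
           "normalize_stain_matrix", "deconvolve", "quantify_stain"]

_PARALLEL_TOL = 1e-6


@dataclass(frozen=True)
class StainMatrix:
    """Columns are unit OD vectors, one per named stain channel."""

    matrix: np.ndarray  # (3, 3), columns unit-norm
    names: tuple[str, str, str]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.shape != (3, 3):
            raise ValueError("stain matrix must be 3x3")
        norms = np.linalg.norm(m, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("stain matrix columns must be unit-norm")
        if abs(np.linalg.det(m)) < 1e-9:
            raise ValueError("stain matrix is singular")
        object.__setattr__(self, "matrix", m)

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)


def normalize_stain_matrix(
    raw_vectors: list[np.ndarray | tuple | None],
    names: tuple[str, str, str] = ("stain1", "stain2", "stain3"),
) -> StainMatrix:
    """Build a stain matrix from up to three raw OD vectors.

    Supplied vectors are scaled to unit norm; missing (None) columns are
    completed by Gram-Schmidt orthonormalization against the supplied ones,
    so the result is always invertible. Two (anti)parallel supplied vectors
    are rejected — they cannot define separable channels.
    """
    if len(raw_vectors) != 3:
        raise ValueError("expected exactly three (possibly None) vectors")
    supplied = []
    for v in raw_vectors:
        if v is None:
            supplied.append(None)
            continue
        arr = np.asarray(v, dtype=np.float64)
        if arr.shape != (3,):
            raise ValueError("each stain vector must have 3 components")
        norm = np.linalg.norm(arr)
        if norm < 1e-12:
            raise ValueError("zero stain vector supplied")
        supplied.append(arr / norm)
    if all(v is None for v in supplied):
        raise ValueError("at least one stain vector must be supplied")

    given = [v for v in supplied if v is not None]
    for i in range(len(given)):
        for j in range(i + 1, len(given)):
            if np.linalg.norm(np.cross(given[i], given[j])) < _PARALLEL_TOL:
                raise ValueError("supplied stain vectors are parallel")

    columns = list(supplied)
    basis = list(given)
    for idx, col in enumerate(columns):
        if col is not None:
            continue
        if len(basis) == 2:
            new = np.cross(basis[0], basis[1])
        else:
            # orthogonal residual of a probe axis against the known columns
            for probe in np.eye(3):
                new = probe.copy()
                for b in basis:
                    new -= (new @ b) * b
                if np.linalg.norm(new) > _PARALLEL_TOL:
                    break
        new = new / np.linalg.norm(new)
        columns[idx] = new
        basis.append(new)
    return StainMatrix(matrix=np.column_stack(columns), names=tuple(names))


@dataclass
class DeconvolutionResult:
    """Per-channel concentration rasters plus clamp bookkeeping."""

    concentrations: np.ndarray  # (H, W, 3), channel order = matrix columns
    names: tuple[str, str, str]
    clamp_fraction: float  # fraction of ROI pixels that needed clamping
    max_clamp: float  # largest clamped |negative concentration|

    def channel(self, name: str) -> np.ndarray:
        return self.concentrations[..., self.names.index(name)]


def deconvolve(
    image: CalibratedImage,
    roi_mask: np.ndarray | None,
    matrix: StainMatrix,
) -> DeconvolutionResult:
    """Invert the stain matrix per pixel: solve OD = M c for concentrations.

    Negative concentrations (noise pushed outside the stain simplex) are
    clamped to zero; the affected pixel fraction and worst magnitude are
    reported. Pixels outside the ROI get zero concentration in all channels.
    """
    od = rgb_to_od(image.pixels)  # (H, W, 3)
    conc = od @ matrix.inverse.T
    if roi_mask is not None:
        roi_mask = np.asarray(roi_mask, dtype=bool)
        if roi_mask.shape != image.shape:
            raise ValueError("ROI mask shape does not match the image")
        conc = np.where(roi_mask[..., None], conc, 0.0)
        n_analyzed = int(roi_mask.sum())
    else:
        n_analyzed = conc.shape[0] * conc.shape[1]
    negative = conc < 0
    max_clamp = float(-conc[negative].min()) if negative.any() else 0.0
    clamp_frac = (
        float(negative.any(axis=-1).sum()) / n_analyzed if n_analyzed else 0.0
    )
    return DeconvolutionResult(
        concentrations=np.maximum(conc, 0.0),
        names=matrix.names,
        clamp_fraction=clamp_frac,
        max_clamp=max_clamp,
    )


@dataclass(frozen=True)
class StainQuantification:
    """Summary metrics of one stain channel over an ROI."""

    channel: str
    mean_od: float  # mean concentration of positive pixels (OD units)
    pct_pos: float  # percentage of ROI pixels above the positivity threshold
    od_x_pctpos: float  # mean_od * pct_pos, the combined burden metric
    n_roi: int
    n_positive: int


def quantify_stain(
    concentrations: np.ndarray,
    roi_mask: np.ndarray,
    positivity_threshold: float = 0.05,
    channel: str = "stain",
) -> StainQuantification:
    """%Pos and OD x %Pos of a single concentration raster over an ROI."""
    if positivity_threshold < 0:
        raise ValueError("positivity threshold must be >= 0")
    roi_mask = np.asarray(roi_mask, dtype=bool)
    conc = np.asarray(concentrations, dtype=np.float64)
    if conc.shape != roi_mask.shape:
        raise ValueError("concentration raster and ROI mask shapes differ")
    n_roi = int(roi_mask.sum())
    if n_roi == 0:
        raise ValueError("empty ROI")
    vals = conc[roi_mask]
    pos = vals > positivity_threshold
    n_pos = int(pos.sum())
    mean_od = float(vals[pos].mean()) if n_pos else 0.0
    pct = 100.0 * n_pos / n_roi
    return StainQuantification(
        channel=channel,
        mean_od=mean_od,
        pct_pos=pct,
        od_x_pctpos=mean_od * pct,
        n_roi=n_roi,
        n_positive=n_pos,
    )
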