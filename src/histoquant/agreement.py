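"""Pearson correlation and Bland-Altman agreement for paired measurements.

Correlation answers "do the two methods rank sections the same way";
Bland-Altman answers "do they give the same numbers", via the mean paired
difference and limits of agreement at mean +- 1.96 x SD of the differences
(SD with the n-1 denominator). Differences are taken as method_a - method_b
throughout, with method_a conventionally the manual/reference measurement,
so a positive mean difference means the automated method reads low.

``compare_methods`` is the study-level harness: it runs an automated
quantifier and its manual proxy over a list of synthetic scenes and returns
the agreement report for the resulting pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .image_model import polygon_area_um2, rasterize_roi
from .synthetic import SyntheticScene

__all__ = ["PairedMeasurements", "AgreementReport", "pearson",
           "bland_altman", "compare_methods"]


@dataclass(frozen=True)
class PairedMeasurements:
    """Equal-length paired method readings with a unit label."""

    method_a: np.ndarray  # reference / manual
    method_b: np.ndarray  # automated
    unit: str = ""
    ids: tuple = ()

    def __post_init__(self) -> None:
        a = np.asarray(self.method_a, dtype=np.float64)
        b = np.asarray(self.method_b, dtype=np.float64)
        if a.ndim != 1 or a.shape != b.shape:
            raise ValueError("paired vectors must be 1-D and equal length")
        if a.size < 3:
            raise ValueError("need at least 3 pairs")
        if not (np.isfinite(a).all() and np.isfinite(b).all()):
            raise ValueError("paired values must be finite")
        object.__setattr__(self, "method_a", a)
        object.__setattr__(self, "method_b", b)
        if not self.ids:
            object.__setattr__(self, "ids", tuple(range(a.size)))

    @property
    def n(self) -> int:
        return int(self.method_a.size)


@dataclass
class AgreementReport:
    pearson_r: float
    p_value: float
    n: int
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    unit: str = ""
    differences: np.ndarray = field(default_factory=lambda: np.empty(0))
    averages: np.ndarray = field(default_factory=lambda: np.empty(0))
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "pearson_r": self.pearson_r,
            "p_value": self.p_value,
            "n": self.n,
            "mean_diff": self.mean_diff,
            "sd_diff": self.sd_diff,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "unit": self.unit,
            "metadata": dict(self.metadata),
        }


def pearson(pairs: PairedMeasurements) -> tuple[float, float, int]:
    """Product-moment r with a two-sided t-transform p-value (n-2 df)."""
    a, b = pairs.method_a, pairs.method_b
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("Pearson r is undefined for a zero-variance vector")
    res = sps.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue), pairs.n


def bland_altman(pairs: PairedMeasurements) -> AgreementReport:
    """Mean difference and +-1.96 SD limits of agreement (a - b)."""
    a, b = pairs.method_a, pairs.method_b
    diffs = a - b
    means = (a + b) / 2.0
    mean_diff = float(diffs.mean())
    sd_diff = float(diffs.std(ddof=1))
    loa = 1.96 * sd_diff
    try:
        r, p, n = pearson(pairs)
    except ValueError:
        r, p, n = float("nan"), float("nan"), pairs.n
    return AgreementReport(
        pearson_r=r,
        p_value=p,
        n=pairs.n,
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_low=mean_diff - loa,
        loa_high=mean_diff + loa,
        unit=pairs.unit,
        differences=diffs,
        averages=means,
        metadata={"difference_direction": "method_a - method_b"},
    )


# ---------------------------------------------------------------------------
# study-level harness
# ---------------------------------------------------------------------------

def _quantify_ppc_area(scene: SyntheticScene, manual_source: str, kw: dict):
    from .ppc import PPCParams, classify_pixels, summarize_ppc

    params = kw.get("ppc_params") or PPCParams()
    roi_mask = np.ones(scene.image.shape, dtype=bool)
    summary = summarize_ppc(classify_pixels(scene.image, roi_mask, params))
    automated = summary["positive_area_um2"]
    if manual_source == "truth":
        manual = scene.truth_area_um2("hemorrhage_rbc")
    else:
        manual = scene.proxy_area_um2()
    return manual, automated, "um^2"


def _quantify_necrosis_area(scene: SyntheticScene, manual_source: str, kw: dict):
    from .classifier import predict_map

    model = kw.get("model")
    if model is None:
        raise ValueError("necrosis_area quantifier requires a trained model")
    roi_mask = np.ones(scene.image.shape, dtype=bool)
    automated = predict_map(model, scene.image, roi_mask)["necrosis_area_um2"]
    if manual_source == "truth":
        manual = scene.truth_area_um2("necrosis")
    else:
        manual = scene.proxy_area_um2()
    return manual, automated, "um^2"


def _quantify_cell_density(scene: SyntheticScene, manual_source: str, kw: dict):
    from .morphometry import (CORTEX_PRESET, cell_density, filter_objects,
                              segment_cells)

    params = kw.get("morph_params") or CORTEX_PRESET
    roi_mask = np.ones(scene.image.shape, dtype=bool)
    objs = filter_objects(segment_cells(scene.image, roi_mask, params), params)
    area_um2 = scene.image.width_px * scene.image.height_px * scene.image.mpp**2
    automated = cell_density(len(objs), area_um2).density_per_mm3
    manual = cell_density(scene.extras["n_cells"], area_um2).density_per_mm3
    return manual, automated, "cells/mm^3"


def _quantify_od_pctpos(scene: SyntheticScene, manual_source: str, kw: dict):
    from . import palettes
    from .deconvolution import deconvolve, normalize_stain_matrix, quantify_stain

    matrix = kw.get("stain_matrix") or normalize_stain_matrix(
        [palettes.SILVER_OD_RAW, palettes.COUNTERSTAIN_OD, None],
        names=("silver", "counterstain", "residual"),
    )
    threshold = kw.get("positivity_threshold", 0.05)
    roi_mask = rasterize_roi(scene.extras["roi"], scene.image)
    sub_mask = rasterize_roi(scene.extras["subregion"], scene.image)
    silver = deconvolve(scene.image, roi_mask, matrix).channel("silver")
    whole = quantify_stain(silver, roi_mask, threshold, "silver").od_x_pctpos
    sub = quantify_stain(silver, sub_mask, threshold, "silver").od_x_pctpos
    # the "manual" arm is the conventional high-magnification static field,
    # i.e. the subregion reading; the automated arm is the whole-ROI reading
    return sub, whole, "OD x %Pos"


_QUANTIFIERS = {
    "ppc_area": ("hemorrhage", _quantify_ppc_area),
    "necrosis_area": ("cv_necrosis", _quantify_necrosis_area),
    "cell_density": ("ihc_microglia", _quantify_cell_density),
    "od_pctpos": ("silver", _quantify_od_pctpos),
}


def compare_methods(
    scenes: list[SyntheticScene],
    quantifier: str,
    manual_source: str = "proxy",
    **kwargs,
) -> AgreementReport:
    """Run a quantifier and its manual counterpart over scenes; report agreement.

    ``quantifier`` is one of ``ppc_area``, ``necrosis_area``,
    ``cell_density``, ``od_pctpos``; every scene must match the quantifier's
    scenario. ``manual_source`` selects the reference arm: the ground-truth
    mask (``truth``) or the hand-outline proxy (``proxy``).
    """
    if quantifier not in _QUANTIFIERS:
        raise ValueError(f"unknown quantifier {quantifier!r}")
    if manual_source not in ("truth", "proxy"):
        raise ValueError("manual_source must be 'truth' or 'proxy'")
    if len(scenes) < 3:
        raise ValueError("need at least 3 scenes")
    scenario, fn = _QUANTIFIERS[quantifier]
    for scene in scenes:
        if scene.params.scenario != scenario:
            raise ValueError(
                f"quantifier {quantifier!r} expects {scenario!r} scenes, got "
                f"{scene.params.scenario!r}"
            )
    manual, automated, unit = [], [], ""
    for scene in scenes:
        m, a, unit = fn(scene, manual_source, kwargs)
        manual.append(m)
        automated.append(a)
    pairs = PairedMeasurements(
        method_a=np.asarray(manual), method_b=np.asarray(automated), unit=unit
    )
    report = bland_altman(pairs)
    report.metadata.update(
        quantifier=quantifier,
        manual_source=manual_source,
        roi_scope=kwargs.get("roi_scope", "frame"),
    )
    return report
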