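"""Trainable tissue-region classifier (necrotic vs intact cortex).

A surrogate for the commercial pattern-recognition step: patches sampled
inside expert-annotated regions are summarized by a fixed bank of color and
texture statistics and fed to a seeded random-forest classifier. The
evaluation contract is the one the validation design needs — train on
annotated regions, emit dense class maps, and report a false positive rate
on known-intact tissue and a positive recognition rate on known-necrotic
tissue — with a leakage guard refusing evaluation on training material.

Features per patch (fixed length 13): per-channel mean and standard
deviation, circular hue mean (as cos/sin components), saturation and
intensity means, gradient energy, and gray-level entropy. Necrotic tissue is
paler and texturally sparser than Nissl-dense intact cortex, so both color
and texture channels carry signal.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
from shapely.geometry import Polygon
from sklearn.ensemble import RandomForestClassifier

from .image_model import CalibratedImage, RegionAnnotation, rgb_to_hsi

__all__ = [
    "TrainingExample", "ClassifierModel", "ClassifierEval",
    "extract_features", "sample_training_patches", "train",
    "predict_map", "evaluate", "FEATURE_NAMES",
]

NECROSIS = "necrosis"
INTACT = "intact"

FEATURE_NAMES = (
    "mean_r", "mean_g", "mean_b", "sd_r", "sd_g", "sd_b",
    "hue_cos", "hue_sin", "sat_mean", "intensity_mean",
    "gradient_energy", "entropy", "granule_fraction",
)


@dataclass(frozen=True)
class TrainingExample:
    image: CalibratedImage
    annotation: RegionAnnotation
    tissue_class: str  # NECROSIS or INTACT


@dataclass
class ClassifierModel:
    forest: RandomForestClassifier
    patch_size: int
    seed: int
    classes: tuple[str, ...]
    training_accuracy: float = 0.0
    #: (image content hash, polygon) pairs of the training regions,
    #: kept for the evaluation leakage guard
    training_regions: list[tuple[str, Polygon]] = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        Path(path).write_bytes(pickle.dumps(self))

    @staticmethod
    def load(path: str | Path) -> "ClassifierModel":
        model = pickle.loads(Path(path).read_bytes())
        if not isinstance(model, ClassifierModel):
            raise ValueError("file does not contain a ClassifierModel")
        return model


@dataclass(frozen=True)
class ClassifierEval:
    """FPR on a known-negative region, PRR on a known-positive region (%)."""

    fpr: float
    prr: float


def extract_features(
    image: CalibratedImage,
    patch_center: tuple[int, int],
    patch_size: int,
) -> np.ndarray:
    """Feature vector of the square patch centered at (row, col)."""
    r, c = patch_center
    half = patch_size // 2
    r0, c0 = r - half, c - half
    r1, c1 = r0 + patch_size, c0 + patch_size
    h, w = image.shape
    if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
        raise ValueError("patch extends outside the image bounds")
    return _patch_features(image.pixels[r0:r1, c0:c1].astype(np.float64))


def _patch_features(patch: np.ndarray) -> np.ndarray:
    means = patch.mean(axis=(0, 1))
    sds = patch.std(axis=(0, 1))
    hue, sat, intensity = rgb_to_hsi(patch)
    # circular hue mean, weighted by saturation so gray pixels don't vote
    weight = np.maximum(sat, 1e-12)
    ang = 2.0 * np.pi * hue
    hue_cos = float((np.cos(ang) * weight).sum() / weight.sum())
    hue_sin = float((np.sin(ang) * weight).sum() / weight.sum())

    gray = intensity
    gy, gx = np.gradient(gray)
    grad_energy = float(np.mean(gx * gx + gy * gy))

    hist, _ = np.histogram(gray, bins=32, range=(0.0, 255.0))
    p = hist / max(1, hist.sum())
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())

    # fraction of pixels darker than the patch mean by > 1 sd: granule load
    sd_gray = gray.std()
    granule = float((gray < gray.mean() - sd_gray).mean()) if sd_gray > 0 else 0.0

    return np.array([*means, *sds, hue_cos, hue_sin, float(sat.mean()),
                     float(gray.mean()), grad_energy, entropy, granule])


def sample_training_patches(
    example: TrainingExample,
    patch_size: int,
    n_patches: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample patch centers inside the annotation; return the feature rows."""
    poly = example.annotation.polygon
    h, w = example.image.shape
    half = patch_size // 2
    minx, miny, maxx, maxy = poly.bounds
    feats = []
    attempts = 0
    max_attempts = 200 * n_patches
    while len(feats) < n_patches and attempts < max_attempts:
        attempts += 1
        x = rng.uniform(max(minx, half), min(maxx, w - half))
        y = rng.uniform(max(miny, half), min(maxy, h - half))
        if not shapely.contains_xy(poly, x, y):
            continue
        r, c = int(y), int(x)
        if r - half < 0 or c - half < 0 or r + half >= h or c + half >= w:
            continue
        feats.append(extract_features(example.image, (r, c), patch_size))
    if len(feats) < n_patches:
        raise ValueError(
            f"could only place {len(feats)}/{n_patches} patches inside "
            f"annotation {example.annotation.label!r}"
        )
    return np.vstack(feats)


def train(
    training: list[TrainingExample],
    seed: int,
    patch_size: int = 32,
    n_patches_per_region: int = 200,
) -> ClassifierModel:
    """Fit the patch classifier on annotated regions.

    Deterministic given the seed; requires both tissue classes to be
    represented.
    """
    classes = sorted({ex.tissue_class for ex in training})
    if len(classes) < 2:
        raise ValueError("training set must contain both tissue classes")
    rng = np.random.default_rng(seed)
    xs, ys, regions = [], [], []
    for ex in training:
        feats = sample_training_patches(ex, patch_size, n_patches_per_region, rng)
        xs.append(feats)
        ys.extend([ex.tissue_class] * len(feats))
        regions.append((ex.image.content_hash(), ex.annotation.polygon))
    forest = RandomForestClassifier(
        n_estimators=100, random_state=int(seed) % (2**31), n_jobs=1
    )
    x, y = np.vstack(xs), np.asarray(ys)
    forest.fit(x, y)
    return ClassifierModel(
        forest=forest,
        patch_size=patch_size,
        seed=seed,
        classes=tuple(classes),
        training_accuracy=float((forest.predict(x) == y).mean()),
        training_regions=regions,
    )


def predict_map(
    model: ClassifierModel,
    image: CalibratedImage,
    roi_mask: np.ndarray,
) -> dict:
    """Dense class map over the ROI via sliding patches and majority vote.

    Patches slide with stride = patch_size / 2; each ROI pixel takes the
    majority class of the patches covering it. Returns the per-pixel label
    map (necrosis=1, intact=0, outside=-1), the necrosis fraction of the
    covered ROI, and the necrosis area in um^2.
    """
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != image.shape:
        raise ValueError("ROI mask shape does not match the image")
    h, w = image.shape
    ps = model.patch_size
    stride = max(1, ps // 2)
    rows_any, cols_any = np.nonzero(roi_mask)
    if rows_any.size == 0:
        raise ValueError("empty ROI")
    r_min, r_max = rows_any.min(), rows_any.max()
    c_min, c_max = cols_any.min(), cols_any.max()
    if (r_max - r_min + 1) < ps or (c_max - c_min + 1) < ps:
        raise ValueError("ROI is smaller than one patch")

    r_starts = list(range(r_min, r_max - ps + 2, stride))
    c_starts = list(range(c_min, c_max - ps + 2, stride))
    if r_starts[-1] != r_max - ps + 1:
        r_starts.append(r_max - ps + 1)
    if c_starts[-1] != c_max - ps + 1:
        c_starts.append(c_max - ps + 1)

    # classify only patches that actually overlap the ROI
    feats, spans = [], []
    px = image.pixels.astype(np.float64)
    for r0 in r_starts:
        for c0 in c_starts:
            if not roi_mask[r0:r0 + ps, c0:c0 + ps].any():
                continue
            feats.append(_patch_features(px[r0:r0 + ps, c0:c0 + ps]))
            spans.append((r0, c0))
    pred = model.forest.predict(np.vstack(feats))
    necrosis_idx = (pred == NECROSIS).astype(np.int32)

    votes_pos = np.zeros((h, w), dtype=np.int32)
    votes_all = np.zeros((h, w), dtype=np.int32)
    for (r0, c0), is_nec in zip(spans, necrosis_idx):
        votes_all[r0:r0 + ps, c0:c0 + ps] += 1
        if is_nec:
            votes_pos[r0:r0 + ps, c0:c0 + ps] += 1

    covered = roi_mask & (votes_all > 0)
    labels = np.full((h, w), -1, dtype=np.int8)
    necrotic = covered & (2 * votes_pos > votes_all)
    labels[covered] = 0
    labels[necrotic] = 1

    n_cov = int(covered.sum())
    n_nec = int(necrotic.sum())
    return {
        "labels": labels,
        "necrosis_fraction": (n_nec / n_cov) if n_cov else 0.0,
        "necrosis_area_um2": n_nec * image.mpp**2,
        "covered_px": n_cov,
    }


def _overlaps_training(model: ClassifierModel, image: CalibratedImage,
                       region: RegionAnnotation) -> bool:
    img_hash = image.content_hash()
    poly = region.polygon
    return any(
        h == img_hash and poly.intersects(train_poly)
        for h, train_poly in model.training_regions
    )


def evaluate(
    model: ClassifierModel,
    negative_region: tuple[CalibratedImage, RegionAnnotation, np.ndarray],
    positive_region: tuple[CalibratedImage, RegionAnnotation, np.ndarray],
) -> ClassifierEval:
    """FPR on an all-intact region and PRR on an all-necrotic region.

    Each region is (image, annotation, roi_mask); the annotation is checked
    against the model's training registry and evaluation refuses regions
    overlapping training material (leakage guard).
    """
    for image, region, _ in (negative_region, positive_region):
        if _overlaps_training(model, image, region):
            raise ValueError(
                f"evaluation region {region.label!r} overlaps a training region"
            )
    neg_img, _, neg_mask = negative_region
    pos_img, _, pos_mask = positive_region
    fpr = 100.0 * predict_map(model, neg_img, neg_mask)["necrosis_fraction"]
    prr = 100.0 * predict_map(model, pos_img, pos_mask)["necrosis_fraction"]
    return ClassifierEval(fpr=fpr, prr=prr)
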