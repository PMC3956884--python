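"""Shared fixtures: small, cheap synthetic material built at test time."""

from __future__ import annotations

import numpy as np
import pytest
from skimage import draw as skdraw

from histoquant import palettes
from histoquant.image_model import CalibratedImage


def make_dab_image(
    centers: list[tuple[float, float]],
    radii: list[float],
    shape: tuple[int, int] = (128, 128),
    mpp: float = 1.0,
    noise: float = 0.0,
    seed: int = 0,
) -> CalibratedImage:
    """DAB-brown disks on the pale blue counterstain; a minimal IHC raster."""
    canvas = np.empty((*shape, 3), dtype=np.float64)
    canvas[:] = palettes.IHC_COUNTERSTAIN
    for (r, c), rad in zip(centers, radii):
        rr, cc = skdraw.disk((r, c), rad, shape=shape)
        canvas[rr, cc] = palettes.DAB_BROWN
    if noise > 0:
        rng = np.random.default_rng(seed)
        canvas = canvas + rng.normal(0, noise, canvas.shape)
    return CalibratedImage(
        pixels=np.clip(np.rint(canvas), 0, 255).astype(np.uint8), mpp=mpp
    )


@pytest.fixture(scope="session")
def trained_necrosis_model():
    """One classifier trained on dedicated scenes, shared across tests."""
    from histoquant.classifier import (INTACT, NECROSIS, TrainingExample,
                                       train)
    from histoquant.image_model import RegionAnnotation
    from histoquant.synthetic import SceneParams, make_scene

    pos = make_scene(
        SceneParams(scenario="cv_necrosis", width_px=320, height_px=320,
                    mpp=1.0, necrosis_fraction=0.5,
                    necrosis_blob_scale_px=45.0),
        seed=9001,
    )
    neg = make_scene(
        SceneParams(scenario="cv_necrosis", width_px=320, height_px=320,
                    mpp=1.0, necrosis_fraction=0.0),
        seed=9002,
    )
    h, w = neg.image.shape
    intact_roi = RegionAnnotation(
        vertices=((2, 2), (w - 2, 2), (w - 2, h - 2), (2, h - 2)),
        label="intact_training",
    )
    examples = [TrainingExample(pos.image, ann, NECROSIS)
                for ann in pos.manual_proxies]
    examples.append(TrainingExample(neg.image, intact_roi, INTACT))
    model = train(examples, seed=42)
    return model, pos, neg
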