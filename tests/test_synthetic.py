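"""Generator contracts: determinism, ground-truth geometry, color windows."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from histoquant.image_model import rasterize_roi, rgb_to_hsi
from histoquant.ppc import circular_hue_distance
from histoquant.synthetic import (
    SceneParams,
    make_cv_necrosis_scene,
    make_hemorrhage_scene,
    make_ihc_scene,
    make_scene,
    make_silver_scene,
)


@pytest.mark.parametrize("scenario, kwargs", [
    ("cv_necrosis", {"necrosis_fraction": 0.3}),
    ("hemorrhage", {"hemorrhage_fraction": 0.01}),
    ("ihc_microglia", {"n_cells": 8}),
    ("silver", {"concentration_factor": 3.0}),
])
def test_determinism_bit_identical(scenario, kwargs):
    """(params, seed) -> scene is a pure function."""
    p = SceneParams(scenario=scenario, width_px=160, height_px=160,
                    mpp=2.0 if scenario == "silver" else 1.0, **kwargs)
    a = make_scene(p, 17)
    b = make_scene(p, 17)
    assert np.array_equal(a.image.pixels, b.image.pixels)
    for name in a.truth_masks:
        assert np.array_equal(a.truth_masks[name], b.truth_masks[name])
    assert [x.vertices for x in a.manual_proxies] == \
           [x.vertices for x in b.manual_proxies]


class TestNecrosisScenes:
    def test_zero_fraction_is_a_negative_control(self):
        p = SceneParams(scenario="cv_necrosis", width_px=128, height_px=128,
                        necrosis_fraction=0.0)
        scene = make_cv_necrosis_scene(p, 1)
        assert not scene.truth_masks["necrosis"].any()
        assert scene.manual_proxies == []

    def test_requested_fraction_is_hit(self):
        p = SceneParams(scenario="cv_necrosis", width_px=256, height_px=256,
                        necrosis_fraction=0.3, necrosis_blob_scale_px=40.0)
        scene = make_cv_necrosis_scene(p, 7)
        frac = scene.truth_masks["necrosis"].mean()
        assert 0.28 <= frac <= 0.32

    def test_overfull_fraction_rejected(self):
        p = SceneParams(scenario="cv_necrosis", necrosis_fraction=0.97)
        with pytest.raises(ValueError):
            make_cv_necrosis_scene(p, 0)

    def test_regions_differ_in_color_and_texture(self):
        """Necrotic tissue is paler and texturally sparser than intact;
        the margin must exceed the additive noise amplitude."""
        p = SceneParams(scenario="cv_necrosis", width_px=256, height_px=256,
                        necrosis_fraction=0.4, necrosis_blob_scale_px=40.0)
        scene = make_cv_necrosis_scene(p, 3)
        mask = scene.truth_masks["necrosis"]
        # erode both regions so boundary pixels don't blur the contrast
        core_nec = ndi.binary_erosion(mask, iterations=3)
        core_int = ndi.binary_erosion(~mask, iterations=3)
        px = scene.image.pixels.astype(float)
        mean_gap = np.abs(px[core_nec].mean(axis=0) - px[core_int].mean(axis=0))
        assert mean_gap.max() > p.noise_amplitude * 3
        sd_nec = px[core_nec].std(axis=0).mean()
        sd_int = px[core_int].std(axis=0).mean()
        assert sd_int > 1.5 * sd_nec  # dense Nissl granules vs sparse remnants


class TestHemorrhageScenes:
    def test_solid_blob_limit_proxy_matches_truth(self):
        p = SceneParams(scenario="hemorrhage", width_px=256, height_px=256,
                        hemorrhage_fraction=0.01, n_clumps=2, gap_scale=0.0)
        scene = make_hemorrhage_scene(p, 5)
        truth = scene.truth_area_um2("hemorrhage_rbc")
        proxy = scene.proxy_area_um2()
        assert proxy == pytest.approx(truth, rel=0.05)
        assert proxy >= truth

    def test_gaps_make_proxy_strictly_larger(self):
        p = SceneParams(scenario="hemorrhage", width_px=256, height_px=256,
                        hemorrhage_fraction=0.01, n_clumps=2, gap_scale=1.5)
        scene = make_hemorrhage_scene(p, 5)
        assert scene.proxy_area_um2() > 1.2 * scene.truth_area_um2("hemorrhage_rbc")

    def test_study_regime_pixel_budget(self):
        """At the whole-hemisphere bleed fraction, red pixels land within
        10% of fraction x frame size."""
        p = SceneParams(scenario="hemorrhage", width_px=2000, height_px=1500,
                        hemorrhage_fraction=0.001354, n_clumps=6)
        scene = make_hemorrhage_scene(p, 11)
        target = 0.001354 * 2000 * 1500
        assert abs(scene.truth_masks["hemorrhage_rbc"].sum() - target) <= 0.1 * target

    def test_two_clumps_of_ten_blobs_give_two_proxies(self):
        p = SceneParams(scenario="hemorrhage", width_px=256, height_px=256,
                        hemorrhage_fraction=0.005, n_clumps=2,
                        n_blobs_per_clump=10)
        scene = make_hemorrhage_scene(p, 2)
        assert len(scene.manual_proxies) == 2

    def test_hue_geometry_of_truth_and_background(self):
        """Red cells sit inside the 0.1 +- 0.3 hue window above the 0.04
        saturation gate; the counterstain occupies the opposite half."""
        p = SceneParams(scenario="hemorrhage", width_px=256, height_px=256,
                        hemorrhage_fraction=0.01, n_clumps=3)
        scene = make_hemorrhage_scene(p, 9)
        hue, sat, _ = rgb_to_hsi(scene.image.pixels)
        truth = scene.truth_masks["hemorrhage_rbc"]
        assert (circular_hue_distance(hue[truth], 0.1) <= 0.3).all()
        assert (sat[truth] > 0.04).all()
        bg = ~ndi.binary_dilation(truth, iterations=2)
        bg_dist = circular_hue_distance(hue[bg], 0.1)
        assert np.quantile(bg_dist, 0.001) > 0.3

    def test_fraction_above_regime_rejected(self):
        p = SceneParams(scenario="hemorrhage", hemorrhage_fraction=0.04)
        with pytest.raises(ValueError):
            make_hemorrhage_scene(
                SceneParams(scenario="hemorrhage", hemorrhage_fraction=0.06), 0)
        make_hemorrhage_scene(p, 0)  # 4% is still in range


class TestIhcScenes:
    def test_component_count_matches_cell_count(self):
        p = SceneParams(scenario="ihc_microglia", width_px=256, height_px=256,
                        n_cells=12)
        scene = make_ihc_scene(p, 4)
        _, n = ndi.label(scene.truth_masks["cell_nuclei"])
        assert n == 12
        assert len(scene.extras["cells"]) == 12

    def test_zero_cells_is_a_valid_scene(self):
        p = SceneParams(scenario="ihc_microglia", width_px=128, height_px=128,
                        n_cells=0)
        scene = make_ihc_scene(p, 0)
        assert not scene.truth_masks["cell_nuclei"].any()

    @pytest.mark.parametrize("morphology, lo, hi", [
        ("bushy", 40.0, np.inf),  # cortex morphology exceeds the 40 um^2 cut
        ("amoeboid", 25.0, 40.0),  # peduncle morphology between 25 and 40
    ])
    def test_soma_area_distributions_straddle_the_size_cuts(
            self, morphology, lo, hi):
        p = SceneParams(scenario="ihc_microglia", width_px=320, height_px=320,
                        n_cells=20, morphology=morphology)
        scene = make_ihc_scene(p, 8)
        median = np.median([c["area_um2"] for c in scene.extras["cells"]])
        assert lo <= median < hi

    def test_infeasible_packing_errors(self):
        p = SceneParams(scenario="ihc_microglia", width_px=96, height_px=96,
                        n_cells=60)
        with pytest.raises(ValueError, match="pack"):
            make_ihc_scene(p, 0)


class TestSilverScenes:
    def test_uniform_limit_subregion_matches_whole(self):
        p = SceneParams(scenario="silver", width_px=600, height_px=450,
                        mpp=2.0, concentration_factor=1.0)
        scene = make_silver_scene(p, 5)
        dep = scene.truth_masks["silver_deposit"]
        roi = rasterize_roi(scene.extras["roi"], scene.image)
        sub = rasterize_roi(scene.extras["subregion"], scene.image)
        assert dep[sub].mean() == pytest.approx(dep[roi].mean(), rel=0.10)

    def test_concentrated_subregion_dominates(self):
        p = SceneParams(scenario="silver", width_px=800, height_px=600,
                        mpp=2.0, concentration_factor=5.0,
                        deposit_density=0.004)
        scene = make_silver_scene(p, 6)
        dep = scene.truth_masks["silver_deposit"]
        roi = rasterize_roi(scene.extras["roi"], scene.image)
        sub = rasterize_roi(scene.extras["subregion"], scene.image)
        assert dep[sub].mean() >= 4.0 * dep[roi].mean()

    def test_deposits_are_achromatic(self):
        # palette contract: exactly equal-RGB without noise, near-equal with
        clean = make_silver_scene(SceneParams(
            scenario="silver", width_px=300, height_px=300, mpp=2.0,
            noise_amplitude=0.0), 7)
        px = clean.image.pixels[clean.truth_masks["silver_deposit"]].astype(float)
        assert np.abs(px / px.sum(axis=1, keepdims=True) - 1 / 3).max() <= 0.02
        noisy = make_silver_scene(SceneParams(
            scenario="silver", width_px=300, height_px=300, mpp=2.0), 7)
        px = noisy.image.pixels[noisy.truth_masks["silver_deposit"]].astype(float)
        chroma_dev = np.abs(px / px.sum(axis=1, keepdims=True) - 1 / 3)
        assert chroma_dev.mean() <= 0.02

    def test_zero_density_gives_empty_truth(self):
        p = SceneParams(scenario="silver", width_px=200, height_px=200,
                        mpp=2.0, deposit_density=0.0)
        scene = make_silver_scene(p, 0)
        assert not scene.truth_masks["silver_deposit"].any()

    def test_subregion_outside_roi_rejected(self):
        p = SceneParams(scenario="silver", width_px=300, height_px=300,
                        mpp=2.0, subregion_origin_px=(280, 280))
        with pytest.raises(ValueError, match="subregion"):
            make_silver_scene(p, 0)


def test_scene_write_roundtrip(tmp_path):
    from histoquant.image_model import read_geojson, read_tiff

    p = SceneParams(scenario="hemorrhage", width_px=96, height_px=96,
                    hemorrhage_fraction=0.01, n_clumps=1)
    scene = make_scene(p, 3)
    scene.write(tmp_path, stem="s")
    back = read_tiff(tmp_path / "s.tif")
    assert np.array_equal(back.pixels, scene.image.pixels)
    assert back.mpp == scene.image.mpp
    proxies = read_geojson(tmp_path / "s.proxies.geojson")
    assert len(proxies) == len(scene.manual_proxies)
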