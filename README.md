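# histoquant

Whole-slide-style quantitation of brain-injury histology, with the
validation machinery needed to trust it: seeded synthetic stained-tissue
scenes with pixel-level ground truth, plus Pearson / Bland-Altman agreement
between automated and manual-style measurements.

## The problem

Quantifying necrosis, micro-hemorrhage, microglial density, and neuronal
degeneration on stained brain sections by hand is slow and
observer-dependent. Digital-slide algorithms promise objective,
high-throughput measurements — but each algorithm has parameters (hue
windows, stain vectors, size and shape filters) whose miscalibration can
silently bias results, and the agreement between automated and manual
readings depends on what exactly each method measures. This package
implements the four standard quantitation algorithms, and a synthetic-data
harness that encodes the mechanisms behind their known failure modes, so
that every pipeline stage can be validated against known ground truth.

## The algorithms

- **Positive pixel counting** (`histoquant.ppc`): a pixel is positive when
  its hue *h* (circular, red = 0) satisfies *d*(h, h₀) ≤ w/2 and its
  saturation *s* = 1 − min(R,G,B)/mean(R,G,B) clears a low gate; positives
  are sub-classed weak/medium/strong by mean intensity. Defaults h₀ = 0.1,
  w = 0.6, s ≥ 0.04 — the settings validated for red micro-hemorrhage on a
  violet counterstain, where the counterstain sits on the opposite half of
  the hue circle.
- **Color deconvolution** (`histoquant.deconvolution`): per-channel optical
  density OD*_c* = −log₁₀(max(I*_c*, 1)/255) mixes linearly over stains,
  OD = **M** c with **M** the unit stain-vector matrix (silver =
  (0.24, 0.24, 0.24) normalized); inverting **M** recovers concentrations,
  quantified as %Pos and OD × %Pos.
- **Nuclear morphometry** (`histoquant.morphometry`): DAB-channel
  deconvolution → Gaussian pre-smoothing → threshold → curvature-governed
  watershed splitting → filtering by minimum nuclear size and elongation
  (minor/major ellipse-axis ratio). Region presets: cortex
  {40 µm², 0.2, curvature 2.5} and cerebral peduncle {25 µm², 0.2, 2.5}.
  Cell density = n / (ROI area × 40 µm section thickness), in cells/mm³.
- **Region classifier** (`histoquant.classifier`): patch color + texture
  features feeding a seeded random forest; trained on annotated regions,
  scored by false-positive rate on intact tissue and positive recognition
  rate on necrotic tissue, with a train/test leakage guard.
- **Agreement statistics** (`histoquant.agreement`): Pearson r (two-sided
  t-transform p, n−2 df) and Bland-Altman mean difference with
  ±1.96 SD limits of agreement (SD with n−1 denominator); differences are
  always manual − automated.

Four synthetic scenarios (`histoquant.synthetic`) emulate the stained
material: cresyl-violet cortex with pale necrotic patches, clumped red-cell
micro-hemorrhages whose manual-outline proxies include the gaps between
cell clusters, DAB-labeled microglial somata in bushy vs amoeboid
morphologies, and gray silver deposits concentrated in a rostral subregion.

## Worked example

Five synthetic micro-hemorrhage fields with increasing bleed load,
quantified by positive pixel counting and compared with the hand-outline
proxy annotations:

```python
import numpy as np
from histoquant import (SceneParams, make_scene, PPCParams, classify_pixels,
                        summarize_ppc, PairedMeasurements, bland_altman)

manual, automated = [], []
for seed, frac in enumerate((0.004, 0.008, 0.012, 0.020, 0.030)):
    params = SceneParams(scenario="hemorrhage", width_px=256, height_px=256,
                         mpp=0.5, hemorrhage_fraction=frac, n_clumps=3,
                         gap_scale=1.0)
    scene = make_scene(params, seed)
    roi = np.ones(scene.image.shape, dtype=bool)
    summary = summarize_ppc(classify_pixels(scene.image, roi, PPCParams()))
    manual.append(scene.proxy_area_um2())
    automated.append(summary["positive_area_um2"])
    print(f"section {seed}: manual {manual[-1]:8.1f} um^2   "
          f"automated {automated[-1]:8.1f} um^2")

report = bland_altman(PairedMeasurements(np.array(manual),
                                         np.array(automated), unit="um^2"))
print(f"Pearson r = {report.pearson_r:.3f}   "
      f"mean difference = {report.mean_diff:.1f} um^2   "
      f"limits of agreement = [{report.loa_low:.1f}, {report.loa_high:.1f}]")
```

Output:

```
section 0: manual    341.3 um^2   automated     55.0 um^2
section 1: manual   1176.9 um^2   automated    133.8 um^2
section 2: manual   2191.7 um^2   automated    206.8 um^2
section 3: manual   3074.1 um^2   automated    323.0 um^2
section 4: manual   6044.5 um^2   automated    491.5 um^2
Pearson r = 0.990   mean difference = 2323.7 um^2   limits of agreement = [-1659.0, 6306.5]
```

The two methods rank sections almost identically (r = 0.990) yet disagree
systematically: the manual outlines span the gaps between red-cell
clusters, so the automated pixel-exact area always reads lower — high
correlation, poor absolute agreement, which is exactly the distinction
Bland-Altman analysis exists to expose.

The same machinery is available from the shell:

```bash
histoquant generate --scenario hemorrhage --seed 4 --out scene_dir
histoquant ppc --image scene_dir/scene.tif --out ppc.csv
histoquant run --config study.yaml --out run_dir   # full study replication
```

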