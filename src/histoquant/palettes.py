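"""Fixed stain palettes used by the synthetic scene generators.

Downstream thresholds (hue windows, stain vectors, positivity cutoffs) are
color-dependent, so these RGB constants are part of the package's test
contract rather than incidental rendering choices. They are plausible
brightfield values chosen for the right hue-wheel geometry:

* cresyl-violet tissue sits on the blue/violet half of the hue circle,
  opposite the red of extravasated red blood cells, which is what makes a
  low saturation gate safe for hemorrhage counting;
* DAB brown and the pale blue counterstain have well-separated OD vectors;
* silver deposits are near-achromatic (equal RGB), separable from a tinted
  counterstain by OD-space deconvolution rather than by hue.
"""

from __future__ import annotations

import numpy as np

from .image_model import rgb_to_od

# --- cresyl violet (Nissl) scenes ------------------------------------------
CV_VIOLET_BG = (178, 150, 224)  # pale violet wash of intact tissue
CV_NISSL_GRANULE = (105, 62, 168)  # dense Nissl-body violet
NECROSIS_BG = (233, 213, 220)  # pale pink necrotic wash
NECROSIS_GRANULE = (205, 172, 186)  # faint shrunken-cell remnants

# --- hemorrhage -------------------------------------------------------------
RBC_RED = (198, 60, 68)  # extravasated red blood cells

# --- Iba-1 immunohistochemistry ---------------------------------------------
DAB_BROWN = (118, 72, 46)  # DAB chromogen in labeled somata
IHC_COUNTERSTAIN = (206, 211, 237)  # pale blue nuclear counterstain

# --- silver degeneration stain ----------------------------------------------
SILVER_GRAY = (82, 82, 82)  # argyrophilic deposit (equal-RGB gray)
SILVER_BG = (222, 190, 238)  # pale violet counterstained background


def _unit_od(rgb: tuple[int, int, int]) -> np.ndarray:
    od = rgb_to_od(np.asarray(rgb, dtype=float))
    return od / np.linalg.norm(od)


#: the study's silver-stain OD vector, normalized to unit length
SILVER_OD_RAW = (0.24, 0.24, 0.24)
SILVER_OD = np.asarray(SILVER_OD_RAW) / np.linalg.norm(SILVER_OD_RAW)
#: default counterstain OD vector (violet background palette)
COUNTERSTAIN_OD = _unit_od(SILVER_BG)
#: DAB OD vector derived from the brown palette entry
DAB_OD = _unit_od(DAB_BROWN)
#: pale blue IHC counterstain OD vector
IHC_COUNTERSTAIN_OD = _unit_od(IHC_COUNTERSTAIN)
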