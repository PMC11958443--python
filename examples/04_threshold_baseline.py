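"""Classical thresholding baseline on a noiseless synthetic pupil scene.

Generates a well-separated scene, detects the pupil and CR by binarization +
center of mass, and compares against the generator's ground-truth labels.
"""

import math

import numpy as np

from leyes.baseline import ThresholdConfig, threshold_detect
from leyes.pipelines import HighResPupilConfig, gen_pupil_scene

cfg = HighResPupilConfig.for_variant(
    "500", stage=2, noise_range=(0.0, 0.0), cr_clear_of_pupil=True,
    pupil_minor_range=(20.0, 40.0), cr_margin=15.0, iris_lum=(100.0, 179.0),
)
scene = gen_pupil_scene(cfg, np.random.default_rng(11))
l_p, l_i = scene.params["L_p"], scene.params["L_i"]
det = threshold_detect(scene.image.pixels, ThresholdConfig(
    pupil_threshold=(l_p + l_i) / 2.0,
    cr_threshold=(l_i + 255.0) / 2.0,
    relative_location_factor=None,
))

px, py = scene.pupil_center
cr = scene.cr_labels[0]
print(f"pupil label ({px:.3f}, {py:.3f}), detected "
      f"({det.pupil_center[0]:.3f}, {det.pupil_center[1]:.3f}), error "
      f"{math.hypot(det.pupil_center[0] - px, det.pupil_center[1] - py):.3f} px")
print(f"CR    label ({cr.x:.3f}, {cr.y:.3f}), detected "
      f"({det.cr_center[0]:.3f}, {det.cr_center[1]:.3f}), error "
      f"{math.hypot(det.cr_center[0] - cr.x, det.cr_center[1] - cr.y):.3f} px")
# Center-of-mass detection on clean, well-separated blobs is accurate to a
# fraction of a pixel; this is the reference method the CNN demo improves on
# in noisy conditions.
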