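"""Grid search for the thresholding baseline's fixed thresholds.

On real recordings the pupil/CR thresholds are tuned per participant by
choosing the values that give the most precise (lowest RMS-S2S) center
signals.  This script mirrors that procedure on synthetic frames: it
generates a short "recording" (a fixed scene geometry redrawn with fresh
noise), sweeps pupil and CR thresholds, and reports the pair minimizing the
combined RMS-S2S of the detected center signals.
"""

import numpy as np

from leyes.baseline import ThresholdConfig, threshold_detect
from leyes.metrics import TimedSignal, rms_s2s
from leyes.render import compose_scene
from leyes.pipelines import HighResPupilConfig, gen_pupil_scene

# one scene geometry, re-rendered with fresh noise per "frame"
cfg = HighResPupilConfig.for_variant(
    "500", stage=2, cr_clear_of_pupil=True, pupil_minor_range=(20.0, 40.0),
    cr_margin=15.0, iris_lum=(100.0, 179.0), noise_range=(8.0, 8.0),
)
scene = gen_pupil_scene(cfg, np.random.default_rng(5))
spec = scene.params["scene"]
n_frames, fs = 150, 500.0
frames = [compose_scene(spec, seed).pixels for seed in range(n_frames)]

best = None
for pupil_th in (30.0, 50.0, 70.0, 90.0):
    for cr_th in (180.0, 200.0, 220.0, 240.0):
        tc = ThresholdConfig(pupil_threshold=pupil_th, cr_threshold=cr_th,
                             relative_location_factor=None)
        pupil_xy, cr_xy = [], []
        for f in frames:
            det = threshold_detect(f, tc)
            pupil_xy.append(det.pupil_center or (np.nan, np.nan))
            cr_xy.append(det.cr_center or (np.nan, np.nan))
        t = np.arange(n_frames) / fs
        try:
            score = (
                rms_s2s(TimedSignal(t=t, xy=np.array(pupil_xy), fs=fs))
                + rms_s2s(TimedSignal(t=t, xy=np.array(cr_xy), fs=fs))
            )
        except ValueError:
            continue
        if best is None or score < best[0]:
            best = (score, pupil_th, cr_th)
        print(f"pupil_th={pupil_th:5.1f} cr_th={cr_th:5.1f} -> "
              f"combined RMS-S2S {score:.3f} px")

print(f"\nbest thresholds: pupil {best[1]:.0f}, CR {best[2]:.0f} "
      f"(combined RMS-S2S {best[0]:.3f} px)")
# Lower combined RMS-S2S means steadier frame-to-frame centers; the winning
# thresholds sit between the pupil/iris and iris/CR luminance levels.
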