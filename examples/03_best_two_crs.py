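"""Best-two CR selection and frame validity from model heatmaps.

Simulates per-identity heatmaps for a five-CR constellation frame where two
CRs dropped out, then runs peak extraction, selection, and the validity rule.
"""

import numpy as np

from leyes.postprocess import check_validity, extract_peaks, select_best_two

rng = np.random.default_rng(0)
true_positions = {0: (40, 30), 1: (70, 35), 3: (75, 80)}  # ids 2, 4 dropped
maps = []
for identity in range(5):
    m = rng.normal(0.0, 0.05, size=(128, 128))
    if identity in true_positions:
        x, y = true_positions[identity]
        m[y, x] = rng.uniform(1.5, 4.0)  # confident detection
    maps.append(m)

peaks = extract_peaks(maps)
print("per-identity max logits:", [f"{p.value:.2f}" for p in peaks.peaks])
best = select_best_two(peaks)
for identity, peak in best:
    print(f"selected CR {identity} at ({peak.x}, {peak.y}), "
          f"logit {peak.value:.2f}")
print("frame valid (>=2 logits >= 1):", check_validity(peaks))
# The two illuminators the model is most confident about are kept; frames
# without two confident CRs (e.g., blinks) are excluded from gaze estimation.
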