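"""Quantify mitochondrial clusters in simulated equatorial-section images.

The aggregated pattern (few large clusters, ~66/section of ~4.7 µm²) marks
phases of high ATP production; the dispersed pattern (many small clusters,
~102/section of ~2.6 µm²) marks low-production phases.  Quantification is
Otsu thresholding, 8-connected labeling, and a 0.2 µm² minimum-particle
filter (the area of a single mitochondrion).
"""

import numpy as np

from mitopulse import classify_pattern, label_clusters, threshold_image
from mitopulse.simulate import simulate_image_preset
from mitopulse.stats import unpaired_t_test

areas = {}
for preset in ("aggregated", "dispersed"):
    img, labels, truth = simulate_image_preset(preset, seed=1)
    mask = threshold_image(img, "otsu")
    cs = label_clusters(mask, img.pixel_size_um, min_area_um2=0.2)
    s = cs.summary
    print(
        f"{preset:10s}: {s['n_clusters']} clusters, "
        f"mean area {s['mean_area_um2']:.2f} ± {s['sem_area_um2']:.2f} µm², "
        f"pattern -> {classify_pattern(s)} (ground truth: {len(truth)} clusters)"
    )
    areas[preset] = cs.areas_um2

res = unpaired_t_test(areas["aggregated"], areas["dispersed"])
print(f"aggregated vs dispersed cluster areas: t={res['t']:.2f}, p={res['p']:.2g}")
# The two regimes separate cleanly (p << 0.01), matching the contrast between
# high- and low-ATP phases of maturation.
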