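"""Score peri-nuclear rings and run a small end-to-end experiment.

At germinal-vesicle breakdown, mitochondria translocate into a dense ring
around the nuclear area.  The ring score is the mean intensity of an annulus
at the nuclear boundary divided by the mean cytoplasmic intensity; a score
>= 1.5 calls the ring present.  run_experiment chains simulation, analysis
and cohort summaries for several arms from one seed.
"""

import numpy as np

from mitopulse import ring_score
from mitopulse.simulate import simulate_image_preset
from mitopulse.stats import run_experiment

for preset in ("gvbd_ring", "dispersed"):
    img, _, _ = simulate_image_preset(preset, seed=3)
    cy, cx = img.meta["cell_center_px"]
    yy, xx = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
    cell = np.hypot(yy - cy, xx - cx) * img.pixel_size_um <= img.meta["cell_radius_um"]
    res = ring_score(img, (cy, cx), r_um=13.0, width_um=5.0, cell_mask=cell)
    print(f"{preset:10s}: ring score {res.score:.2f} -> present={res.present}")

report = run_experiment(
    {
        "seed": 7,
        "trace_arms": [
            {"name": "control", "preset": "maturing", "n": 6},
            {"name": "nocodazole", "preset": "nocodazole", "n": 6},
        ],
        "image_arms": [{"name": "gvbd", "preset": "gvbd_ring", "n": 3}],
    }
)
for name, arm in report["trace_arms"].items():
    print(f"arm {name:10s}: modal pulse count {arm['modal_pulse_count']}")
gvbd = report["image_arms"]["gvbd"]
print(f"arm gvbd      : ring fraction {gvbd['ring_fraction']['fraction']:.2f}, "
      f"mean count {gvbd['mean_count']:.1f}")
# A GVBD-stage arm shows rings in every section; nocodazole halves the pulse count.
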