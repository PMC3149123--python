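"""Compare ATP-pulse phenotypes across treatment cohorts.

Treatments edit the default three-pulse schedule: IBMX keeps oocytes
arrested (no pulses), nocodazole and enucleation block meiosis-I completion
(first two pulses only), and cytochalasin B disrupts microfilaments
(no early pulses; a small third pulse in a minority of oocytes).
"""

from mitopulse import detect_pulses, fit_baseline, summarize_trace
from mitopulse.simulate import simulate_cohort
from mitopulse.stats import summarize_cohort

for preset, n in [("maturing", 10), ("ibmx_arrest", 10), ("nocodazole", 10), ("cytochalasin_b", 12)]:
    summaries = []
    for trace in simulate_cohort(preset, n, base_seed=42):
        fit = fit_baseline(trace)
        summaries.append(summarize_trace(detect_pulses(fit)))
    report = summarize_cohort(summaries)
    inc = report["incidence_any_pulse"]
    print(
        f"{preset:15s} n={report['n']:3d}  modal pulse count={report['modal_pulse_count']}  "
        f"any-pulse incidence={inc['fraction']:.2f} ± {inc['se']:.2f}"
    )
# Modal counts 3 / 0 / 2 / 0 mirror the treatment effects on ATP dynamics.
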