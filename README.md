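# mitopulse

Analysis pipeline for **ATP dynamics and mitochondrial redistribution during
mouse oocyte maturation**, with a synthetic-data generator providing ground
truth for every stage.

Maturing mouse oocytes, released from IBMX arrest, show three discrete bursts
of ATP production — around germinal-vesicle breakdown (~1–2 h), during
spindle migration (~5–7 h), and at the MI→MII transition (~11–12 h) — and, in
parallel, remodel their mitochondria between an *aggregated* pattern (few
large clusters, ~66 per equatorial section of ~4.7 µm²) and a *dispersed*
pattern (many small clusters, ~102 per section of ~2.6 µm²), including a
dense peri-nuclear "mito-ring" at GVBD. `mitopulse` is for researchers who
want to quantify both readouts reproducibly: luminescence traces from
luciferase-injected oocytes, and single-channel equatorial-section images of
mitotracker-style staining.

## The model

**Traces.** Photon counts per 30-s bin are modelled as Poisson draws around a
smooth expression/destruction baseline times a pulse factor:

```
counts_i ~ Poisson( f(t_i) · (1 + Σ_j a_j · rc((t_i − c_j)/w_j)) )

f(t) = b + A · (k/λ) ((t−t0)/λ)^(k−1) exp(−((t−t0)/λ)^k) · Δt      (Weibull)
```

with `rc(x) = ½(1+cos πx)` on |x|<1 a raised-cosine bump, `Δt` the bin width
in hours, and a log-normal alternative for `f`. Analysis inverts this:
`fit_baseline` estimates `(A, k, λ, t0, b)` by bounded nonlinear least
squares, and `detect_pulses` calls pulses as runs of the smoothed
Poisson-scaled residual `z_i = r_i / √max(f̂_i, 1)` that stay above `τ = 2`
for at least 15 min (30-min merge gap, 30-min edge trim).

**Images.** Quantification mirrors the ImageJ threshold → Analyse-Particles
workflow: Otsu (or fixed) global threshold, 8-connected component labeling,
areas in µm² via the pixel size, and a 0.2 µm² minimum-particle filter — the
cross-section of a single mitochondrion (0.5–1 µm diameter → 0.2–0.8 µm²).
Ring formation is scored as annulus-to-cytoplasm mean-intensity ratio
(present at ≥ 1.5); the aggregated/dispersed pattern is classified from the
count/mean-area summary.

## Worked example

```python
from mitopulse import detect_pulses, fit_baseline, summarize_trace
from mitopulse.simulate import TraceSimConfig, simulate_trace

trace = simulate_trace(TraceSimConfig(seed=1))   # maturing preset, 1680 bins
fit = fit_baseline(trace, model="weibull")
for p in detect_pulses(fit):
    print(f"{p.start_h:.2f}-{p.end_h:.2f} h  peak {p.peak_h:.2f} h  z={p.peak_z:.1f}")
print(summarize_trace(detect_pulses(fit))["classification"])
```

prints

```
1.32-1.71 h  peak 1.48 h  z=3.0
5.57-6.51 h  peak 5.97 h  z=5.0
11.22-11.76 h  peak 11.45 h  z=4.3
maturing-like
```

— three pulses at the scheduled GVBD / spindle-migration / MI→MII times, so
the trace is classified as a fully maturing oocyte. The `examples/`
directory has one narrative script per capability (pulse detection,
treatment cohorts, cluster quantification, ring scoring and the experiment
runner); each prints what it computes and what the numbers mean.

A thin CLI wraps the same functions:

```bash
mitopulse simulate-trace --preset maturing --seed 1 --out trace.csv
mitopulse analyze-trace trace.csv --model weibull --out result.json
mitopulse simulate-image --preset aggregated --seed 1 --out section.tif
mitopulse quantify-image section.tif --method otsu --min-area 0.2 --out clusters.json
mitopulse run-experiment config.yaml --out report/
```

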