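# Methods

## Trace model and baseline fit

A luciferase-injected oocyte on a photon-counting camera yields counts per
30-s bin over 13–16 h. The slow trend — cRNA translation building luciferase
up, destruction and substrate depletion bringing it down — is modelled as a
scaled Weibull density plus a constant offset:

```
f(t) = b + A · pdf_weibull(t − t0; k, λ) · Δt,    t > t0;  f(t) = b otherwise
```

`A` is the total photon budget of the expression transient (photons), `k`
the dimensionless shape, `λ` the scale in hours, `t0` the onset in hours and
`b` the camera offset in counts/bin. Because `A` is a photon total, the
per-bin expectation carries the bin width `Δt = bin_s/3600` h; with the
defaults (`A = 2×10⁶`, `k = 2.2`, `λ = 9 h`, `t0 = 0`, `b = 50`) the peak
expectation is ≈1.7×10³ counts per 30-s bin, a realistic photon-counting
magnitude. A log-normal transient (`μ`, `σ` replacing `k`, `λ`) is available
through `fit_baseline(..., model="lognormal")`; model choice is left to the
caller — no automatic AIC selection.

The fit is bounded nonlinear least squares (trust-region reflective) from a
moment-based start: `t0 = 0`, `λ` at the time of peak count, `k = 2`,
`A = Σ(counts − min)`, `b = min count`. Parameters are scaled by their
starting magnitudes so the 10⁶-scale amplitude and O(1) shape parameters are
equally conditioned; tolerances are 10⁻¹² so a noiseless model trace refits
to ≲10⁻³ relative error in every parameter (absolute 10⁻³ h for `t0`, which
sits on its lower bound at 0). Non-convergence is reported on the fit object
rather than raised; pulse detection refuses non-converged fits unless forced.

## Pulse detection

ATP bursts appear as supra-baseline excursions of the residuals
`r_i = counts_i − f̂(t_i)`. Because counts span orders of magnitude along a
trace, residuals are normalized on the Poisson scale,
`z_i = r_i / √max(f̂_i, 1)`, not by a global SD. The detector then:

1. smooths `z` with a centered moving average over 21 bins (the configured
   20 is forced odd; ≈10 min), shrinking the per-bin noise ≈4.5-fold;
2. ignores the first and last 30 min, where the baseline fit is least
   constrained;
3. takes maximal runs with smoothed `z > τ` (default `τ = 2`);
4. merges runs separated by ≤30 min (closed interval: a gap of exactly
   30 min merges);
5. keeps runs sustained ≥15 min.

Each pulse reports start/end (outer bin edges), the peak time and smoothed
`z` at the peak, and the integrated residual excess in photons. Merging
before the duration filter means raising `τ` can in principle split a wide
run into two; with the default 30-min gap and the pulse widths simulated
here the pulse count is monotone non-increasing in both `τ` and the minimum
duration, and the tests assert this on simulated traces.

A trace is classified *maturing-like* (≥3 pulses), *partial* (1–2, the
nocodazole/enucleation phenotype) or *arrested-like* (0).

Adding a constant to all counts is absorbed by the free offset `b`, leaving
residuals unchanged; the *calls* are unchanged only while the offset is
small against the local baseline, since `√f̂` normalization deliberately
deflates `z` when the background grows. This is a property of Poisson
scaling, not a defect: a pulse of fixed photon excess genuinely is less
significant on a brighter background.

## Synthetic traces

The generator draws `counts_i ~ Poisson(m(t_i))` with
`m(t) = f(t)·(1 + Σ a_j·rc_j(t))`, where `rc_j` is a raised-cosine bump of
half-width `w_j` and fractional amplitude `a_j` (defaults: centers 1.5, 6.0,
11.5 h; half-widths 0.5, 1.0, 0.5 h; `a = 0.15`). Multiplicative pulses were
chosen because burst size should track the amount of luciferase present; an
additive mode (bump anchored to the baseline value at the pulse center) is
available. Treatment presets edit the schedule: `ibmx_arrest` retains no
pulses; `nocodazole` and `enucleation` retain pulses 1–2; `cytochalasin_b`
removes pulses 1–2 and keeps a ×0.3-attenuated third pulse in a
deterministic `round(n·14/36)` subset of the cohort (drawn from the cohort
seed), reflecting the minority of treated oocytes that keep a small late
burst. At default `τ` the attenuated pulse (≈4.5% excursion) stays below
threshold, so detected incidence is 0 while the ground truth records it.
Per-oocyte seeds are `base_seed + i`; identical configs are bit-identical.

## Synthetic images

A section image is a 768² uint16 raster at 0.1 µm/px holding a circular cell
of radius 35 µm (a mouse oocyte is ~70–80 µm across). Cluster areas are
log-normal with configurable mean and CV 0.5, floored at 0.2 µm²; clusters
are rendered as filled rotated ellipses (axis ratio uniform in [1, 2]) of
the sampled area, placed by rejection sampling uniformly over the cell disc
(or, for ring clusters, uniformly over the configured annulus) with a 1-px
exclusion margin so no two clusters touch even diagonally — the measurement
counts discrete clusters, so overlap is forbidden. Placement failure after
the retry budget raises an error naming the coverage achieved. Foreground
intensity is 20 000 on a uniform background of 2 000 with additive Gaussian
noise (SD 1 000 = 5% of foreground); the background is uniform across the
whole field (a camera/offset floor) rather than darker outside the cell, so
the histogram is bimodal and a global threshold is well posed.

Presets: `aggregated` (66 clusters, mean 4.7 µm²), `dispersed` (102
clusters, 2.6 µm²), `gvbd_ring` (aggregated + 60% of clusters in a 13–18 µm
annulus around a 12-µm nuclear exclusion zone), `cytochalasin` (dispersed;
cortical clefts are not modelled). Cluster counts per section are fixed at
the preset value rather than resampled — the regime means are the study
conditions, and between-section count variation would only dilute them.

What the generator does **not** emulate: optical PSF blur and partial-volume
edges, intra-cluster intensity texture, out-of-focus light, cumulus debris,
uneven illumination, and irregular (non-elliptical) cluster shapes. Passing
tests therefore demonstrate that the measurement chain is correct and
unbiased on well-posed input, not that segmentation is robust to microscope
artefacts; on real data the threshold step is the fragile link and both the
method and value are exposed.

## Image quantification

Thresholding is `pixels > t` with `t` fixed or Otsu's maximizer of
between-class variance on a 256-bin histogram (constant images are an
explicit error). Labeling uses 8-connectivity by default (the ImageJ
Analyse-Particles convention; 4-connectivity available), then drops
components below 0.2 µm² — smaller than one mitochondrion, hence noise.
Border-touching clusters are retained. The ring score divides the mean
intensity of the annulus `[r, r+w]` by the mean of the cytoplasm beyond it
(the nucleus disc inside `r` is excluded); `θ_ring = 1.5` operationalizes
"dense ring present", and the annulus geometry must be supplied (from
simulation ground truth or the caller) — automatic nucleus detection is out
of scope. Pattern classification: aggregated iff mean area > 3.5 µm² and
count < 85; dispersed iff both inequalities reverse; intermediate otherwise
(boundaries included). The cutpoints sit between the two regimes' printed
means and are configurable.

## Cohort statistics

Continuous measures are reported mean ± SEM (`sd/√n`, sample SD); incidence
as a proportion with binomial SE `√(p(1−p)/n)`. Group contrasts use the
two-sided unpaired Student's t-test with pooled variance (Welch behind a
flag); zero variance with equal means returns `t=0, p=1`, with unequal means
it is an error. No multiple-testing correction is applied.
`run_experiment` chains simulate → analyze → summarize per arm with arm
seeds derived deterministically from the master seed, so a report reproduces
bit-exactly from its config.

## Numerical choices and problem sizes

- Detector window forced odd (20 → 21 bins) so the moving average is
  centered; edge bins use shrinking windows.
- Runs separated by exactly the merge gap are merged (closed interval).
- Non-uniform time grids are rejected, not resampled.
- Areas are always `pixel_count · pixel_size_um²`; image computations are in
  float regardless of input dtype.
- Test and acceptance workloads are sized to be comfortable on one CPU:
  pulse-recovery checks use 100 traces per preset (~1 s per 100 fits) and
  cluster-statistic recovery uses 20 images per preset (~2 s per 20), which
  puts Monte-Carlo error well inside the asserted bands.

## Known limitations

- Luminescence is relative; no absolute ATP calibration is attempted.
- The baseline family (Weibull/log-normal) is phenomenological; traces whose
  expression trend departs from both will bias residuals and pulse calls.
- Pulse detection thresholds (`τ`, durations) are an operationalization of a
  judgement historically made by eye from residual plots; the defaults are
  exposed rather than claimed optimal.
- The ring score requires the ring geometry as input.
- Cluster segmentation assigns each connected component one cluster; truly
  touching clusters would be merged (the generator forbids contact, real
  images do not).
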