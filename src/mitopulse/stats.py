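"""Cohort-level statistics and the end-to-end experiment runner.

Summaries follow the reporting conventions of the measurements they
aggregate: continuous quantities as mean ± SEM, incidence as a proportion
with binomial standard error, and group contrasts with an unpaired two-sided
Student's t-test (pooled variance by default, Welch optional).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from mitopulse import images, simulate, traces

__all__ = [
    "GroupSummary",
    "group_summary",
    "proportion_summary",
    "unpaired_t_test",
    "summarize_cohort",
    "quantify_image_arm",
    "run_experiment",
]


@dataclass(frozen=True)
class GroupSummary:
    """Mean ± SEM for one group of measurements."""

    n: int
    mean: float
    sem: float
    values: tuple[float, ...]


def group_summary(values) -> GroupSummary:
    """Summarize a group as mean ± SEM (sd/√n, sample sd)."""
    arr = np.asarray(list(values), dtype=float)
    n = arr.size
    if n < 2:
        raise ValueError("need at least 2 values for a group summary")
    return GroupSummary(
        n=int(n),
        mean=float(arr.mean()),
        sem=float(arr.std(ddof=1) / math.sqrt(n)),
        values=tuple(arr.tolist()),
    )


def proportion_summary(k: int, n: int) -> dict:
    """Incidence fraction with binomial standard error sqrt(p(1-p)/n)."""
    if n < 1 or not (0 <= k <= n):
        raise ValueError("need 0 <= k <= n with n >= 1")
    p = k / n
    return {"k": k, "n": n, "fraction": p, "se": math.sqrt(p * (1 - p) / n)}


def unpaired_t_test(group_a, group_b, welch: bool = False) -> dict:
    """Two-sided unpaired t-test between two groups.

    Student's pooled-variance test by default; set ``welch=True`` for the
    unequal-variance form.  Degenerate zero-variance input with equal means
    returns ``t=0, p=1``; with unequal means it is an error (the statistic
    is undefined).
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            df = a.size + b.size - 2
            return {"t": 0.0, "df": float(df), "p": 1.0}
        raise ValueError("zero variance in both groups with unequal means: t undefined")
    res = sps.ttest_ind(a, b, equal_var=not welch)
    return {"t": float(res.statistic), "df": float(res.df), "p": float(res.pvalue)}


def summarize_cohort(trace_summaries: list[dict]) -> dict:
    """Aggregate per-oocyte pulse summaries into a cohort report.

    Parameters
    ----------
    trace_summaries
        Output of :func:`mitopulse.traces.summarize_trace`, one per oocyte.

    Returns
    -------
    dict with cohort size, per-oocyte pulse counts, the modal pulse count,
    incidence of any pulse (with binomial SE), classification fractions, and
    mean ± SEM peak times by pulse rank among oocytes showing the modal count.
    """
    if not trace_summaries:
        raise ValueError("cohort is empty")
    n = len(trace_summaries)
    counts = [s["n_pulses"] for s in trace_summaries]
    modal = Counter(counts).most_common(1)[0][0]
    any_pulse = sum(1 for c in counts if c >= 1)

    class_fracs = {}
    for label in ("maturing-like", "partial", "arrested-like"):
        k = sum(1 for s in trace_summaries if s["classification"] == label)
        class_fracs[label] = proportion_summary(k, n)

    # mean peak time by rank, over oocytes that show the modal pulse count
    pulse_time_stats = []
    if modal >= 1:
        modal_sets = [s["pulse_times"] for s in trace_summaries if s["n_pulses"] == modal]
        for rank in range(modal):
            vals = [pt[rank] for pt in modal_sets]
            if len(vals) >= 2:
                g = group_summary(vals)
                pulse_time_stats.append({"rank": rank + 1, "mean_h": g.mean, "sem_h": g.sem, "n": g.n})
            else:
                pulse_time_stats.append({"rank": rank + 1, "mean_h": vals[0], "sem_h": math.nan, "n": 1})

    return {
        "n": n,
        "pulse_counts": counts,
        "modal_pulse_count": modal,
        "incidence_any_pulse": proportion_summary(any_pulse, n),
        "classification_fractions": class_fracs,
        "pulse_times": pulse_time_stats,
    }


def quantify_image_arm(
    preset: str,
    n_images: int,
    base_seed: int = 0,
    threshold_method: str = "otsu",
    min_area_um2: float = 0.2,
    theta_ring: float = 1.5,
) -> dict:
    """Simulate and quantify ``n_images`` sections of one image preset.

    Each image is thresholded and labeled, its aggregation pattern is
    classified, and the peri-nuclear ring is scored on the simulated ring
    geometry (or the default geometry when the preset has no ring).
    """
    cfg = simulate.IMAGE_PRESETS[preset]
    per_image = []
    all_areas: list[float] = []
    ring_calls = 0
    for i in range(n_images):
        img, _, _ = simulate.simulate_image_preset(preset, seed=base_seed + i)
        mask = threshold_image_from(img, threshold_method)
        cs = images.label_clusters(mask, img.pixel_size_um, min_area_um2=min_area_um2)
        summary = cs.summary
        pattern = images.classify_pattern(summary)

        center = img.meta["cell_center_px"]
        ring_spec = img.meta.get("ring") or simulate.RingSpec()
        yy, xx = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
        cell = np.hypot(yy - center[0], xx - center[1]) * img.pixel_size_um <= cfg.cell_radius_um
        ring = images.ring_score(
            img, center, ring_spec.radius_um, ring_spec.width_um, cell, theta_ring=theta_ring
        )
        ring_calls += int(ring.present)
        all_areas.extend(cs.areas_um2.tolist())
        per_image.append({**summary, "pattern": pattern, "ring_score": ring.score, "ring_present": ring.present})

    counts = [p["n_clusters"] for p in per_image]
    patterns = Counter(p["pattern"] for p in per_image)
    return {
        "preset": preset,
        "n_images": n_images,
        "per_image": per_image,
        "mean_count": float(np.mean(counts)),
        "sem_count": float(np.std(counts, ddof=1) / math.sqrt(len(counts))) if len(counts) > 1 else math.nan,
        "grand_mean_area_um2": float(np.mean(all_areas)) if all_areas else math.nan,
        "ring_fraction": proportion_summary(ring_calls, n_images),
        "pattern_fractions": {k: v / n_images for k, v in patterns.items()},
    }


def threshold_image_from(img: images.MitoImage, method: str):
    """Dispatch helper accepting 'otsu' or 'fixed:<value>'."""
    if method.startswith("fixed:"):
        return images.threshold_image(img, "fixed", value=float(method.split(":", 1)[1]))
    return images.threshold_image(img, method)


def run_experiment(config: dict) -> dict:
    """Run a full synthetic experiment: simulate, analyze, summarize.

    ``config`` schema::

        seed: int                     # master seed
        trace_arms:                   # cohorts of luminescence traces
          - {name, preset, n}
        image_arms:                   # batches of section images
          - {name, preset, n}
        detector: {tau, smooth_bins, min_dur_min, merge_gap_min, edge_trim_min}
        baseline_model: weibull | lognormal

    Per-arm seeds are derived deterministically from the master seed, so the
    whole report reproduces bit-exactly from the same config.
    """
    known = {"seed", "trace_arms", "image_arms", "detector", "baseline_model"}
    unknown = set(config) - known
    if unknown:
        raise ValueError(f"unknown experiment config keys: {sorted(unknown)}")
    seed = int(config.get("seed", 0))
    model = config.get("baseline_model", "weibull")
    det = traces.DetectorParams(**config.get("detector", {}))

    report: dict = {"seed": seed, "trace_arms": {}, "image_arms": {}}
    for j, arm in enumerate(config.get("trace_arms", [])):
        arm_seed = seed + 10_000 * (j + 1)
        cohort = simulate.simulate_cohort(arm["preset"], arm["n"], base_seed=arm_seed)
        summaries = []
        for tr in cohort:
            fit = traces.fit_baseline(tr, model=model)
            pulses = traces.detect_pulses(fit, det)
            summaries.append(traces.summarize_trace(pulses))
        report["trace_arms"][arm["name"]] = {
            "preset": arm["preset"],
            "seed": arm_seed,
            **summarize_cohort(summaries),
        }
    for j, arm in enumerate(config.get("image_arms", [])):
        arm_seed = seed + 1_000_000 * (j + 1)
        report["image_arms"][arm["name"]] = {
            "seed": arm_seed,
            **quantify_image_arm(arm["preset"], arm["n"], base_seed=arm_seed),
        }
    return report
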