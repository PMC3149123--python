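"""Synthetic luminescence traces and equatorial-section images with ground truth.

The generator emulates the two kinds of raw data the analysis consumes:

* photon-count luminescence traces — a smooth Weibull expression/destruction
  baseline with up to three multiplicative raised-cosine ATP pulses (around
  1.5 h, 6 h and 11.5 h after release from IBMX arrest) and Poisson counting
  noise;
* single-channel mitotracker-like section images — bright elliptical
  mitochondrial clusters with log-normally distributed areas placed without
  overlap inside a circular cell, optionally concentrated into a peri-nuclear
  ring, over a uniform background with additive Gaussian noise.

Treatment presets encode which pulses survive each experimental manipulation:
IBMX arrest retains none, nocodazole and enucleation retain the first two,
and cytochalasin B removes the first two and leaves an attenuated third pulse
in a minority of the cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage

from mitopulse.images import MitoImage
from mitopulse.traces import LuminescenceTrace, weibull_baseline

__all__ = [
    "PulseSpec",
    "TraceSimConfig",
    "ImageSimConfig",
    "TreatmentPreset",
    "DEFAULT_PULSES",
    "TRACE_PRESETS",
    "IMAGE_PRESETS",
    "simulate_trace",
    "simulate_cohort",
    "simulate_image",
]


@dataclass(frozen=True)
class PulseSpec:
    """One ATP pulse: a raised-cosine bump on the baseline.

    ``frac_amplitude`` is the fractional excursion at the pulse center
    relative to the local baseline (0.15 means a 15% rise).
    """

    center_h: float
    half_width_h: float
    frac_amplitude: float

    def __post_init__(self) -> None:
        if self.half_width_h <= 0:
            raise ValueError("half_width_h must be positive")
        if self.frac_amplitude < 0:
            raise ValueError("frac_amplitude must be non-negative")


#: Default pulse schedule: GVBD (~1-2 h after IBMX release), spindle
#: migration (~5-7 h), and the MI-MII transition (~11-12 h).
DEFAULT_PULSES: tuple[PulseSpec, ...] = (
    PulseSpec(center_h=1.5, half_width_h=0.5, frac_amplitude=0.15),
    PulseSpec(center_h=6.0, half_width_h=1.0, frac_amplitude=0.15),
    PulseSpec(center_h=11.5, half_width_h=0.5, frac_amplitude=0.15),
)

#: Baseline defaults: total photon budget A, Weibull shape k and scale lam
#: (hours), onset t0 (hours), camera offset b (counts/bin).  Peak expectation
#: lands in the low thousands of counts per 30-s bin.
DEFAULT_BASELINE: dict[str, float] = {"A": 2e6, "k": 2.2, "lam": 9.0, "t0": 0.0, "b": 50.0}


@dataclass(frozen=True)
class TraceSimConfig:
    """Configuration for one simulated luminescence trace."""

    duration_h: float = 14.0
    bin_s: float = 30.0
    baseline_params: dict = field(default_factory=lambda: dict(DEFAULT_BASELINE))
    pulses: tuple[PulseSpec, ...] = DEFAULT_PULSES
    pulse_mode: Literal["multiplicative", "additive"] = "multiplicative"
    poisson_noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        n = self.duration_h * 3600.0 / self.bin_s
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"duration_h={self.duration_h} is not a whole number of {self.bin_s}-s bins"
            )
        p = self.baseline_params
        if p["k"] <= 0 or p["lam"] <= 0 or p["t0"] < 0 or p["b"] < 0 or p["A"] < 0:
            raise ValueError("baseline parameters out of bounds")
        for ps in self.pulses:
            if not (0 <= ps.center_h <= self.duration_h):
                raise ValueError(f"pulse center {ps.center_h} h outside trace duration")

    @property
    def n_bins(self) -> int:
        return int(round(self.duration_h * 3600.0 / self.bin_s))


def _raised_cosine(t: np.ndarray, pulse: PulseSpec) -> np.ndarray:
    """Unit-peak raised-cosine bump, zero outside |t - center| >= half_width."""
    x = (t - pulse.center_h) / pulse.half_width_h
    bump = np.where(np.abs(x) < 1.0, 0.5 * (1.0 + np.cos(np.pi * x)), 0.0)
    return bump


def expected_counts(config: TraceSimConfig, times: np.ndarray | None = None) -> np.ndarray:
    """Noiseless expected counts per bin m(t) for a trace configuration."""
    if times is None:
        bin_h = config.bin_s / 3600.0
        times = (np.arange(config.n_bins) + 0.5) * bin_h
    p = config.baseline_params
    base = weibull_baseline(times, p["A"], p["k"], p["lam"], p["t0"], p["b"], config.bin_s / 3600.0)
    if config.pulse_mode == "multiplicative":
        factor = np.ones_like(base)
        for ps in config.pulses:
            factor += ps.frac_amplitude * _raised_cosine(times, ps)
        return base * factor
    # additive: bump amplitude anchored at the baseline value under the pulse center
    m = base.copy()
    for ps in config.pulses:
        anchor = weibull_baseline(
            np.array([ps.center_h]), p["A"], p["k"], p["lam"], p["t0"], p["b"], config.bin_s / 3600.0
        )[0]
        m += ps.frac_amplitude * anchor * _raised_cosine(times, ps)
    return m


def simulate_trace(config: TraceSimConfig) -> LuminescenceTrace:
    """Simulate one luminescence trace.

    Counts are drawn ``Poisson(m(t))`` per bin, where the expectation is the
    Weibull baseline modulated by the configured pulses; with
    ``poisson_noise=False`` the trace carries ``m(t)`` exactly.  The
    ground-truth pulse schedule is stored in ``trace.meta["pulses"]``.
    Identical configurations (including seed) give bit-identical traces.
    """
    bin_h = config.bin_s / 3600.0
    times = (np.arange(config.n_bins) + 0.5) * bin_h
    m = expected_counts(config, times)
    if config.poisson_noise:
        rng = np.random.default_rng(config.seed)
        counts = rng.poisson(m).astype(float)
    else:
        counts = m
    return LuminescenceTrace(
        times=times,
        counts=counts,
        bin_s=config.bin_s,
        meta={"pulses": list(config.pulses), "config": config},
    )


@dataclass(frozen=True)
class TreatmentPreset:
    """Which default pulses a treatment retains, and its image pattern.

    ``retained`` indexes into the default three-pulse schedule.
    ``attenuated`` maps a pulse index to an amplitude multiplier applied in a
    ``attenuated_fraction`` subset of the cohort (cytochalasin B leaves a
    small third pulse in 14/36 of oocytes).
    """

    name: str
    retained: tuple[int, ...]
    attenuated: dict = field(default_factory=dict)
    attenuated_fraction: float = 0.0
    image_pattern: str = "aggregated"


TRACE_PRESETS: dict[str, TreatmentPreset] = {
    "maturing": TreatmentPreset("maturing", retained=(0, 1, 2), image_pattern="aggregated"),
    "ibmx_arrest": TreatmentPreset("ibmx_arrest", retained=(), image_pattern="aggregated"),
    "nocodazole": TreatmentPreset("nocodazole", retained=(0, 1), image_pattern="aggregated"),
    "enucleation": TreatmentPreset("enucleation", retained=(0, 1), image_pattern="gvbd_ring"),
    "cytochalasin_b": TreatmentPreset(
        "cytochalasin_b",
        retained=(),
        attenuated={2: 0.3},
        attenuated_fraction=14.0 / 36.0,
        image_pattern="dispersed",
    ),
}


def _preset_pulses(preset: TreatmentPreset, attenuate: bool) -> tuple[PulseSpec, ...]:
    pulses = []
    for i, ps in enumerate(DEFAULT_PULSES):
        if i in preset.retained:
            pulses.append(ps)
        elif attenuate and i in preset.attenuated:
            pulses.append(replace(ps, frac_amplitude=ps.frac_amplitude * preset.attenuated[i]))
    return tuple(pulses)


def simulate_cohort(
    preset: TreatmentPreset | str,
    n: int,
    base_seed: int = 0,
    **config_overrides,
) -> list[LuminescenceTrace]:
    """Simulate a cohort of ``n`` oocytes under one treatment preset.

    Each oocyte uses seed ``base_seed + i``.  For presets with an attenuated
    subset (cytochalasin B), ``round(n * attenuated_fraction)`` cohort members
    are selected deterministically from ``base_seed`` to keep the attenuated
    pulse; the rest lose it entirely.
    """
    if isinstance(preset, str):
        try:
            preset = TRACE_PRESETS[preset]
        except KeyError:
            raise ValueError(
                f"unknown preset {preset!r}; choose from {sorted(TRACE_PRESETS)}"
            ) from None
    if n < 1:
        raise ValueError("cohort size must be at least 1")

    attenuated_idx: set[int] = set()
    if preset.attenuated and preset.attenuated_fraction > 0:
        k = int(round(n * preset.attenuated_fraction))
        picker = np.random.default_rng(base_seed)
        attenuated_idx = set(picker.choice(n, size=k, replace=False).tolist())

    traces = []
    for i in range(n):
        pulses = _preset_pulses(preset, attenuate=i in attenuated_idx)
        cfg = TraceSimConfig(pulses=pulses, seed=base_seed + i, **config_overrides)
        trace = simulate_trace(cfg)
        trace.meta["preset"] = preset.name
        trace.meta["oocyte"] = i
        traces.append(trace)
    return traces


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RingSpec:
    """Peri-nuclear ring: a fraction of clusters is placed in an annulus."""

    radius_um: float = 13.0
    width_um: float = 5.0
    fraction_of_clusters: float = 0.6

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction_of_clusters <= 1.0):
            raise ValueError("ring fraction must lie in [0, 1]")


@dataclass(frozen=True)
class ImageSimConfig:
    """Configuration for one simulated equatorial-section image.

    Cluster areas (µm²) are log-normal with the given mean and coefficient of
    variation, floored at 0.2 µm² — the area of a single mitochondrion, below
    which a cluster is not physically meaningful.  Clusters are rendered as
    filled ellipses (axis ratio uniform in [1, 2]) at non-overlapping
    positions inside the cell disc.
    """

    field_px: int = 768
    pixel_size_um: float = 0.1
    cell_radius_um: float = 35.0
    n_clusters: int = 66
    mean_area_um2: float = 4.7
    area_cv: float = 0.5
    cluster_intensity: float = 20000.0
    background_level: float = 2000.0
    noise_sd: float = 1000.0
    ring: RingSpec | None = None
    nucleus_radius_um: float | None = None
    seed: int = 0
    min_area_um2: float = 0.2
    max_place_tries: int = 500

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.n_clusters < 0:
            raise ValueError("n_clusters must be non-negative")
        if self.cell_radius_um * 2 > self.field_px * self.pixel_size_um:
            raise ValueError("cell does not fit in the field")


#: Image presets matching the measured aggregation regimes: few large
#: clusters (aggregated) vs many small ones (dispersed); gvbd_ring adds the
#: dense peri-nuclear ring seen at germinal-vesicle breakdown.
IMAGE_PRESETS: dict[str, ImageSimConfig] = {
    "aggregated": ImageSimConfig(n_clusters=66, mean_area_um2=4.7),
    "dispersed": ImageSimConfig(n_clusters=102, mean_area_um2=2.6),
    "gvbd_ring": ImageSimConfig(
        n_clusters=66, mean_area_um2=4.7, ring=RingSpec(), nucleus_radius_um=12.0
    ),
    "cytochalasin": ImageSimConfig(n_clusters=102, mean_area_um2=2.6),
}


def _sample_area(rng: np.random.Generator, mean: float, cv: float, floor: float) -> float:
    """Log-normal area with given mean and CV, resampled to respect the floor."""
    sigma2 = math.log(1.0 + cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    for _ in range(1000):
        a = float(rng.lognormal(mu, math.sqrt(sigma2)))
        if a >= floor:
            return a
    raise RuntimeError("area sampling failed to clear the minimum-area floor")


def _ellipse_mask(a_px: float, b_px: float, theta: float) -> np.ndarray:
    """Boolean mask of a filled rotated ellipse on a tight bounding box."""
    r = int(math.ceil(max(a_px, b_px))) + 1
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    ct, st = math.cos(theta), math.sin(theta)
    u = (xx * ct + yy * st) / a_px
    v = (-xx * st + yy * ct) / b_px
    return (u * u + v * v) <= 1.0


def simulate_image(config: ImageSimConfig) -> tuple[MitoImage, np.ndarray, list[dict]]:
    """Simulate one section image with ground truth.

    Returns
    -------
    image : MitoImage
        Rendered uint16 raster with the configured pixel size; metadata
        records the cell center/radius and any ring geometry.
    labels : ndarray of int32
        Ground-truth label raster (0 = background); label ``i`` marks exactly
        the pixels rendered for cluster ``i``.
    clusters : list of dict
        Per-cluster ground truth: sampled target area, rendered pixel count
        and area in µm², centroid, and whether it was placed in the ring.

    Raises
    ------
    RuntimeError
        If a cluster cannot be placed without overlap within the retry
        budget; the message names the density achieved.
    """
    rng = np.random.default_rng(config.seed)
    ps = config.pixel_size_um
    n_px = config.field_px
    center = (n_px - 1) / 2.0

    yy, xx = np.mgrid[0:n_px, 0:n_px]
    dist_um = np.hypot(yy - center, xx - center) * ps
    cell_mask = dist_um <= config.cell_radius_um

    labels = np.zeros((n_px, n_px), dtype=np.int32)
    occupied = np.zeros((n_px, n_px), dtype=bool)
    # forbidden = occupied grown by one pixel so clusters never touch, even diagonally
    forbidden = np.zeros((n_px, n_px), dtype=bool)
    clusters: list[dict] = []

    n_ring = 0
    if config.ring is not None:
        n_ring = int(round(config.n_clusters * config.ring.fraction_of_clusters))

    for i in range(config.n_clusters):
        in_ring = i < n_ring
        area_um2 = _sample_area(rng, config.mean_area_um2, config.area_cv, config.min_area_um2)
        area_px = area_um2 / (ps * ps)
        q = rng.uniform(1.0, 2.0)
        a_px = math.sqrt(area_px * q / math.pi)
        b_px = math.sqrt(area_px / (q * math.pi))
        theta = rng.uniform(0.0, math.pi)
        tile = _ellipse_mask(a_px, b_px, theta)
        r_tile = tile.shape[0] // 2

        placed = False
        for _ in range(config.max_place_tries):
            if in_ring:
                rad = rng.uniform(config.ring.radius_um, config.ring.radius_um + config.ring.width_um)
                ang = rng.uniform(0.0, 2.0 * math.pi)
                cy = center + (rad / ps) * math.sin(ang)
                cx = center + (rad / ps) * math.cos(ang)
            else:
                # uniform over the cell disc
                rad = config.cell_radius_um * math.sqrt(rng.uniform())
                ang = rng.uniform(0.0, 2.0 * math.pi)
                cy = center + (rad / ps) * math.sin(ang)
                cx = center + (rad / ps) * math.cos(ang)
            iy, ix = int(round(cy)), int(round(cx))
            y0, y1 = iy - r_tile, iy + r_tile + 1
            x0, x1 = ix - r_tile, ix + r_tile + 1
            if y0 < 0 or x0 < 0 or y1 > n_px or x1 > n_px:
                continue
            d_center = math.hypot(iy - center, ix - center) * ps
            # keep the whole ellipse inside the cell
            if d_center + max(a_px, b_px) * ps > config.cell_radius_um:
                continue
            if config.nucleus_radius_um is not None and not in_ring:
                if d_center - max(a_px, b_px) * ps < config.nucleus_radius_um:
                    continue
            region = (slice(y0, y1), slice(x0, x1))
            if np.any(tile & forbidden[region]):
                continue
            labels[region][tile] = i + 1
            occupied[region] |= tile
            # grow the new cluster by 1 px (8-neighborhood) into the forbidden
            # mask so no later cluster can touch it, even diagonally
            grown = ndimage.binary_dilation(tile, structure=np.ones((3, 3), dtype=bool))
            forbidden[region] |= grown
            pix = int(tile.sum())
            clusters.append(
                {
                    "id": i + 1,
                    "target_area_um2": area_um2,
                    "pixel_count": pix,
                    "area_um2": pix * ps * ps,
                    "centroid": (float(iy), float(ix)),
                    "in_ring": in_ring,
                }
            )
            placed = True
            break
        if not placed:
            density = occupied.sum() * ps * ps / (math.pi * config.cell_radius_um**2)
            raise RuntimeError(
                f"could not place cluster {i + 1}/{config.n_clusters} after "
                f"{config.max_place_tries} tries; cell already {density:.1%} covered"
            )

    img = np.full((n_px, n_px), config.background_level, dtype=float)
    img[occupied] = config.cluster_intensity
    if config.noise_sd > 0:
        img += rng.normal(0.0, config.noise_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, 65535).astype(np.uint16)

    meta = {
        "seed": config.seed,
        "cell_center_px": (center, center),
        "cell_radius_um": config.cell_radius_um,
        "nucleus_radius_um": config.nucleus_radius_um,
        "ring": config.ring,
    }
    return MitoImage(pixels=img, pixel_size_um=ps, meta=meta), labels, clusters


def simulate_image_preset(name: str, seed: int = 0, **overrides) -> tuple[MitoImage, np.ndarray, list[dict]]:
    """Convenience wrapper: simulate one of the named image presets."""
    try:
        base = IMAGE_PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown image preset {name!r}; choose from {sorted(IMAGE_PRESETS)}") from None
    cfg = replace(base, seed=seed, **overrides)
    img, labels, clusters = simulate_image(cfg)
    img.meta["preset"] = name
    return img, labels, clusters
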