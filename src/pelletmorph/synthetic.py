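"""Synthetic ground-truth data: bright-field-like pellet scenes and
replicate growth curves.

Scenes emulate what the 40x bright-field flow-through-chamber camera
sees: dark, roughly circular pellets with fuzzy halos on a bright,
possibly gradient-illuminated, noisy background.  Each pellet is rendered
as a radially symmetric sigmoid intensity profile

    I(d) = core + (background(d) - core) / (1 + exp(-(d - r_mid) / softness))

with ``r_mid = radius + halo_width/2``, so the silhouette fades from the
dark core (distance ≤ radius) through the halo to the background over
``halo_width`` pixels.  The *ground-truth* projected area of a pellet is
its halo-inclusive silhouette (distance ≤ radius + halo_width); because
the detection pipeline thresholds and erodes into the halo, it
systematically recovers slightly less than this truth — mirroring the
documented behaviour on real micrographs.

Growth curves emulate replicate backscatter measurements: a logistic mean
curve per well, sampled every cycle, under i.i.d. multiplicative
lognormal noise.  ``lag_h`` is defined as the time at which the mean
signal exceeds the pre-growth baseline by one signal unit.

All randomness flows from the integer ``seed`` fields; identical specs
give bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError, PlacementError
from .growth_stats import BackscatterSeries
from .image_io import DEFAULT_PIXEL_AREA_UM2, RawImage, write_image


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic pellet scene.

    Pellet radii (px) are lognormal: ``log r ~ N(radius_mu_log,
    radius_sigma_log²)``.  ``illumination_gradient`` is (direction_deg,
    amplitude): a linear ramp of the given 8-bit amplitude across the
    image along the given direction.  ``min_separation_px`` is the
    minimum center-to-center distance (0 allows touching/overlap).
    """

    image_shape: tuple[int, int] = (960, 1280)  # rows, cols
    n_pellets: int = 30
    radius_mu_log: float = math.log(20.0)
    radius_sigma_log: float = 0.25
    core_intensity: float = 60.0
    background_intensity: float = 200.0
    halo_width_px: float = 7.0
    halo_softness: float = 1.0
    illumination_gradient: tuple[float, float] = (0.0, 25.0)
    noise_sd: float = 5.0
    min_separation_px: float = 90.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pellets < 0:
            raise ParameterError("n_pellets must be >= 0")
        for name in ("core_intensity", "background_intensity"):
            v = getattr(self, name)
            if not 0 <= v <= 255:
                raise ParameterError(f"{name} must be within the 8-bit range")
        if self.halo_width_px < 0 or self.halo_softness <= 0:
            raise ParameterError("halo_width_px >= 0 and halo_softness > 0 required")
        if self.noise_sd < 0 or self.min_separation_px < 0:
            raise ParameterError("noise_sd and min_separation_px must be >= 0")


@dataclass(frozen=True)
class PelletTruth:
    """Ground truth for one rendered pellet."""

    center: tuple[float, float]  # (row, col)
    radius_px: float
    core_area_px: int  # pixels with distance <= radius
    halo_area_px: int  # pixels with distance <= radius + halo_width


@dataclass
class SyntheticScene:
    """Rendered image plus the ground-truth pellet list."""

    image: RawImage
    truth: list[PelletTruth] = field(default_factory=list)
    spec: SceneSpec = field(default_factory=SceneSpec)

    @property
    def true_core_areas_px(self) -> np.ndarray:
        return np.array([t.core_area_px for t in self.truth], dtype=float)

    @property
    def true_halo_areas_px(self) -> np.ndarray:
        return np.array([t.halo_area_px for t in self.truth], dtype=float)


@dataclass(frozen=True)
class GrowthSpec:
    """Parameters of synthetic replicate backscatter curves.

    The mean curve is ``baseline + capacity / (1 + exp(-rate (t - t_mid)))``
    with ``t_mid`` placed so the mean exceeds the baseline by exactly one
    signal unit at ``t = lag_h``.  ``noise_sigma`` is the SD of the log of
    the multiplicative noise, drawn independently per cycle and well.
    """

    n_wells: int = 8
    lag_h: float = 10.0
    rate: float = 0.3  # 1/h
    capacity: float = 100.0  # backscatter a.u. above baseline
    baseline: float = 2.0  # instrument blank signal, a.u.
    noise_sigma: float = 0.13
    cycle_interval_h: float = 1.0 / 6.0  # one cycle every 10 minutes
    duration_h: float = 48.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.capacity <= 0 or self.baseline <= 0:
            raise ParameterError("capacity and baseline must be > 0")
        if self.noise_sigma < 0:
            raise ParameterError("noise_sigma must be >= 0")
        if self.n_wells < 2:
            raise ParameterError("need >= 2 replicate wells")
        if self.rate <= 0 or self.cycle_interval_h <= 0 or self.duration_h <= 0:
            raise ParameterError("rate, cycle_interval_h, duration_h must be > 0")


# ---------------------------------------------------------------------------
# scene generation
# ---------------------------------------------------------------------------


def _place_centers(
    rng: np.random.Generator,
    shape: tuple[int, int],
    radii: np.ndarray,
    halo_width: float,
    min_separation: float,
    max_tries_per_pellet: int = 500,
) -> np.ndarray:
    """Rejection-sample pellet centers honouring separation and margins."""
    centers: list[tuple[float, float]] = []
    for r in radii:
        margin = r + halo_width + 6.0  # keep clear of the border-clearing zone
        if 2 * margin >= min(shape):
            raise PlacementError(
                f"pellet radius {r:.1f} px does not fit image {shape}"
            )
        for _ in range(max_tries_per_pellet):
            row = rng.uniform(margin, shape[0] - margin)
            col = rng.uniform(margin, shape[1] - margin)
            if all(
                math.hypot(row - cr, col - cc) >= min_separation
                for cr, cc in centers
            ):
                centers.append((row, col))
                break
        else:
            raise PlacementError(
                f"could not place pellet {len(centers) + 1}/{len(radii)} with "
                f"min_separation {min_separation} px after {max_tries_per_pellet} tries"
            )
    return np.array(centers).reshape(-1, 2)


def _background_plane(spec: SceneSpec) -> np.ndarray:
    rows, cols = spec.image_shape
    direction_deg, amplitude = spec.illumination_gradient
    bg = np.full(spec.image_shape, spec.background_intensity, dtype=np.float64)
    if amplitude:
        theta = math.radians(direction_deg)
        rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
        proj = math.cos(theta) * cc / max(cols - 1, 1) + math.sin(theta) * rr / max(rows - 1, 1)
        span = proj.max() - proj.min()
        if span > 0:
            bg += amplitude * ((proj - proj.min()) / span - 0.5)
    return bg


def generate_scene(spec: SceneSpec) -> SyntheticScene:
    """Render one synthetic bright-field pellet scene with ground truth.

    Deterministic given ``spec.seed``.  Raises :class:`PlacementError` when
    ``n_pellets`` cannot be placed under ``min_separation_px`` within a
    bounded number of retries.
    """
    rng = np.random.default_rng(spec.seed)
    radii = np.exp(rng.normal(spec.radius_mu_log, spec.radius_sigma_log, spec.n_pellets))
    img = _background_plane(spec)
    truth: list[PelletTruth] = []
    if spec.n_pellets:
        centers = _place_centers(
            rng, spec.image_shape, radii, spec.halo_width_px, spec.min_separation_px
        )
        for (crow, ccol), r in zip(centers, radii):
            r_out = r + spec.halo_width_px
            pad = int(math.ceil(r_out + 8 * spec.halo_softness))
            r0 = max(0, int(crow) - pad)
            r1 = min(spec.image_shape[0], int(crow) + pad + 1)
            c0 = max(0, int(ccol) - pad)
            c1 = min(spec.image_shape[1], int(ccol) + pad + 1)
            rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
            d = np.hypot(rr - crow, cc - ccol)
            fade = 1.0 / (1.0 + np.exp(
                -(d - (r + spec.halo_width_px / 2.0)) / spec.halo_softness
            ))
            patch = img[r0:r1, c0:c1]
            img[r0:r1, c0:c1] = spec.core_intensity + (patch - spec.core_intensity) * fade
            truth.append(
                PelletTruth(
                    center=(float(crow), float(ccol)),
                    radius_px=float(r),
                    core_area_px=int((d <= r).sum()),
                    halo_area_px=int((d <= r_out).sum()),
                )
            )
    if spec.noise_sd:
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return SyntheticScene(
        image=RawImage(pixels=img, pixel_area_um2=DEFAULT_PIXEL_AREA_UM2,
                       source_path=f"synthetic:seed={spec.seed}"),
        truth=truth,
        spec=spec,
    )


def render_core_mask(scene: SyntheticScene) -> np.ndarray:
    """Noiseless hard-core rendering: True where distance ≤ radius.

    Used to check ground-truth conservation: for non-overlapping pellets
    the union's pixel count equals the sum of per-pellet core areas.
    """
    mask = np.zeros(scene.image.shape, dtype=bool)
    rr, cc = np.indices(scene.image.shape)
    for t in scene.truth:
        crow, ccol = t.center
        mask |= np.hypot(rr - crow, cc - ccol) <= t.radius_px
    return mask


def _derived_seed(base_seed: int, median_area: float, scene_index: int) -> int:
    """Stable per-scene seed derived from (base seed, target median, index).

    Keyed on the target median area so a constant growth function
    reproduces byte-identical time points.
    """
    ss = np.random.SeedSequence(
        entropy=[int(base_seed), int(round(median_area * 1e6)), int(scene_index)]
    )
    return int(ss.generate_state(1)[0] % (2**31))


def generate_timeseries_scenes(
    base: SceneSpec,
    time_points: Sequence[float],
    median_growth: Callable[[float], float],
    scenes_per_time: int = 1,
) -> list[tuple[float, list[SyntheticScene]]]:
    """Scenes for a whole cultivation time course.

    ``median_growth(t)`` gives the target *true median projected area*
    (halo-inclusive, px²) at time ``t``; the lognormal radius median is
    rescaled so the pellet population matches it, and the minimum pellet
    separation is rescaled proportionally so growing pellets stay
    non-overlapping (as on real micrographs, where fewer but larger
    pellets fill a frame).  Per-scene seeds are derived from the base
    seed, the target median and the scene index.
    """
    base_r_median = math.exp(base.radius_mu_log)
    out: list[tuple[float, list[SyntheticScene]]] = []
    for t in time_points:
        target_area = float(median_growth(t))
        if target_area <= 0:
            raise ParameterError(f"median_growth({t}) must be positive")
        r_median = math.sqrt(target_area / math.pi) - base.halo_width_px
        if r_median <= 1:
            raise ParameterError(
                f"target median area {target_area:.0f} px² too small for "
                f"halo width {base.halo_width_px}"
            )
        scenes = []
        for k in range(scenes_per_time):
            spec_t = replace(
                base,
                radius_mu_log=math.log(r_median),
                min_separation_px=base.min_separation_px * r_median / base_r_median,
                seed=_derived_seed(base.seed, target_area, k),
            )
            scenes.append(generate_scene(spec_t))
        out.append((float(t), scenes))
    return out


# ---------------------------------------------------------------------------
# growth curves
# ---------------------------------------------------------------------------


def logistic_mean(spec: GrowthSpec, t: np.ndarray) -> np.ndarray:
    """Mean backscatter curve; exceeds the baseline by 1 a.u. at lag_h."""
    # Solve baseline + capacity/(1+exp(-rate (lag - t_mid))) = baseline + 1.
    t_mid = spec.lag_h + math.log(spec.capacity - 1.0) / spec.rate
    return spec.baseline + spec.capacity / (1.0 + np.exp(-spec.rate * (np.asarray(t) - t_mid)))


def expected_onset_cycle(spec: GrowthSpec, blank_cycles: int = 5,
                         alpha: float = 0.01) -> int:
    """Noise-free expected signal-start cycle for a growth spec.

    Closed form: the first cycle where the mean logistic curve exceeds the
    limit of detection computed from the true blank statistics (blank mean
    of the first ``blank_cycles`` cycles; blank SD from the lognormal
    noise model, ``mean × sqrt(exp(σ²) − 1)``).
    """
    from scipy import stats as _stats

    t = np.arange(0.0, spec.duration_h + 1e-9, spec.cycle_interval_h)
    mean = logistic_mean(spec, t)
    blank_mean = mean[:blank_cycles].mean()
    blank_sd = blank_mean * math.sqrt(math.expm1(spec.noise_sigma**2))
    lod = blank_mean + _stats.norm.ppf(1 - alpha) * blank_sd
    above = mean > lod
    if not above.any():
        raise ParameterError("mean curve never exceeds its expected LOD")
    return int(np.argmax(above))


def generate_growth_curves(spec: GrowthSpec) -> BackscatterSeries:
    """Replicate backscatter curves under multiplicative lognormal noise.

    With ``noise_sigma`` 0 all wells are identical (rmcv is exactly 0);
    otherwise the population CV at every cycle is
    ``sqrt(exp(noise_sigma²) − 1) ≈ noise_sigma``.
    """
    rng = np.random.default_rng(spec.seed)
    t = np.arange(0.0, spec.duration_h + 1e-9, spec.cycle_interval_h)
    mean = logistic_mean(spec, t)
    if spec.noise_sigma:
        noise = np.exp(rng.normal(0.0, spec.noise_sigma, (t.size, spec.n_wells)))
    else:
        noise = np.ones((t.size, spec.n_wells))
    values = mean[:, None] * noise
    return BackscatterSeries(
        time_h=t, values=values,
        well_ids=[f"W{j + 1}" for j in range(spec.n_wells)],
    )


# ---------------------------------------------------------------------------
# fixture export
# ---------------------------------------------------------------------------


def write_scene(scene: SyntheticScene, image_path: str | Path,
                truth_path: str | Path) -> None:
    """Write a scene as 8-bit PNG plus its ground-truth CSV."""
    write_image(scene.image, image_path)
    pd.DataFrame(
        {
            "center_row": [t.center[0] for t in scene.truth],
            "center_col": [t.center[1] for t in scene.truth],
            "radius_px": [t.radius_px for t in scene.truth],
            "core_area_px": [t.core_area_px for t in scene.truth],
            "halo_area_px": [t.halo_area_px for t in scene.truth],
        }
    ).to_csv(truth_path, index=False)
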