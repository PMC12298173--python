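"""Synthetic ground truth: RTD families, rendered tube images, feed logs.

No experimental photographs are deposited with the method, so testing
runs on synthetic fixtures generated here:

* a tanks-in-series RTD family (N ideal mixers in sequence) as the
  ground-truth density — its closed forms (mean ``t_m``, dimensionless
  variance ``1/N``) make it a self-checking oracle, and N of 2-3 matches
  the intermediate mixing regimes seen in twin-screw granulation;
* a renderer that inverts the measurement pipeline, painting a tube
  photograph whose per-grid gray level encodes a known concentration
  profile through a linear concentration-L* calibration, plus the
  matching blank image;
* a cumulative-mass feed log with injected excursions for the feeder
  audit.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .calibration import LinearCalibration
from .color import rgb_to_lab
from .feed_audit import FeedLog
from .region import DetectionRegion, divide_grid
from .rtd import times_from_collection_window

__all__ = [
    "TanksInSeriesSpec",
    "TubeImageSpec",
    "tanks_in_series_E",
    "render_tube_image",
    "gray_for_lstar",
    "synth_feed_log",
    "synthetic_concentration_calibration",
]


@dataclass(frozen=True)
class TanksInSeriesSpec:
    """N ideal stirred tanks in series with overall mean residence t_m."""

    n_tanks: int
    t_m_true: float
    amplitude: float = 2.0  # peak concentration, wt%

    def __post_init__(self):
        if self.n_tanks < 1:
            raise ValueError("n_tanks must be >= 1")
        if self.t_m_true <= 0:
            raise ValueError("t_m_true must be positive")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")


@dataclass(frozen=True)
class TubeImageSpec:
    """Geometry and noise model of a rendered tube photograph."""

    height_px: int = 1100
    width_px: int = 300
    center_column: int = 150
    region_width_px: int = 100
    row_bottom: int = 1050
    row_top: int = 50
    blank_lstar: float = 85.0
    noise_sigma: float = 0.0  # gray levels (0-255 scale)
    seed: int = 0

    def __post_init__(self):
        if self.height_px <= 0 or self.width_px <= 0:
            raise ValueError("image dimensions must be positive")
        if not 0 < self.blank_lstar <= 100:
            raise ValueError("blank_lstar must lie in (0, 100]")

    def region(self) -> DetectionRegion:
        return DetectionRegion(self.center_column, self.region_width_px,
                               self.row_bottom, self.row_top)


def tanks_in_series_E(spec: TanksInSeriesSpec, t) -> np.ndarray:
    """Tanks-in-series RTD density.

    ``E(t) = (N/t_m)^N t^(N-1) exp(-N t / t_m) / (N-1)!`` — a gamma
    density with shape N and scale ``t_m / N``; mean ``t_m`` and
    dimensionless variance ``1/N``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    return stats.gamma.pdf(t, a=spec.n_tanks, scale=spec.t_m_true / spec.n_tanks)


def synthetic_concentration_calibration(blank_lstar: float = 85.0,
                                        slope: float = -0.05) -> LinearCalibration:
    """A concentration-L* line whose zero sits at the blank lightness.

    The intercept is ``-slope * blank_lstar`` so tracer-free granules
    read exactly C = 0 and the blank-corrected darkness stays strictly
    proportional to concentration.  The gentle default slope (0.05 wt%
    per L* unit) spreads the working concentration range over tens of L*
    units, so 8-bit gray quantization is negligible in round trips.
    """
    if slope >= 0:
        raise ValueError("concentration slope must be negative")
    return LinearCalibration.from_coefficients(
        slope, -slope * blank_lstar, domain=(0.0, 100.0))


def gray_for_lstar(target_lstar: float, gamma_mode: str = "paper_literal",
                   tol: float = 1e-6) -> float:
    """Invert the gray-level -> L* map by bisection.

    Finds g in [0, 1] with L*(g, g, g) = ``target_lstar``; numeric
    inversion keeps this valid for either gamma mode.
    """
    if not 0 <= target_lstar <= 100:
        raise ValueError("target L* must lie in [0, 100]")

    def lstar(g: float) -> float:
        return float(rgb_to_lab(np.array([g, g, g]), gamma_mode=gamma_mode)[0])

    lo, hi = 0.0, 1.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if lstar(mid) < target_lstar:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _paint(img: np.ndarray, gray_byte: int) -> None:
    img[...] = gray_byte


def render_tube_image(
    e_truth,
    cal: LinearCalibration,
    spec: TubeImageSpec,
    t0: float,
    t1: float,
    *,
    n_grids: int = 200,
    amplitude: float = 2.0,
    gamma_mode: str = "paper_literal",
):
    """Render (sample, blank) tube photographs from a ground-truth RTD.

    ``e_truth`` is a callable density E(t) or an array of per-grid
    values.  Per grid, the concentration ``c_i = amplitude * E_i /
    max(E)`` is mapped to a target L* through the inverted calibration
    line ``L* = (c - intercept) / slope`` and then to a gray byte via
    :func:`gray_for_lstar`.  Gaussian pixel noise (std ``spec.noise_sigma``
    gray levels) is added with ``spec.seed``; the blank is rendered at
    ``spec.blank_lstar``.

    Returns ``(sample, blank, truth)`` with uint8 H x W x 3 images and a
    truth record holding the grid times, concentrations, target L*
    values and any clipping warnings.
    """
    region = spec.region()
    intervals = divide_grid(region, n_grids)
    t, dt = times_from_collection_window(t0, t1, n_grids)
    if callable(e_truth):
        e_vals = np.asarray(e_truth(t), dtype=float)
    else:
        e_vals = np.asarray(e_truth, dtype=float)
        if e_vals.shape != t.shape:
            raise ValueError("e_truth length must match n_grids")
    if np.any(e_vals < 0) or not np.any(e_vals > 0):
        raise ValueError("e_truth must be non-negative with some mass")
    c = amplitude * e_vals / e_vals.max()

    target_lstar = (c - cal.intercept_) / cal.slope_
    clipped = (target_lstar < 0) | (target_lstar > 100)
    warnings_rec = [
        f"grid {i}: target L* {v:.2f} clipped to [0, 100]"
        for i, v in enumerate(target_lstar) if not 0 <= v <= 100
    ]
    target_lstar = np.clip(target_lstar, 0.0, 100.0)

    blank_gray = int(round(255 * gray_for_lstar(spec.blank_lstar, gamma_mode)))
    blank = np.empty((spec.height_px, spec.width_px, 3), dtype=np.uint8)
    _paint(blank, blank_gray)
    sample = blank.copy()

    # distinct target L* values are few relative to grids; cache inversions
    cache: dict[float, int] = {}
    cols = slice(region.col_start, region.col_stop)
    for (a, b), lstar in zip(intervals, target_lstar):
        key = round(float(lstar), 9)
        if key not in cache:
            cache[key] = int(round(255 * gray_for_lstar(float(lstar), gamma_mode)))
        sample[a:b, cols] = cache[key]

    rng = np.random.default_rng(spec.seed)
    if spec.noise_sigma > 0:
        for img in (sample, blank):
            noisy = img.astype(float) + rng.normal(0.0, spec.noise_sigma, img.shape)
            img[...] = np.clip(np.round(noisy), 0, 255).astype(np.uint8)

    truth = {
        "t": t,
        "dt": dt,
        "c": c,
        "target_lstar": target_lstar,
        "clipped": clipped,
        "warnings": warnings_rec,
        "t0": t0,
        "t1": t1,
        "n_grids": n_grids,
    }
    return sample, blank, truth


@dataclass(frozen=True)
class ExcursionSpec:
    """Rectangular cumulative-mass excursion: offset of ``peak`` grams
    between ``t_start`` and ``t_start + duration``."""

    t_start: float
    duration: float
    peak: float  # signed, g

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("duration must be positive")


def synth_feed_log(set_rate: float, duration: float, episodes=(),
                   noise_sigma: float = 0.0, seed: int = 0,
                   dt: float = 1.0) -> FeedLog:
    """Cumulative-mass log: set line plus rectangular excursions plus noise.

    ``episodes`` is an iterable of :class:`ExcursionSpec` (or
    ``(t_start, duration, peak)`` tuples); overlapping excursions raise.
    Deterministic under a fixed seed.
    """
    eps = [e if isinstance(e, ExcursionSpec) else ExcursionSpec(*e) for e in episodes]
    eps.sort(key=lambda e: e.t_start)
    for a, b in zip(eps, eps[1:]):
        if a.t_start + a.duration > b.t_start:
            raise ValueError("overlapping excursions")
    t = np.arange(0.0, duration + dt / 2, dt)
    mass = set_rate * t / 60.0
    for e in eps:
        inside = (t >= e.t_start) & (t < e.t_start + e.duration)
        mass = mass + np.where(inside, e.peak, 0.0)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        mass = mass + rng.normal(0.0, noise_sigma, t.shape)
    return FeedLog(t, mass, set_rate)
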