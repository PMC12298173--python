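"""Detection region, grid division and per-grid lightness profiles.

Granules collected in a glass tube are photographed once; a vertical
detection region (fixed width, default 100 px, centred on the tube axis
to dodge specular reflections) is divided into ``n`` uniform grids along
its height.  Each grid's mean lightness L* gives one point of the tracer
profile; because the tube fills bottom-up at a constant collection rate,
grid index 0 (tube bottom) corresponds to the earliest collection time.

A blank (tracer-free) photograph of the same material provides the
background: the working signal is the blank-corrected darkness
``max(0, (100 - L*_sample) - (100 - L*_blank))`` per grid.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .color import darkness_signal, normalize_rgb, rgb_to_lab

__all__ = [
    "DetectionRegion",
    "GridProfile",
    "define_region",
    "divide_grid",
    "grid_mean_lightness",
    "blank_correct",
    "EmptyRegionError",
]


class EmptyRegionError(ValueError):
    """Auto region detection found no filled rows."""


@dataclass(frozen=True)
class DetectionRegion:
    """A vertical strip of the tube image.

    ``row_bottom`` is the pixel row of the tube bottom and ``row_top``
    the row of the granule top; with the usual photo orientation the
    bottom has the larger row index.  The row range is half-open
    (``row_top`` excluded when below ``row_bottom`` and vice versa).
    """

    center_column: int
    width_px: int = 100
    row_bottom: int = 0
    row_top: int = 0

    def __post_init__(self):
        if self.width_px < 1:
            raise ValueError("width_px must be >= 1")
        if self.row_bottom == self.row_top:
            raise ValueError("row_bottom and row_top must differ")

    @property
    def height(self) -> int:
        return abs(self.row_bottom - self.row_top)

    @property
    def col_start(self) -> int:
        return self.center_column - self.width_px // 2

    @property
    def col_stop(self) -> int:
        return self.col_start + self.width_px

    def validate_against(self, image_shape) -> None:
        h, w = image_shape[0], image_shape[1]
        if not (0 <= min(self.row_bottom, self.row_top)
                and max(self.row_bottom, self.row_top) <= h):
            raise ValueError("region rows outside image bounds")
        if not (0 <= self.col_start and self.col_stop <= w):
            raise ValueError("region columns outside image bounds")


@dataclass
class GridProfile:
    """Ordered per-grid lightness profile; index 0 = tube bottom."""

    mean_lstar: np.ndarray
    signal: np.ndarray
    intervals: list = field(default_factory=list)
    corrected: bool = False

    def __post_init__(self):
        self.mean_lstar = np.asarray(self.mean_lstar, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.mean_lstar.shape != self.signal.shape:
            raise ValueError("mean_lstar and signal lengths differ")

    @property
    def n_grids(self) -> int:
        return len(self.mean_lstar)

    @property
    def has_tracer(self) -> bool:
        return bool(np.any(self.signal > 0))

    def to_frame(self) -> pd.DataFrame:
        if self.intervals:
            starts = [a for a, _ in self.intervals]
            ends = [b for _, b in self.intervals]
        else:
            starts = ends = [np.nan] * self.n_grids
        return pd.DataFrame(
            {
                "grid_index": np.arange(self.n_grids),
                "row_start": starts,
                "row_end": ends,
                "mean_lstar": self.mean_lstar,
                "signal": self.signal,
            }
        )

    def to_csv(self, path_or_buf) -> None:
        self.to_frame().to_csv(path_or_buf, index=False)

    @classmethod
    def from_csv(cls, path_or_buf) -> "GridProfile":
        df = pd.read_csv(path_or_buf)
        intervals = []
        if df["row_start"].notna().all():
            intervals = list(zip(df["row_start"].astype(int), df["row_end"].astype(int)))
        return cls(df["mean_lstar"].to_numpy(), df["signal"].to_numpy(), intervals)

    def to_csv_string(self) -> str:
        buf = io.StringIO()
        self.to_csv(buf)
        return buf.getvalue()


def define_region(
    img,
    center_column: int,
    width_px: int = 100,
    row_bottom: int | None = None,
    row_top: int | None = None,
    *,
    blank=None,
    gamma_mode: str = "paper_literal",
    fill_threshold: float = 2.0,
    min_run: int = 3,
) -> DetectionRegion:
    """Define the detection region, manually or automatically.

    Manual mode: pass both ``row_bottom`` and ``row_top``.  Auto mode
    (``row_top`` omitted, ``blank`` image required): the granule top is
    the topmost row whose blank-corrected row-mean darkness exceeds
    ``fill_threshold`` for at least ``min_run`` consecutive rows, which
    makes the detection robust to isolated noisy rows.
    """
    img = normalize_rgb(np.asarray(img))
    h = img.shape[0]
    if row_bottom is None:
        row_bottom = h
    if row_top is not None:
        region = DetectionRegion(center_column, width_px, row_bottom, row_top)
        region.validate_against(img.shape)
        return region

    if blank is None:
        raise ValueError("auto region detection requires a blank image")
    blank = normalize_rgb(np.asarray(blank))
    col_start = center_column - width_px // 2
    col_stop = col_start + width_px
    if col_start < 0 or col_stop > img.shape[1]:
        raise ValueError("region columns outside image bounds")
    cols = slice(col_start, col_stop)
    dark_sample = darkness_signal(rgb_to_lab(img[:, cols], gamma_mode=gamma_mode)).mean(axis=1)
    dark_blank = darkness_signal(rgb_to_lab(blank[:, cols], gamma_mode=gamma_mode)).mean(axis=1)
    corrected = np.clip(dark_sample - dark_blank, 0.0, None)
    filled = corrected > fill_threshold

    # scan from the granule-top side towards the tube bottom; the granule
    # top is the start of the first run of >= min_run filled rows
    bottom_is_high = row_bottom >= h // 2
    order = np.arange(h) if bottom_is_high else np.arange(h)[::-1]
    run = 0
    top_row = None
    for r in order:
        if filled[r]:
            run += 1
            if run >= min_run:
                # half-open bound: inclusive start row when the top is the
                # low-index end, exclusive stop row when it is the high end
                top_row = int(r) - (min_run - 1) if bottom_is_high else int(r) + min_run
                break
        else:
            run = 0
    if top_row is None:
        raise EmptyRegionError("no filled rows found above the fill threshold")
    region = DetectionRegion(center_column, width_px, row_bottom, top_row)
    region.validate_against(img.shape)
    return region


def divide_grid(region: DetectionRegion, n: int = 200) -> list[tuple[int, int]]:
    """Divide the region height into ``n`` uniform grid row-intervals.

    Returns half-open ``(row_start, row_end)`` pairs ordered from the
    tube bottom (interval 0) to the granule top.  When the height does
    not divide evenly the remainder is distributed one extra row per
    grid starting from the bottom, so interval heights differ by at most
    one pixel.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    h = region.height
    if n > h:
        raise ValueError(f"cannot divide height {h} into {n} grids")
    base, rem = divmod(h, n)
    sizes = np.full(n, base, dtype=int)
    sizes[:rem] += 1
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    if region.row_bottom > region.row_top:
        return [
            (region.row_bottom - int(bounds[i + 1]), region.row_bottom - int(bounds[i]))
            for i in range(n)
        ]
    return [
        (region.row_bottom + int(bounds[i]), region.row_bottom + int(bounds[i + 1]))
        for i in range(n)
    ]


def grid_mean_lightness(
    img,
    region: DetectionRegion,
    intervals=None,
    gamma_mode: str = "paper_literal",
    statistic: str = "mean",
    n_grids: int = 200,
) -> GridProfile:
    """Per-grid average lightness over the region's grid rectangles.

    ``statistic`` is ``"mean"`` (default, averages out pixel noise) or
    ``"median"``.
    """
    img = normalize_rgb(np.asarray(img))
    region.validate_against(img.shape)
    if intervals is None:
        intervals = divide_grid(region, n_grids)
    cols = slice(region.col_start, region.col_stop)
    lab = rgb_to_lab(img[:, cols], gamma_mode=gamma_mode)
    l_star = lab[..., 0]
    reduce = {"mean": np.mean, "median": np.median}[statistic]
    means = np.empty(len(intervals))
    for i, (a, b) in enumerate(intervals):
        block = l_star[a:b]
        if block.size == 0:
            raise ValueError(f"grid {i} is empty (rows {a}:{b})")
        means[i] = reduce(block)
    return GridProfile(means, 100.0 - means, list(intervals))


def blank_correct(sample: GridProfile, blank) -> GridProfile:
    """Subtract the blank background darkness, clipping at zero.

    ``blank`` may be a :class:`GridProfile` (grid-by-grid correction,
    the default form) or a scalar mean darkness.  The corrected profile
    keeps the sample's raw L* values and grid ordering.
    """
    if isinstance(blank, GridProfile):
        if blank.n_grids != sample.n_grids:
            raise ValueError("sample and blank grid counts differ")
        blank_sig = blank.signal
    else:
        blank_sig = float(blank)
    corrected = np.clip(sample.signal - blank_sig, 0.0, None)
    return GridProfile(sample.mean_lstar, corrected, sample.intervals, corrected=True)
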