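"""Raster image loading for tube photographs."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .color import normalize_rgb

__all__ = ["load_image"]


def load_image(source) -> np.ndarray:
    """Load an RGB raster (PNG/TIFF/JPEG) as float values in [0, 1].

    ``source`` may be a path or an already-loaded array; 8-bit input is
    scaled by 255 and 16-bit by 65535.  Alpha channels are dropped and
    single-channel grayscale is broadcast to RGB.
    """
    if isinstance(source, (str, Path)):
        arr = iio.imread(source)
    else:
        arr = np.asarray(source)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:
        arr = arr[..., :3]
    if arr.shape[-1] != 3:
        raise ValueError("expected an RGB image")
    return normalize_rgb(arr)
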