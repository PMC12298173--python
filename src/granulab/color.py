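"""RGB -> XYZ -> CIELAB conversion for image densitometry.

The tracer signal lives in the lightness channel L* of the Lab color
space: black dye lowers L*, so ``100 - L*`` (the "darkness" signal) is a
monotone proxy for tracer concentration.  The conversion goes through the
XYZ tristimulus space with the standard linear-RGB/D65 matrix; the white
point used for normalization is the row-sum white of that matrix, so a
pure-white pixel maps exactly to (L*, a*, b*) = (100, 0, 0).

Two treatments of the camera RGB values are supported:

``paper_literal``
    the 3x3 matrix is applied directly to the [0, 1]-normalized channel
    values, with no gamma decoding (the default);
``srgb_linearized``
    channels are first decoded with the sRGB electro-optical transfer
    function before the matrix product.

Because the downstream residence-time analysis is normalized and
blank-corrected, either choice is internally consistent; the default is
the literal pipeline.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "RGB_TO_XYZ",
    "D65_WHITE",
    "GAMMA_MODES",
    "companding",
    "rgb_to_xyz",
    "xyz_to_lab",
    "rgb_to_lab",
    "darkness_signal",
    "normalize_rgb",
]

#: Linear-RGB -> XYZ matrix (ITU-R BT.709 primaries, D65 white).
RGB_TO_XYZ = np.array(
    [
        [0.412453, 0.357580, 0.180423],
        [0.212671, 0.715160, 0.072169],
        [0.019334, 0.119193, 0.950227],
    ]
)

#: Reference white: image of (1, 1, 1), i.e. the row sums of the matrix.
D65_WHITE = RGB_TO_XYZ.sum(axis=1)

GAMMA_MODES = ("paper_literal", "srgb_linearized")

# cube-root / linear switch point of the Lab companding function
_DELTA = 6.0 / 29.0
_DELTA3 = _DELTA**3


def companding(t):
    """Piecewise cube-root compression used by the Lab transform.

    ``f(t) = t**(1/3)`` for ``t > (6/29)**3`` and the matched linear
    segment ``t / (3 * (6/29)**2) + 4/29`` below; continuous and strictly
    increasing on ``t >= 0``.

    Parameters
    ----------
    t : array_like
        Non-negative white-point-normalized tristimulus values.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("companding requires t >= 0")
    out = np.where(t > _DELTA3, np.cbrt(t), t / (3.0 * _DELTA**2) + 4.0 / 29.0)
    if out.ndim == 0:
        return float(out)
    return out


def _srgb_eotf(c):
    """Decode sRGB-encoded channel values to linear light."""
    c = np.asarray(c, dtype=float)
    return np.where(c <= 0.04045, c / 12.92, ((c + 0.055) / 1.055) ** 2.4)


def _check_channels(rgb):
    rgb = np.asarray(rgb, dtype=float)
    if rgb.shape[-1] != 3:
        raise ValueError("expected trailing axis of length 3 (R, G, B)")
    if np.any(rgb < 0.0) or np.any(rgb > 1.0):
        raise ValueError("RGB channels must be normalized to [0, 1]")
    return rgb


def normalize_rgb(arr):
    """Normalize an integer raster to float RGB in [0, 1].

    8-bit arrays are divided by 255, 16-bit by 65535; float input is
    validated and passed through.
    """
    arr = np.asarray(arr)
    if arr.dtype == np.uint8:
        return arr.astype(float) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(float) / 65535.0
    if np.issubdtype(arr.dtype, np.integer):
        # generic integer storage: assume 8-bit convention
        return arr.astype(float) / 255.0
    return _check_channels(arr)


def rgb_to_xyz(rgb, gamma_mode: str = "paper_literal"):
    """Convert normalized RGB (last axis of size 3) to XYZ tristimulus values."""
    rgb = _check_channels(rgb)
    if gamma_mode not in GAMMA_MODES:
        raise ValueError(f"gamma_mode must be one of {GAMMA_MODES}")
    if gamma_mode == "srgb_linearized":
        rgb = _srgb_eotf(rgb)
    return rgb @ RGB_TO_XYZ.T


def xyz_to_lab(xyz, white_point=None):
    """Convert XYZ to (L*, a*, b*).

    Tristimulus values are normalized by the reference white, compressed
    with :func:`companding`, and combined linearly:
    ``L* = 116 f(Y/Yn) - 16``, ``a* = 500 (f(X/Xn) - f(Y/Yn))``,
    ``b* = 200 (f(Y/Yn) - f(Z/Zn))``.  L* is clamped to [0, 100].
    """
    if white_point is None:
        white_point = D65_WHITE
    white_point = np.asarray(white_point, dtype=float)
    if white_point.shape != (3,) or np.any(white_point <= 0):
        raise ValueError("white_point must be three strictly positive values")
    xyz = np.asarray(xyz, dtype=float)
    if xyz.shape[-1] != 3:
        raise ValueError("expected trailing axis of length 3 (X, Y, Z)")
    f = companding(xyz / white_point)
    f = np.atleast_2d(f) if np.ndim(f) == 1 else f
    fx, fy, fz = np.moveaxis(np.asarray(f), -1, 0)
    l_star = np.clip(116.0 * fy - 16.0, 0.0, 100.0)
    a_star = 500.0 * (fx - fy)
    b_star = 200.0 * (fy - fz)
    lab = np.stack([l_star, a_star, b_star], axis=-1)
    if np.ndim(xyz) == 1:
        return lab[0]
    return lab


def rgb_to_lab(rgb, gamma_mode: str = "paper_literal", white_point=None):
    """Composed RGB -> XYZ -> Lab conversion with the default white point."""
    return xyz_to_lab(rgb_to_xyz(rgb, gamma_mode=gamma_mode), white_point=white_point)


def darkness_signal(lab):
    """Tracer darkness ``100 - L*`` from Lab values (or bare L* values).

    Accepts either an array whose trailing axis is (L*, a*, b*) or an
    array of L* values alone.
    """
    lab = np.asarray(lab, dtype=float)
    if lab.ndim >= 1 and lab.shape[-1] == 3:
        l_star = lab[..., 0]
    else:
        l_star = lab
    out = 100.0 - l_star
    if out.ndim == 0:
        return float(out)
    return out
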