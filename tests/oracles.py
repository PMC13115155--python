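"""Independent brute-force oracles used by the feature tests.

Everything here is deliberately naive: scalar per-pixel color
conversions (colorsys for HSV, single-pixel calls into the reference
colorimetry routine for CIELAB, a hand-written closed form as a second
Lab reference) and explicit per-element moment sums, so the vectorized
implementation is checked against an independent computation path.
"""

from __future__ import annotations

import colorsys
import math

import numpy as np
from skimage.color import rgb2lab


def hsv_pixel(r: int, g: int, b: int) -> tuple[float, float, float]:
    """Scalar 8-bit RGB -> (H 0-180, S 0-255, V 0-255) via colorsys."""
    h, s, v = colorsys.rgb_to_hsv(r / 255.0, g / 255.0, b / 255.0)
    return (h * 180.0, s * 255.0, v * 255.0)


def lab_pixel(r: int, g: int, b: int) -> tuple[float, float, float]:
    """Scalar 8-bit sRGB -> CIELAB via a single-pixel reference call."""
    lab = rgb2lab(np.array([[[r, g, b]]], dtype=np.float64) / 255.0)
    return tuple(float(x) for x in lab[0, 0])


def lab_pixel_closed_form(r: int, g: int, b: int) -> tuple[float, float, float]:
    """Hand-written sRGB (D65, 2 deg) -> CIELAB, independent of any library."""

    def linearize(c: float) -> float:
        c = c / 255.0
        return c / 12.92 if c <= 0.04045 else ((c + 0.055) / 1.055) ** 2.4

    rl, gl, bl = linearize(r), linearize(g), linearize(b)
    x = 0.412453 * rl + 0.357580 * gl + 0.180423 * bl
    y = 0.212671 * rl + 0.715160 * gl + 0.072169 * bl
    z = 0.019334 * rl + 0.119193 * gl + 0.950227 * bl
    xn, yn, zn = 0.95047, 1.0, 1.08883
    delta = 6.0 / 29.0

    def f(t: float) -> float:
        return t ** (1.0 / 3.0) if t > delta**3 else t / (3 * delta**2) + 4.0 / 29.0

    fx, fy, fz = f(x / xn), f(y / yn), f(z / zn)
    return (116.0 * fy - 16.0, 500.0 * (fx - fy), 200.0 * (fy - fz))


def loop_moments(values) -> tuple[float, float, float, float]:
    """Population moments by an explicit per-element loop."""
    values = [float(v) for v in values]
    n = len(values)
    mean = sum(values) / n
    m2 = sum((v - mean) ** 2 for v in values) / n
    m3 = sum((v - mean) ** 3 for v in values) / n
    m4 = sum((v - mean) ** 4 for v in values) / n
    if m2 == 0.0:
        return (mean, 0.0, 0.0, 0.0)
    return (mean, math.sqrt(m2), m3 / m2**1.5, m4 / m2**2 - 3.0)


def loop_features(image: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """The full 36-entry descriptor computed pixel by pixel."""
    coords = list(zip(*np.nonzero(mask)))
    rgb = [tuple(int(c) for c in image[i, j]) for i, j in coords]
    hsv = [hsv_pixel(*px) for px in rgb]
    lab = [lab_pixel(*px) for px in rgb]
    out: dict[str, float] = {}
    for space, chans, data in (
        ("RGB", "RGB", rgb),
        ("HSV", "HSV", hsv),
        ("LAB", "Lab", lab),
    ):
        for ci, chan in enumerate(chans):
            moments = loop_moments([px[ci] for px in data])
            for name, val in zip(("mean", "std", "skewness", "kurtosis"), moments):
                out[f"{space}_{chan}_{name}"] = val
    return out
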