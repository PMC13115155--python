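"""Color-space conversions and the 36-feature color-moment descriptor.

The descriptor summarizes the segmented sauce region by the mean,
standard deviation, skewness and excess kurtosis of each of nine color
channels — R, G, B; H, S, V; CIELAB L, a, b — giving 9 x 4 = 36 named
features.  Channel scales follow the 8-bit imaging convention: R, G, B,
S, V in [0, 255], hue in [0, 180] half-degrees (so the red wrap-around
sits at both ends of the scale), L in [0, 100], a and b signed.

Moments are population moments (divisor n); skewness is m3 / m2^1.5 and
kurtosis is m4 / m2^2 - 3 (excess), with both defined as 0 for a
zero-variance channel.  Hue is treated linearly, not circularly: the
sauce mask restricts hue to a narrow wrapped red band, but the 0/180
seam remains a known limitation for the H-channel features.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skimage.color import rgb2lab

__all__ = [
    "FEATURE_NAMES",
    "MOMENT_NAMES",
    "rgb_to_hsv",
    "rgb_to_cielab",
    "channel_moments",
    "extract_features",
    "features_table",
    "MissingRegionError",
]

MOMENT_NAMES = ("mean", "std", "skewness", "kurtosis")
_CHANNELS = (
    ("RGB", "R"), ("RGB", "G"), ("RGB", "B"),
    ("HSV", "H"), ("HSV", "S"), ("HSV", "V"),
    ("LAB", "L"), ("LAB", "a"), ("LAB", "b"),
)
#: Frozen names of the 36 descriptor entries, e.g. ``HSV_S_mean``.
FEATURE_NAMES = tuple(
    f"{space}_{chan}_{moment}" for space, chan in _CHANNELS for moment in MOMENT_NAMES
)


class MissingRegionError(ValueError):
    """Raised when a feature is requested for an empty segmented region."""


def rgb_to_hsv(pixels: np.ndarray) -> np.ndarray:
    """8-bit RGB -> HSV with H on [0, 180), S and V on [0, 255].

    Standard hexcone conversion; achromatic pixels (max = min) get hue 0,
    and S is 0 where V is 0.  Accepts any (..., 3) array.
    """
    rgb = np.asarray(pixels, dtype=np.float64)
    if rgb.shape[-1] != 3:
        raise ValueError("expected a (..., 3) RGB array")
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    mx = np.maximum(np.maximum(r, g), b)
    mn = np.minimum(np.minimum(r, g), b)
    delta = mx - mn

    with np.errstate(divide="ignore", invalid="ignore"):
        h_deg = np.where(
            delta == 0,
            0.0,
            np.where(
                mx == r,
                np.mod((g - b) / delta, 6.0),
                np.where(mx == g, (b - r) / delta + 2.0, (r - g) / delta + 4.0),
            )
            * 60.0,
        )
        s = np.where(mx == 0, 0.0, 255.0 * delta / mx)
    out = np.empty_like(rgb)
    out[..., 0] = h_deg / 2.0
    out[..., 1] = s
    out[..., 2] = mx
    return out


def rgb_to_cielab(pixels: np.ndarray) -> np.ndarray:
    """8-bit sRGB -> CIELAB under the D65 illuminant, 2-degree observer."""
    rgb = np.asarray(pixels, dtype=np.float64) / 255.0
    if rgb.shape[-1] != 3:
        raise ValueError("expected a (..., 3) RGB array")
    single = rgb.ndim == 2
    if single:  # rgb2lab wants an image-shaped array
        rgb = rgb[np.newaxis, :, :]
    lab = rgb2lab(rgb)
    return lab[0] if single else lab


def channel_moments(values) -> tuple[float, float, float, float]:
    """Population (mean, std, skewness, excess kurtosis) of a 1-D sample.

    With zero variance the higher standardized moments are undefined and
    are reported as 0 by convention.
    """
    x = np.asarray(values, dtype=np.float64).ravel()
    if x.size == 0:
        raise MissingRegionError("channel_moments: empty input (missing region)")
    mean = x.mean()
    d = x - mean
    m2 = np.mean(d**2)
    std = np.sqrt(m2)
    if m2 <= 0.0:
        return (float(mean), 0.0, 0.0, 0.0)
    m3 = np.mean(d**3)
    m4 = np.mean(d**4)
    return (float(mean), float(std), float(m3 / m2**1.5), float(m4 / m2**2 - 3.0))


def extract_features(image: np.ndarray, sauce_mask: np.ndarray) -> pd.Series:
    """The 36-entry color-moment descriptor of the masked region.

    Returns a Series indexed by :data:`FEATURE_NAMES`.  Raises
    :class:`MissingRegionError` on an empty mask, so callers can attach
    the offending sample id.
    """
    img = np.asarray(image)
    mask = np.asarray(sauce_mask, dtype=bool)
    if mask.shape != img.shape[:2]:
        raise ValueError("sauce_mask is not aligned with the image")
    if not mask.any():
        raise MissingRegionError("extract_features: empty sauce mask")
    rgb = img[mask].astype(np.float64)  # (n, 3)
    spaces = {"RGB": rgb, "HSV": rgb_to_hsv(rgb), "LAB": rgb_to_cielab(rgb)}
    out = {}
    for space, chan in _CHANNELS:
        col = {"R": 0, "G": 1, "B": 2, "H": 0, "S": 1, "V": 2, "L": 0, "a": 1, "b": 2}[chan]
        moments = channel_moments(spaces[space][:, col])
        for moment_name, val in zip(MOMENT_NAMES, moments):
            out[f"{space}_{chan}_{moment_name}"] = val
    return pd.Series(out, index=list(FEATURE_NAMES))


def features_table(images, masks, records: pd.DataFrame) -> pd.DataFrame:
    """Descriptor table: one row per sample with metadata passthrough.

    ``records`` must carry sample_id, temperature_c, time_days and label;
    images/masks are aligned with its rows.  Samples whose mask is empty
    raise :class:`MissingRegionError` naming the sample.
    """
    rows = []
    for (_, rec), img, mask in zip(records.iterrows(), images, masks):
        try:
            feats = extract_features(img, mask)
        except MissingRegionError as exc:
            raise MissingRegionError(f"sample {rec['sample_id']}: {exc}") from exc
        row = {
            "sample_id": rec["sample_id"],
            "temperature_c": rec["temperature_c"],
            "time_days": rec["time_days"],
            "label": rec["label"],
        }
        row.update(feats.to_dict())
        rows.append(row)
    return pd.DataFrame(rows)
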