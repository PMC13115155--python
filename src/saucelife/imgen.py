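"""Synthetic frozen-pizza scene and study generator with ground truth.

The study photographs this package was designed around are not publicly
deposited, so every analysis here runs on controlled synthetic stand-ins
that reproduce the statistical structure the downstream pipeline assumes:
a roughly circular product on a near-black background, a tan crust
annulus, a red-hued sauce layer whose HSV saturation follows a quadratic
trajectory over storage time, pale cheese blobs partially occluding the
sauce, and Bernoulli acceptability labels drawn from a known logistic
model in storage time and saturation.

Every generated scene carries pixel-exact ground-truth masks, so the
segmentation pipeline can be scored by Dice overlap instead of by eye.
"""

from __future__ import annotations

import colorsys
import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.transform import resize

__all__ = [
    "SceneSpec",
    "GroundTruth",
    "StudySpec",
    "StudyDataset",
    "render_pizza",
    "simulate_trajectory",
    "simulate_labels",
    "generate_study",
    "default_study_spec",
]

# Fixed palette (8-bit RGB).  The dough gap color is deliberately low
# saturation (S ~= 51) and the cheese near-achromatic (S ~= 24) so both
# fall below the sauce mask's saturation floor; the crust is a saturated
# tan that *would* pass the hue test, which is exactly why the circular
# crop stage has to exclude it.
_BACKGROUND_RGB = (10, 10, 12)
_CRUST_RGB = (170, 130, 75)
_DOUGH_RGB = (200, 190, 160)
_CHEESE_RGB = (232, 228, 210)


def _hsv8_to_rgb8(h: float, s: float, v: float) -> tuple[int, int, int]:
    """HSV on the (0-180, 0-255, 0-255) scale -> 8-bit RGB triple."""
    r, g, b = colorsys.hsv_to_rgb(h / 180.0, s / 255.0, v / 255.0)
    return (int(round(r * 255)), int(round(g * 255)), int(round(b * 255)))


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of a single rendered scene.

    Defaults emulate a standardized top-down capture: product disk of
    radius 0.45 x min(H, W) centered on a dark board, crust occupying the
    outer 15% of the radius, sauce covering 95% of the inner disk at HSV
    (5, 200, 180), six cheese blobs, mild sensor noise.
    """

    width: int = 384
    height: int = 384
    center: tuple[float, float] | None = None  # (x, y); None -> image center
    radius: float | None = None  # None -> 0.45 * min(width, height)
    crust_fraction: float = 0.15
    sauce_coverage: float = 0.95
    sauce_hue: float = 5.0  # 0-180 half-degree scale
    sauce_saturation_target: float = 200.0
    sauce_value: float = 180.0
    cheese_blob_count: int = 6
    noise_sd: float = 3.0
    seed: int = 42

    def resolved_center(self) -> tuple[float, float]:
        return self.center if self.center is not None else ((self.width - 1) / 2.0, (self.height - 1) / 2.0)

    def resolved_radius(self) -> float:
        return self.radius if self.radius is not None else 0.45 * min(self.width, self.height)

    def validate(self) -> None:
        r = self.resolved_radius()
        if r <= 0:
            raise ValueError(f"degenerate geometry: radius must be positive, got {r}")
        if r > min(self.width, self.height) / 2 - 1:
            raise ValueError(
                f"radius {r} exceeds min(width, height)/2 - 1 = {min(self.width, self.height) / 2 - 1}"
            )
        if not (0.0 <= self.crust_fraction <= 1.0):
            raise ValueError(f"crust_fraction must be in [0, 1], got {self.crust_fraction}")
        if not (0.0 <= self.sauce_coverage <= 1.0):
            raise ValueError(f"sauce_coverage must be in [0, 1], got {self.sauce_coverage}")
        if not (0.0 <= self.sauce_hue <= 180.0):
            raise ValueError(f"sauce_hue must be on the 0-180 scale, got {self.sauce_hue}")
        for name in ("sauce_saturation_target", "sauce_value"):
            val = getattr(self, name)
            if not (0.0 <= val <= 255.0):
                raise ValueError(f"{name} must be in [0, 255], got {val}")
        if self.cheese_blob_count < 0:
            raise ValueError("cheese_blob_count must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class GroundTruth:
    """Pixel-exact masks painted by the renderer, nested sauce <= roi <= foreground."""

    foreground_mask: np.ndarray  # full product disk (crust included)
    roi_mask: np.ndarray  # inner disk (crust excluded)
    sauce_mask: np.ndarray  # painted sauce minus cheese occlusion
    true_sauce_saturation: float  # mean HSV S of painted sauce pixels, pre-noise


def render_pizza(spec: SceneSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render one scene; deterministic for a fixed ``spec.seed``.

    Returns the 8-bit RGB image and its :class:`GroundTruth`.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    cx, cy = spec.resolved_center()
    radius = spec.resolved_radius()

    yy, xx = np.mgrid[0:h, 0:w]
    dist = np.hypot(xx - cx, yy - cy)
    foreground = dist <= radius
    inner_radius = radius * (1.0 - spec.crust_fraction)
    roi = dist <= inner_radius

    # Smooth random field thresholded at a quantile gives a blobby sauce
    # layer covering the requested fraction of the inner disk.
    lowres = rng.normal(size=(12, 12))
    field = resize(lowres, (h, w), order=3, mode="reflect", anti_aliasing=False)
    if spec.sauce_coverage <= 0.0 or not roi.any():
        painted = np.zeros_like(roi)
    elif spec.sauce_coverage >= 1.0:
        painted = roi.copy()
    else:
        thr = np.quantile(field[roi], 1.0 - spec.sauce_coverage)
        painted = roi & (field >= thr)

    cheese = np.zeros_like(roi)
    for _ in range(spec.cheese_blob_count):
        theta = rng.uniform(0, 2 * np.pi)
        rho = rng.uniform(0, 0.8) * inner_radius
        bx, by = cx + rho * np.cos(theta), cy + rho * np.sin(theta)
        a = rng.uniform(0.08, 0.18) * radius
        b = rng.uniform(0.08, 0.18) * radius
        phi = rng.uniform(0, np.pi)
        dx, dy = xx - bx, yy - by
        u = dx * np.cos(phi) + dy * np.sin(phi)
        v = -dx * np.sin(phi) + dy * np.cos(phi)
        cheese |= (u / a) ** 2 + (v / b) ** 2 <= 1.0
    cheese &= roi

    sauce = painted & ~cheese

    sauce_rgb = _hsv8_to_rgb8(spec.sauce_hue, spec.sauce_saturation_target, spec.sauce_value)
    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = _BACKGROUND_RGB
    img[foreground & ~roi] = _CRUST_RGB
    img[roi] = _DOUGH_RGB
    img[painted] = sauce_rgb
    img[cheese] = _CHEESE_RGB

    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    mx, mn = max(sauce_rgb), min(sauce_rgb)
    true_sat = 255.0 * (mx - mn) / mx if (sauce.any() and mx > 0) else float("nan")
    truth = GroundTruth(
        foreground_mask=foreground,
        roi_mask=roi,
        sauce_mask=sauce,
        true_sauce_saturation=true_sat,
    )
    return img, truth


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_trajectory(beta, times, noise_sd: float = 0.0, seed=None) -> np.ndarray:
    """Quadratic saturation trajectory S(t) = b0 + b1*t + b2*t^2 + Normal(0, sd) noise.

    Values are clipped to the 8-bit saturation scale [0, 255]; clipping is
    reported through a warning, never silent.
    """
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("storage times must be >= 0 days")
    b0, b1, b2 = beta
    s = b0 + b1 * times + b2 * times**2
    if noise_sd > 0:
        s = s + _as_rng(seed).normal(0.0, noise_sd, size=times.shape)
    n_clip = int(np.sum((s < 0) | (s > 255)))
    if n_clip:
        warnings.warn(
            f"simulate_trajectory: {n_clip} of {s.size} saturation values clipped to [0, 255]",
            stacklevel=2,
        )
        s = np.clip(s, 0.0, 255.0)
    return s


def simulate_labels(alpha, t, S, seed=None) -> np.ndarray:
    """Bernoulli acceptability labels, P(y=1) = logistic(a0 + a1*t + a2*S)."""
    t = np.asarray(t, dtype=float)
    S = np.asarray(S, dtype=float)
    if t.shape != S.shape:
        raise ValueError("t and S must have the same length")
    a0, a1, a2 = alpha
    eta = a0 + a1 * t + a2 * S
    p = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
    return (_as_rng(seed).random(size=t.shape) < p).astype(int)


@dataclass(frozen=True)
class StudySpec:
    """Design of a synthetic storage study.

    Each of ``n_samples`` frozen pizzas is assigned one storage
    temperature and one storage time; its sauce saturation target is drawn
    from that temperature's quadratic trajectory plus noise, its
    acceptability label from the logistic model in (t, S).  Per-sample
    jitter on sauce value and hue emulates batch/lighting variability that
    is unrelated to storage time.
    """

    n_samples: int = 36
    temperatures: tuple[float, ...] = (-12.0, -18.0)
    sample_temperatures: tuple[float, ...] = ()  # one entry per sample
    time_grid: tuple[float, ...] = ()  # days, one entry per sample
    trajectory_coefficients: dict = field(
        default_factory=lambda: {-12.0: (140.0, 0.9, -0.0018), -18.0: (140.0, 0.45, -0.0009)}
    )
    trajectory_noise_sd: float = 5.0
    label_coefficients: tuple[float, float, float] = (-26.0, -0.01, 0.15)
    scene: SceneSpec = field(default_factory=SceneSpec)
    value_jitter_sd: float = 25.0
    hue_jitter_sd: float = 3.0
    seed: int = 42

    def validate(self) -> None:
        if self.n_samples < 4:
            raise ValueError("n_samples must be >= 4")
        if len(self.time_grid) != self.n_samples or len(self.sample_temperatures) != self.n_samples:
            raise ValueError(
                "time_grid and sample_temperatures must each have exactly n_samples entries"
            )
        if any(t < 0 for t in self.time_grid):
            raise ValueError("storage times must be >= 0 days")
        for temp in self.sample_temperatures:
            if temp not in self.temperatures:
                raise ValueError(f"sample temperature {temp} not in declared temperatures")
            if temp not in self.trajectory_coefficients:
                raise ValueError(f"no trajectory coefficients for temperature {temp}")


def default_study_spec(seed: int = 42, n_per_temperature: int = 18, max_days: float = 200.0) -> StudySpec:
    """The default two-temperature study: 36 samples, times on [0, 200] days."""
    times = tuple(np.linspace(0.0, max_days, n_per_temperature))
    return StudySpec(
        n_samples=2 * n_per_temperature,
        sample_temperatures=(-12.0,) * n_per_temperature + (-18.0,) * n_per_temperature,
        time_grid=times + times,
        seed=seed,
    )


@dataclass
class StudyDataset:
    """Generated study: record table plus rendered images and ground truth."""

    spec: StudySpec
    records: pd.DataFrame
    images: list  # of uint8 RGB arrays, aligned with records rows
    truths: list  # of GroundTruth, aligned with records rows


def generate_study(spec: StudySpec) -> StudyDataset:
    """Simulate trajectories and labels, then render one scene per sample.

    Fully reproducible: the record table and every image are functions of
    ``spec`` (including its seed) only.
    """
    spec.validate()
    n = spec.n_samples
    rng = np.random.default_rng(spec.seed)
    t = np.asarray(spec.time_grid, dtype=float)
    temps = np.asarray(spec.sample_temperatures, dtype=float)

    eps = rng.normal(0.0, spec.trajectory_noise_sd, size=n) if spec.trajectory_noise_sd > 0 else np.zeros(n)
    u_label = rng.random(n)
    value_jitter = rng.normal(0.0, spec.value_jitter_sd, size=n)
    hue_jitter = rng.normal(0.0, spec.hue_jitter_sd, size=n)
    scene_seeds = rng.integers(0, 2**31 - 1, size=n)

    sat = np.empty(n)
    for temp, beta in spec.trajectory_coefficients.items():
        sel = temps == temp
        if not sel.any():
            continue
        b0, b1, b2 = beta
        sat[sel] = b0 + b1 * t[sel] + b2 * t[sel] ** 2
    sat = sat + eps
    n_clip = int(np.sum((sat < 0) | (sat > 255)))
    if n_clip:
        warnings.warn(f"generate_study: {n_clip} of {n} saturation targets clipped to [0, 255]")
        sat = np.clip(sat, 0.0, 255.0)

    a0, a1, a2 = spec.label_coefficients
    p = 1.0 / (1.0 + np.exp(-(a0 + a1 * t + a2 * sat)))
    y = (u_label < p).astype(int)

    images, truths, rows = [], [], []
    for i in range(n):
        scene = dataclasses.replace(
            spec.scene,
            sauce_saturation_target=float(sat[i]),
            sauce_value=float(np.clip(spec.scene.sauce_value + value_jitter[i], 120.0, 230.0)),
            sauce_hue=float(np.clip(spec.scene.sauce_hue + hue_jitter[i], 1.0, 14.0)),
            seed=int(scene_seeds[i]),
        )
        img, truth = render_pizza(scene)
        images.append(img)
        truths.append(truth)
        rows.append(
            {
                "sample_id": f"S{i + 1:03d}",
                "temperature_c": float(temps[i]),
                "time_days": float(t[i]),
                "true_saturation": float(sat[i]),
                "label": int(y[i]),
            }
        )
    records = pd.DataFrame(rows)
    return StudyDataset(spec=spec, records=records, images=images, truths=truths)
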