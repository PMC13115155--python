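"""Disk formats: 8-bit PNG images, 0/255 mask PNGs, CSV tables, YAML manifests."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from .imgen import SceneSpec, StudyDataset, StudySpec
from .segment import SegmentationParams

__all__ = [
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "write_study",
    "spec_to_dict",
    "study_spec_from_dict",
    "segmentation_params_from_dict",
    "write_manifest",
]


def read_image(path) -> np.ndarray:
    img = iio.imread(path)
    if img.ndim == 3 and img.shape[2] == 4:
        img = img[..., :3]
    if img.ndim != 3 or img.shape[2] != 3 or img.dtype != np.uint8:
        raise ValueError(f"{path}: expected an 8-bit RGB PNG")
    return img


def write_image(path, image: np.ndarray) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, np.asarray(image, dtype=np.uint8))


def read_mask(path) -> np.ndarray:
    arr = iio.imread(path)
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel mask PNG")
    return arr > 127


def write_mask(path, mask: np.ndarray) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, (np.asarray(mask, dtype=bool) * np.uint8(255)))


def _tuples_to_lists(obj):
    if isinstance(obj, dict):
        return {k: _tuples_to_lists(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_tuples_to_lists(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def spec_to_dict(spec) -> dict:
    """Dataclass spec -> plain YAML/JSON-serializable dict."""
    return _tuples_to_lists(dataclasses.asdict(spec))


def _scene_from_dict(d: dict) -> SceneSpec:
    d = dict(d)
    if d.get("center") is not None:
        d["center"] = tuple(d["center"])
    return SceneSpec(**d)


def study_spec_from_dict(d: dict) -> StudySpec:
    """Inverse of :func:`spec_to_dict` for :class:`StudySpec` (lossless round-trip)."""
    d = dict(d)
    d["temperatures"] = tuple(d["temperatures"])
    d["sample_temperatures"] = tuple(d["sample_temperatures"])
    d["time_grid"] = tuple(d["time_grid"])
    d["label_coefficients"] = tuple(d["label_coefficients"])
    d["trajectory_coefficients"] = {
        float(k): tuple(v) for k, v in d["trajectory_coefficients"].items()
    }
    d["scene"] = _scene_from_dict(d["scene"])
    return StudySpec(**d)


def segmentation_params_from_dict(d: dict) -> SegmentationParams:
    d = dict(d)
    for key in ("hue_low_interval", "hue_high_interval"):
        d[key] = tuple(d[key])
    if d.get("init_rect") is not None:
        d["init_rect"] = tuple(d["init_rect"])
    return SegmentationParams(**d)


def write_study(dataset: StudyDataset, outdir, write_truth_masks: bool = True) -> Path:
    """Write a generated study: images/, truth masks, records.csv, manifest.yaml."""
    outdir = Path(outdir)
    records = dataset.records.copy()
    paths = []
    for sid, img, truth in zip(records["sample_id"], dataset.images, dataset.truths):
        rel = f"images/{sid}.png"
        write_image(outdir / rel, img)
        if write_truth_masks:
            write_mask(outdir / f"truth/{sid}_foreground.png", truth.foreground_mask)
            write_mask(outdir / f"truth/{sid}_roi.png", truth.roi_mask)
            write_mask(outdir / f"truth/{sid}_sauce.png", truth.sauce_mask)
        paths.append(rel)
    records["image_path"] = paths
    records.to_csv(outdir / "records.csv", index=False)
    manifest = {"study_spec": spec_to_dict(dataset.spec)}
    (outdir / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    return outdir


def write_manifest(path, config_dict: dict, seed: int | None = None) -> None:
    """Run manifest: canonical config hash, seed, package version."""
    from . import __version__

    canonical = json.dumps(_tuples_to_lists(config_dict), sort_keys=True)
    manifest = {
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
        "seed": seed,
        "saucelife_version": __version__,
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(yaml.safe_dump(manifest, sort_keys=True))
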