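"""File I/O, run configuration, and dataset-generation driver.

Generated datasets are written as 8-bit grayscale PNGs with a ``labels.csv``
(columns: filename, feature, id, x, y, absent; coordinates in the
full-resolution image frame, 0-based pixel centers), optional mask PNGs, and
a ``manifest.json`` recording the seed, pipeline, resolved configuration and
counts, so every run is reproducible from its output directory alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .pipelines import (
    ConstellationConfig,
    EDS2019Config,
    HighResCRConfig,
    HighResPupilConfig,
    LabeledImage,
    gen_chugh_scene,
    gen_cr_scene,
    gen_eds2019_scene,
    gen_eds2020_scene,
    gen_pupil_scene,
)

__all__ = [
    "RunConfig",
    "PIPELINES",
    "write_png",
    "read_png",
    "scene_to_dict",
    "scene_from_dict",
    "save_scene_yaml",
    "load_scene_yaml",
    "run_generate",
    "run_eval",
]


def write_png(path, pixels: np.ndarray) -> None:
    """Write a [0, 1] or uint8 image as 8-bit grayscale PNG."""
    arr = np.asarray(pixels)
    if arr.dtype != np.uint8:
        arr = np.round(np.clip(arr, 0.0, 1.0) * 255.0).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(Path(path))


def read_png(path) -> np.ndarray:
    """Read an 8-bit grayscale PNG as a uint8 array."""
    return np.asarray(Image.open(Path(path)).convert("L"))


# ---------------------------------------------------------------------------
# scene serialization (YAML/JSON-safe dicts) for reproducible rendering

from .render import (  # noqa: E402  (grouped with their use)
    FrozenCollarette,
    GaussianFeature,
    GradientBackground,
    SceneSpec,
    SoftEdgeEllipse,
    SplitLineBackground,
    UniformBackground,
)

_SCENE_TYPES = {
    cls.__name__: cls
    for cls in (
        GaussianFeature, SoftEdgeEllipse, FrozenCollarette,
        UniformBackground, SplitLineBackground, GradientBackground,
    )
}


def _plain(v):
    if isinstance(v, (tuple, list)):
        return [_plain(x) for x in v]
    if isinstance(v, np.floating):
        return float(v)
    if isinstance(v, np.integer):
        return int(v)
    return v


def _obj_to_dict(obj) -> dict:
    d = {"type": type(obj).__name__}
    for k, v in dataclasses.asdict(obj).items():
        d[k] = _plain(v)
    return d


def _obj_from_dict(d: dict):
    d = dict(d)
    cls = _SCENE_TYPES[d.pop("type")]
    if cls is FrozenCollarette and "radii" in d:
        d["radii"] = tuple(d["radii"])
    return cls(**d)


def scene_to_dict(spec: SceneSpec) -> dict:
    """A JSON/YAML-safe description of a scene (pure data, no arrays)."""
    return {
        "width": spec.width,
        "height": spec.height,
        "sigma_n": spec.sigma_n,
        "background": _obj_to_dict(spec.background),
        "layers": [_obj_to_dict(layer) for layer in spec.layers],
    }


def scene_from_dict(d: dict) -> SceneSpec:
    return SceneSpec(
        width=d["width"], height=d["height"], sigma_n=d["sigma_n"],
        background=_obj_from_dict(d["background"]),
        layers=tuple(_obj_from_dict(x) for x in d["layers"]),
    )


def save_scene_yaml(spec: SceneSpec, path) -> None:
    Path(path).write_text(yaml.safe_dump(scene_to_dict(spec), sort_keys=True))


def load_scene_yaml(path) -> SceneSpec:
    return scene_from_dict(yaml.safe_load(Path(path).read_text()))


def _pipeline_factory(name: str, stage: int, overrides: dict):
    if name in ("cr500", "cr1000"):
        cfg = HighResCRConfig.for_variant(name[2:], stage=stage, **overrides)
        return cfg, lambda rng: gen_cr_scene(cfg, rng)
    if name in ("pupil500", "pupil1000"):
        cfg = HighResPupilConfig.for_variant(name[5:], stage=stage, **overrides)
        return cfg, lambda rng: gen_pupil_scene(cfg, rng)
    if name == "eds2019":
        cfg = EDS2019Config(**overrides)
        return cfg, lambda rng: gen_eds2019_scene(cfg, rng)
    if name == "chugh":
        cfg = ConstellationConfig.chugh(stage=stage, **overrides)
        return cfg, lambda rng: gen_chugh_scene(cfg, rng=rng)
    if name == "eds2020":
        cfg = ConstellationConfig.eds2020(stage=stage, **overrides)
        return cfg, lambda rng: gen_eds2020_scene(cfg, rng=rng)
    raise ValueError(f"unknown pipeline {name!r}")


PIPELINES = ("cr500", "cr1000", "pupil500", "pupil1000", "eds2019", "chugh", "eds2020")


@dataclass(frozen=True)
class RunConfig:
    """One dataset-generation run."""

    pipeline: str
    stage: int = 1
    n: int = 10
    seed: int = 0
    out_dir: str = "."
    overrides: Optional[dict] = None

    def __post_init__(self) -> None:
        if self.pipeline not in PIPELINES:
            raise ValueError(
                f"unknown pipeline {self.pipeline!r}; choose from {PIPELINES}"
            )
        if self.stage not in (1, 2):
            raise ValueError("stage must be 1 or 2")


def _labels_rows(filename: str, labeled: LabeledImage) -> list[dict]:
    rows = []
    if labeled.pupil_center is not None:
        rows.append({
            "filename": filename, "feature": "pupil", "id": 0,
            "x": labeled.pupil_center[0], "y": labeled.pupil_center[1],
            "absent": 0,
        })
    for cr in labeled.cr_labels:
        rows.append({
            "filename": filename, "feature": "cr", "id": cr.identity,
            "x": cr.x, "y": cr.y, "absent": int(cr.absent),
        })
    return rows


def run_generate(cfg: RunConfig) -> dict:
    """Generate a labeled dataset; returns the manifest.

    Image ``i`` is drawn from its own counter-indexed random substream, so
    the dataset content depends only on (seed, pipeline, stage, n).
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    overrides = dict(cfg.overrides or {})
    pipeline_cfg, gen = _pipeline_factory(cfg.pipeline, cfg.stage, overrides)

    rows: list[dict] = []
    n_masks = 0
    for i in range(cfg.n):
        rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), i]))
        labeled = gen(rng)
        filename = f"{cfg.pipeline}_s{cfg.stage}_{i:06d}.png"
        write_png(out / filename, labeled.image.pixels)
        for mask_name, mask in labeled.masks.items():
            write_png(out / f"{Path(filename).stem}_{mask_name}_mask.png",
                      mask.astype(np.uint8) * 255)
            n_masks += 1
        rows.extend(_labels_rows(filename, labeled))
    pd.DataFrame(rows, columns=["filename", "feature", "id", "x", "y", "absent"]) \
        .to_csv(out / "labels.csv", index=False)

    cfg_dict = dataclasses.asdict(pipeline_cfg)
    cfg_yaml = yaml.safe_dump(cfg_dict, sort_keys=True)
    (out / "config.yaml").write_text(cfg_yaml)
    manifest = {
        "pipeline": cfg.pipeline,
        "stage": cfg.stage,
        "n_images": cfg.n,
        "n_masks": n_masks,
        "seed": cfg.seed,
        "config_sha256": hashlib.sha256(cfg_yaml.encode()).hexdigest(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def run_eval(
    pred_csv, truth_csv, thresholds: tuple[float, ...] = (2.0, 5.0),
    scale: float = 1.0,
) -> dict:
    """Compare predicted and ground-truth feature centers.

    Both CSVs must have columns filename, feature, id, x, y; rows are joined
    on (filename, feature, id).  Reports the mean pixel error (predictions
    upscaled by ``scale``) and cumulative detection rates at the given
    pixel thresholds.
    """
    from .metrics import cumulative_detection_rate, mean_pixel_error

    keys = ["filename", "feature", "id"]
    pred = pd.read_csv(pred_csv)
    truth = pd.read_csv(truth_csv)
    if "absent" in truth.columns:
        truth = truth[truth["absent"] == 0]
    merged = truth.merge(pred, on=keys, suffixes=("_true", "_pred"), how="left")
    if merged["x_pred"].isna().all():
        raise ValueError("no matching prediction rows (key mismatch?)")
    p = merged[["x_pred", "y_pred"]].to_numpy()
    t = merged[["x_true", "y_true"]].to_numpy()
    mpe = mean_pixel_error(p, t, scale=scale)
    err = np.hypot(p[:, 0] * scale - t[:, 0], p[:, 1] * scale - t[:, 1])
    err = err[np.isfinite(err)]
    rates = cumulative_detection_rate(err, thresholds)
    return {
        "n_pairs": int(len(err)),
        "mean_pixel_error": mpe,
        **{f"detection_rate_{t}px": float(r) for t, r in zip(thresholds, rates)},
    }
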