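"""Desk-scale training harness on streamed synthetic images.

Models are trained the way the generators are meant to be used: every batch
is freshly generated, shown once, and discarded, so no image is ever reused
and the training distribution is the generator itself.  A small
center-regression CNN (trained on second-stage single-CR scenes, where the
feature center lies within 0.75 px of the image center and the regression
target is the offset from the image center) demonstrates sub-pixel feature
localization at desk scale.  The full-scale architectures used for real
eye-tracking work (seven-conv-layer CR/pupil CNNs, residual heatmap U-Nets)
are recorded as declarative configurations.

Two-stage training follows the curriculum idea: a first stage on broad
"hard" parameter distributions, then a second stage at a much lower learning
rate on distributions closer to the target setup, with early convolutional
layers frozen.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterator, Optional, Sequence

import numpy as np

from .nn import Adam, Conv2D, Dense, Flatten, MaxPool2, ReLU, Sequential, mae_loss, mse_loss
from .pipelines.base import PlacementError
from .pipelines.highres import HighResCRConfig, gen_cr_scene

__all__ = [
    "ModelSpec",
    "StreamSpec",
    "StageConfig",
    "TrainConfig",
    "DEMO_CENTER_REGRESSOR",
    "CR_CNN_SPEC",
    "PUPIL_CNN_500_SPEC",
    "PUPIL_CNN_1000_SPEC",
    "VR_UNET_CONFIG",
    "build_model",
    "stream_batches",
    "make_heatmap_targets",
    "train_two_stage",
    "evaluate_synthetic",
    "make_cr_demo_generator",
    "run_demo_training",
]

# image sample -> (HxWx1 float32 image, target vector) pair
SampleFn = Callable[[np.random.Generator], tuple[np.ndarray, np.ndarray]]


@dataclass(frozen=True)
class ModelSpec:
    """Declarative CNN architecture: conv widths (3x3 kernels, ReLU),
    2x2 max pooling after every conv layer (``pool="every"``) or after every
    second one (``pool="every_second"``), then dense layers and a linear
    output head."""

    name: str
    input_size: int
    conv_widths: tuple[int, ...]
    dense_widths: tuple[int, ...]
    n_outputs: int = 2
    pool: str = "every_second"


# The demo pools after every conv layer, which keeps single-CPU epochs short
# while retaining sub-pixel regression capacity.
DEMO_CENTER_REGRESSOR = ModelSpec(
    name="demo-center-regressor", input_size=64,
    conv_widths=(16, 32, 64, 64), dense_widths=(64,), n_outputs=2,
    pool="every",
)

# Reference configurations of the full-scale feature-localization CNNs
# (documented shapes; training them is outside the desk-scale demo).
CR_CNN_SPEC = ModelSpec(
    name="cr-cnn", input_size=180,
    conv_widths=(64, 64, 128, 128, 256, 256, 512), dense_widths=(64, 32),
)
PUPIL_CNN_500_SPEC = ModelSpec(
    name="pupil-cnn-500", input_size=180,
    conv_widths=(64, 64, 128, 128, 256, 256, 512), dense_widths=(64, 64),
)
PUPIL_CNN_1000_SPEC = ModelSpec(
    name="pupil-cnn-1000", input_size=180,
    conv_widths=(128, 128, 256, 256, 512, 512, 768), dense_widths=(64, 64),
)

# Residual heatmap U-Net used for the constellation tasks (config only).
VR_UNET_CONFIG = {
    "encoder_residual_modules": 6,
    "decoder_residual_modules": 6,
    "channels": 256,
    "output": "one heatmap per feature (pupil + one per CR identity)",
    "loss": "bce + dice + focal (optional bce weight 100)",
    "optimizer": "adamw, initial lr 1e-4, exponential decay",
}


def build_model(spec: ModelSpec, rng: np.random.Generator) -> Sequential:
    """Instantiate a ModelSpec as a trainable layer stack."""
    layers: list = []
    c_in = 1
    size = spec.input_size
    if spec.pool not in ("every", "every_second"):
        raise ValueError(f"unknown pooling scheme {spec.pool!r}")
    for i, width in enumerate(spec.conv_widths):
        layers.append(Conv2D(c_in, width, rng=rng))
        layers.append(ReLU())
        c_in = width
        if spec.pool == "every" or i % 2 == 1:
            layers.append(MaxPool2())
            size //= 2
    layers.append(Flatten())
    n_in = size * size * c_in
    for width in spec.dense_widths:
        layers.append(Dense(n_in, width, rng=rng))
        layers.append(ReLU())
        n_in = width
    layers.append(Dense(n_in, spec.n_outputs, rng=rng))
    return Sequential(layers)


# ---------------------------------------------------------------------------
# streaming generation


@dataclass(frozen=True)
class StreamSpec:
    """On-the-fly batch stream: each image is generated fresh from its own
    counter-indexed random substream, shown once, and discarded."""

    sample: SampleFn
    images_per_epoch: int = 1000
    batch_size: int = 16


def _sample_rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


def stream_batches(
    spec: StreamSpec, seed: int, epoch: int = 0
) -> Iterator[tuple[np.ndarray, np.ndarray]]:
    """Yield (images, targets) batches for one epoch, deterministically.

    Image ``i`` of epoch ``e`` always comes from the substream keyed by
    (seed, e, i), so content does not depend on generation order.  A
    generator placement failure retries with the next substream.
    """
    n_batches = spec.images_per_epoch // spec.batch_size
    counter = 0
    for _ in range(n_batches):
        images, targets = [], []
        while len(images) < spec.batch_size:
            rng = _sample_rng(seed, epoch, counter)
            counter += 1
            try:
                img, tgt = spec.sample(rng)
            except PlacementError:
                continue
            images.append(img)
            targets.append(tgt)
        yield np.stack(images), np.stack(targets)


def make_heatmap_targets(
    centers: Sequence[Optional[tuple[float, float]]],
    shape: tuple[int, int],
    sd: float = 1.0,
    peak: float = 1.0,
) -> np.ndarray:
    """Per-feature target maps: an isotropic Gaussian bump with the given
    peak value at the rounded feature center; absent features (``None``)
    yield all-zero maps.

    The peak value of 1 ties the training targets to the inference-side
    validity rule (a frame needs two CR heatmap maxima >= 1).
    """
    h, w = shape
    maps = np.zeros((len(centers), h, w), dtype=np.float32)
    yy, xx = np.indices((h, w), dtype=np.float64)
    for i, c in enumerate(centers):
        if c is None:
            continue
        cx, cy = round(c[0]), round(c[1])
        maps[i] = peak * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2.0 * sd**2))
    return maps


# ---------------------------------------------------------------------------
# two-stage training with early stopping


@dataclass(frozen=True)
class StageConfig:
    lr: float = 1e-4
    max_epochs: int = 20
    patience: int = 5
    frozen_layers: tuple[int, ...] = ()
    batch_size: int = 16
    images_per_epoch: int = 1000
    lr_decay: float = 0.97
    loss: str = "mse"


@dataclass(frozen=True)
class TrainConfig:
    stages: tuple[StageConfig, ...]
    val_size: int = 300

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValueError("need at least one stage")
        for a, b in zip(self.stages, self.stages[1:]):
            if b.lr > a.lr:
                raise ValueError("later stages must not raise the learning rate")


_LOSSES = {"mse": mse_loss, "mae": mae_loss}


@dataclass
class EpochRecord:
    stage: int
    epoch: int
    lr: float
    train_loss: float
    val_loss: float


def _make_val_set(sample: SampleFn, n: int, seed: int, stage: int):
    images, targets = [], []
    i = 0
    while len(images) < n:
        rng = _sample_rng(seed, 900000 + stage, i)
        i += 1
        try:
            img, tgt = sample(rng)
        except PlacementError:
            continue
        images.append(img)
        targets.append(tgt)
    return np.stack(images), np.stack(targets)


def train_two_stage(
    model: Sequential,
    cfg: TrainConfig,
    stage_samplers: Sequence[SampleFn],
    seed: int,
) -> list[EpochRecord]:
    """Train through the configured stages with early stopping.

    Each stage streams fresh batches, validates on a pre-generated fixed
    synthetic set after every epoch, decays the learning rate exponentially
    per epoch, stops once the validation loss has not improved for
    ``patience`` consecutive epochs, and restores the stage-best weights.
    Frozen-layer lists are applied at stage start.
    """
    if len(stage_samplers) != len(cfg.stages):
        raise ValueError("one sampler per stage required")
    history: list[EpochRecord] = []
    for s_idx, (stage, sample) in enumerate(zip(cfg.stages, stage_samplers), start=1):
        model.set_frozen(stage.frozen_layers)
        loss_fn = _LOSSES[stage.loss]
        val_x, val_y = _make_val_set(sample, cfg.val_size, seed, s_idx)
        opt = Adam(model, lr=stage.lr)
        stream = StreamSpec(
            sample=sample, images_per_epoch=stage.images_per_epoch,
            batch_size=stage.batch_size,
        )
        best_val = np.inf
        best_weights = model.get_weights()
        bad_epochs = 0
        for epoch in range(1, stage.max_epochs + 1):
            opt.lr = stage.lr * stage.lr_decay ** (epoch - 1)
            train_losses = []
            for xb, yb in stream_batches(stream, seed, epoch=s_idx * 1000 + epoch):
                pred = model.forward(xb.astype(np.float32))
                loss, grad = loss_fn(pred, yb.astype(np.float32))
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite training loss at stage {s_idx} epoch {epoch}"
                    )
                model.backward(grad)
                opt.step()
                train_losses.append(loss)
            val_loss = _eval_loss(model, val_x, val_y, loss_fn, stage.batch_size)
            history.append(EpochRecord(
                stage=s_idx, epoch=epoch, lr=opt.lr,
                train_loss=float(np.mean(train_losses)), val_loss=val_loss,
            ))
            if val_loss < best_val:
                best_val = val_loss
                best_weights = model.get_weights()
                bad_epochs = 0
            else:
                bad_epochs += 1
                if bad_epochs >= stage.patience:
                    break
        model.set_weights(best_weights)
    return history


def _eval_loss(model, x, y, loss_fn, batch_size) -> float:
    losses = []
    for i in range(0, len(x), batch_size):
        pred = model.forward(x[i : i + batch_size].astype(np.float32))
        loss, _ = loss_fn(pred, y[i : i + batch_size].astype(np.float32))
        losses.append(loss * len(pred))
    return float(np.sum(losses) / len(x))


# ---------------------------------------------------------------------------
# demo: sub-pixel CR localization


def make_cr_demo_generator(
    size: int = 64, variant: str = "500", stage: int = 2
) -> SampleFn:
    """Sampler producing (image, center-offset target) pairs from the
    second-stage single-CR pipeline on a small canvas."""
    cfg = HighResCRConfig.for_variant(variant, stage=stage, width=size, height=size)
    cx, cy = (size - 1) / 2.0, (size - 1) / 2.0

    def sample(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        scene = gen_cr_scene(cfg, rng)
        img = (scene.image.pixels - 0.5).astype(np.float32)[..., None]
        label = scene.cr_labels[0]
        return img, np.array([label.x - cx, label.y - cy], dtype=np.float32)

    return sample


def evaluate_synthetic(
    model: Sequential, sample: SampleFn, n: int, seed: int,
    batch_size: int = 64,
) -> dict:
    """Localization-error statistics on freshly generated held-out images."""
    x, y = _make_val_set(sample, n, seed, stage=777)
    preds = []
    for i in range(0, n, batch_size):
        preds.append(model.forward(x[i : i + batch_size]))
    pred = np.concatenate(preds)
    err = np.hypot(pred[:, 0] - y[:, 0], pred[:, 1] - y[:, 1])
    return {
        "n": int(n),
        "median_px": float(np.median(err)),
        "mean_px": float(np.mean(err)),
        "rate_le_1px": float(np.mean(err <= 1.0)),
        "rate_le_2px": float(np.mean(err <= 2.0)),
        "rate_le_5px": float(np.mean(err <= 5.0)),
    }


def run_demo_training(
    seed: int,
    size: int = 64,
    variant: str = "500",
    epochs: int = 20,
    images_per_epoch: int = 1000,
    batch_size: int = 16,
    patience: int = 6,
    lr: float = 1e-3,
    n_eval: int = 500,
) -> tuple[Sequential, list[EpochRecord], dict]:
    """Train the demo center-regressor on streamed stage-2 CR images and
    evaluate it on fresh held-out synthetic images.

    Returns (model, history, evaluation statistics).
    """
    sample = make_cr_demo_generator(size=size, variant=variant)
    spec = ModelSpec(
        name=DEMO_CENTER_REGRESSOR.name, input_size=size,
        conv_widths=DEMO_CENTER_REGRESSOR.conv_widths,
        dense_widths=DEMO_CENTER_REGRESSOR.dense_widths,
        pool=DEMO_CENTER_REGRESSOR.pool,
    )
    model = build_model(spec, np.random.default_rng(seed))
    cfg = TrainConfig(
        stages=(StageConfig(
            lr=lr, max_epochs=epochs, patience=patience,
            batch_size=batch_size, images_per_epoch=images_per_epoch,
        ),),
        val_size=300,
    )
    history = train_two_stage(model, cfg, [sample], seed)
    stats = evaluate_synthetic(model, sample, n_eval, seed)
    return model, history, stats
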