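"""Shared label container and sampling utilities for the synthetic pipelines."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ..render import RenderedImage

__all__ = [
    "CRLabel",
    "LabeledImage",
    "PlacementError",
    "sample_uniform",
    "sample_log_uniform",
    "sample_exponential_luminance",
    "sample_weibull_luminance",
    "sample_normal_luminance",
    "image_center",
    "noise_seed_from",
]


class PlacementError(RuntimeError):
    """Raised when a rejection-sampling placement loop exhausts its budget."""


@dataclass(frozen=True)
class CRLabel:
    """One corneal-reflection label: identity index, center, presence flag."""

    identity: int
    x: float
    y: float
    absent: bool = False


@dataclass
class LabeledImage:
    """A rendered image together with its ground-truth labels.

    ``image`` is ``None`` when the generator ran in label-only mode (used for
    fast distributional checks over many draws).  ``params`` records the
    sampled scalar parameters of the draw for inspection and testing.
    """

    image: Optional[RenderedImage]
    pupil_center: Optional[tuple[float, float]] = None
    cr_labels: list[CRLabel] = field(default_factory=list)
    masks: dict[str, np.ndarray] = field(default_factory=dict)
    valid: bool = True
    params: dict = field(default_factory=dict)

    @property
    def cr_centers(self) -> list[tuple[float, float, int]]:
        """Present CR centers as (x, y, identity) tuples."""
        return [(c.x, c.y, c.identity) for c in self.cr_labels if not c.absent]


def sample_uniform(rng: np.random.Generator, rng_lo_hi) -> float:
    lo, hi = rng_lo_hi
    return float(rng.uniform(lo, hi))


def sample_log_uniform(rng: np.random.Generator, rng_lo_hi) -> float:
    """Log-uniform draw, used for Gaussian amplitudes spanning decades."""
    lo, hi = rng_lo_hi
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def sample_exponential_luminance(
    rng: np.random.Generator, scale: float = 10.0, offset: float = 1.0,
    upper: float = 255.0,
) -> float:
    """Exponential(scale) + offset, resampled until it fits the 8-bit range."""
    while True:
        v = float(rng.exponential(scale) + offset)
        if v <= upper:
            return v


def sample_weibull_luminance(
    rng: np.random.Generator, shape: float = 2.0, scale: float = 25.0,
    offset: float = 18.0, upper: float = 255.0,
) -> float:
    """Weibull(shape)*scale + offset, resampled until within the 8-bit range."""
    while True:
        v = float(rng.weibull(shape) * scale + offset)
        if v <= upper:
            return v


def sample_normal_luminance(
    rng: np.random.Generator, mean: float, sd: float
) -> float:
    """Normal luminance clipped into [0, 255]."""
    return float(np.clip(rng.normal(mean, sd), 0.0, 255.0))


def image_center(width: int, height: int) -> tuple[float, float]:
    """Center of the canvas in pixel-center coordinates."""
    return ((width - 1) / 2.0, (height - 1) / 2.0)


def noise_seed_from(rng: np.random.Generator) -> int:
    """Draw a noise seed for compose_scene from the pipeline rng."""
    return int(rng.integers(0, 2**31 - 1))
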