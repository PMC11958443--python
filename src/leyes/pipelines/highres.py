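"""Synthetic pipelines for high-resolution (desk-mounted camera) eye images.

Two families of generators, each in a 500-Hz and 1000-Hz variant:

* CR scenes: one circular bright corneal reflection on a background split by
  a randomly oriented straight line (the pupil-iris border) that passes close
  to the CR.  One side of the line is dark (exponential pupil luminance), the
  other is iris grey.
* Pupil scenes: one dark elliptical pupil plus one to four bright CRs that
  may overlap the pupil, on a uniform iris-grey background.

Each pipeline has a second-stage variant in which the labeled feature center
is constrained to a 1.5-px span around the image center (and, for pupil
scenes, exactly one CR is generated), used for the fine-tuning stage of the
two-stage training regime.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from ..render import (
    GaussianFeature,
    SceneSpec,
    SplitLineBackground,
    UniformBackground,
    compose_scene,
)
from .base import (
    CRLabel,
    LabeledImage,
    PlacementError,
    image_center,
    noise_seed_from,
    sample_exponential_luminance,
    sample_log_uniform,
    sample_uniform,
)

__all__ = [
    "HighResCRConfig",
    "HighResPupilConfig",
    "gen_cr_scene",
    "gen_pupil_scene",
    "sample_nonoverlapping_crs",
]


@dataclass(frozen=True)
class HighResCRConfig:
    """Parameter ranges for the single-CR scenes.

    Defaults follow the 500-Hz variant: circular CRs with plateau radius in
    [1, 30] px, amplitude in [2, 20000] (log-uniform), full-white luminance,
    iris grey fixed at 128, pupil-side luminance exponential(10)+1, and pixel
    noise sigma in [0, 30].  The 1000-Hz variant draws the iris grey from
    [32, 153] instead.
    """

    width: int = 180
    height: int = 180
    r_range: tuple[float, float] = (1.0, 30.0)
    amp_range: tuple[float, float] = (2.0, 20000.0)
    l_cr: float = 255.0
    iris_lum: tuple[float, float] = (128.0, 128.0)
    pupil_lum_scale: float = 10.0
    pupil_lum_offset: float = 1.0
    noise_range: tuple[float, float] = (0.0, 30.0)
    stage: int = 1
    center_halfspan: float = 0.75
    line_dist_factor: float = 2.0

    @classmethod
    def for_variant(cls, variant: str, stage: int = 1, **overrides) -> "HighResCRConfig":
        if variant not in ("500", "1000"):
            raise ValueError("variant must be '500' or '1000'")
        iris = (128.0, 128.0) if variant == "500" else (32.0, 153.0)
        overrides.setdefault("iris_lum", iris)
        return cls(stage=stage, **overrides)


@dataclass(frozen=True)
class HighResPupilConfig:
    """Parameter ranges for the pupil scenes.

    Pupil plateau minor radius in [20, 60] px with major = minor * [1.0, 1.3];
    one to four CRs with minor radius in [4, 12] and major = minor *
    [1.0, 1.1], placed anywhere subject to the pairwise separation rule.
    Iris grey in [64, 179] (500 Hz) or [32, 153] (1000 Hz).

    ``cr_clear_of_pupil`` additionally keeps CRs clear of the pupil (the same
    1.25x separation rule applied against the pupil), producing
    well-separated scenes for baseline evaluation.
    """

    width: int = 180
    height: int = 180
    pupil_minor_range: tuple[float, float] = (20.0, 60.0)
    pupil_major_factor: tuple[float, float] = (1.0, 1.3)
    pupil_amp_range: tuple[float, float] = (2.0, 20000.0)
    pupil_lum_scale: float = 10.0
    pupil_lum_offset: float = 1.0
    n_cr_range: tuple[int, int] = (1, 4)
    cr_minor_range: tuple[float, float] = (4.0, 12.0)
    cr_major_factor: tuple[float, float] = (1.0, 1.1)
    cr_amp_range: tuple[float, float] = (2.0, 20000.0)
    l_cr: float = 255.0
    iris_lum: tuple[float, float] = (64.0, 179.0)
    noise_range: tuple[float, float] = (0.0, 30.0)
    stage: int = 1
    center_halfspan: float = 0.75
    cr_clear_of_pupil: bool = False
    cr_margin: float = 0.0  # keep CR centers this far from the canvas border

    @classmethod
    def for_variant(cls, variant: str, stage: int = 1, **overrides) -> "HighResPupilConfig":
        if variant not in ("500", "1000"):
            raise ValueError("variant must be '500' or '1000'")
        iris = (64.0, 179.0) if variant == "500" else (32.0, 153.0)
        overrides.setdefault("iris_lum", iris)
        return cls(stage=stage, **overrides)


SEPARATION_FACTOR = 1.25  # min center distance as multiple of summed major radii


def _sample_center(
    rng: np.random.Generator, width: int, height: int,
    stage: int, halfspan: float,
) -> tuple[float, float]:
    if stage == 2:
        cx, cy = image_center(width, height)
        return (
            float(rng.uniform(cx - halfspan, cx + halfspan)),
            float(rng.uniform(cy - halfspan, cy + halfspan)),
        )
    return (
        float(rng.uniform(0.0, width - 1.0)),
        float(rng.uniform(0.0, height - 1.0)),
    )


def gen_cr_scene(
    cfg: HighResCRConfig, rng: np.random.Generator, render: bool = True
) -> LabeledImage:
    """Generate one single-CR scene with a split-line background.

    The dividing line's closest approach to the CR center is drawn uniformly
    from [0, line_dist_factor * r_cr]; which side of the line is dark is
    chosen with equal probability.
    """
    r = sample_uniform(rng, cfg.r_range)
    amp = sample_log_uniform(rng, cfg.amp_range)
    theta = float(rng.uniform(0.0, math.pi))
    cx, cy = _sample_center(rng, cfg.width, cfg.height, cfg.stage, cfg.center_halfspan)

    line_angle = float(rng.uniform(0.0, math.pi))
    dist = float(rng.uniform(0.0, cfg.line_dist_factor * r))
    side = float(rng.choice([-1.0, 1.0]))
    # offset the line anchor from the CR center along the line normal; the
    # sign decides which side of the line the CR lies on
    nx, ny = -math.sin(line_angle), math.cos(line_angle)
    x0, y0 = cx + side * dist * nx, cy + side * dist * ny

    l_p = sample_exponential_luminance(rng, cfg.pupil_lum_scale, cfg.pupil_lum_offset)
    l_i = sample_uniform(rng, cfg.iris_lum)
    sigma_n = sample_uniform(rng, cfg.noise_range)

    cr = GaussianFeature(
        x_c=cx, y_c=cy, r_minor=r, r_major=r, A=amp, theta=theta,
        L=cfg.l_cr, polarity="bright",
    )
    # the random sign of the anchor offset already puts the CR on either side
    # of the pupil-iris border with equal probability
    bg = SplitLineBackground(x0=x0, y0=y0, angle=line_angle, L_dark=l_p, L_light=l_i)

    spec = SceneSpec(
        width=cfg.width, height=cfg.height, background=bg,
        layers=(cr,), sigma_n=sigma_n,
    )
    image = compose_scene(spec, noise_seed_from(rng)) if render else None
    return LabeledImage(
        image=image,
        cr_labels=[CRLabel(identity=0, x=cx, y=cy)],
        params={
            "r": r, "A": amp, "L_p": l_p, "L_i": l_i, "sigma_n": sigma_n,
            "line_angle": line_angle, "line_dist": dist, "scene": spec,
        },
    )


def sample_nonoverlapping_crs(
    n: int,
    minor_range: tuple[float, float],
    major_factor: tuple[float, float],
    amp_range: tuple[float, float],
    width: int,
    height: int,
    rng: np.random.Generator,
    l_cr: float = 255.0,
    max_attempts: int = 1000,
    keepout: Optional[tuple[float, float, float]] = None,
    margin: float = 0.0,
) -> list[GaussianFeature]:
    """Place ``n`` bright CRs subject to the pairwise separation rule.

    A CR whose center is closer to another CR than 1.25 times the sum of
    their major-axis radii is removed and replaced by a fresh random CR, up
    to ``max_attempts`` replacements per CR.  ``keepout`` is an optional
    (x, y, radius) exclusion: CR centers must also be at least
    ``1.25 * (radius + cr_major)`` away from it.  ``margin`` keeps CR
    centers away from the canvas border.
    """
    if n < 1:
        raise ValueError("need n >= 1")

    def draw() -> GaussianFeature:
        mn = sample_uniform(rng, minor_range)
        mj = mn * sample_uniform(rng, major_factor)
        return GaussianFeature(
            x_c=float(rng.uniform(margin, width - 1.0 - margin)),
            y_c=float(rng.uniform(margin, height - 1.0 - margin)),
            r_minor=mn, r_major=mj,
            A=sample_log_uniform(rng, amp_range),
            theta=float(rng.uniform(0.0, math.pi)),
            L=l_cr, polarity="bright",
        )

    def violates(f: GaussianFeature, others: list[GaussianFeature]) -> bool:
        for o in others:
            if o is f:
                continue
            d = math.hypot(f.x_c - o.x_c, f.y_c - o.y_c)
            if d < SEPARATION_FACTOR * (f.r_major + o.r_major):
                return True
        if keepout is not None:
            kx, ky, kr = keepout
            if math.hypot(f.x_c - kx, f.y_c - ky) < SEPARATION_FACTOR * (kr + f.r_major):
                return True
        return False

    crs = [draw() for _ in range(n)]
    for i in range(n):
        attempts = 0
        while violates(crs[i], crs[:i]):
            attempts += 1
            if attempts > max_attempts:
                raise PlacementError(
                    f"could not place CR {i} after {max_attempts} attempts"
                )
            crs[i] = draw()
    return crs


def gen_pupil_scene(
    cfg: HighResPupilConfig, rng: np.random.Generator, render: bool = True
) -> LabeledImage:
    """Generate one pupil scene: dark pupil + N bright CRs on uniform grey."""
    p_minor = sample_uniform(rng, cfg.pupil_minor_range)
    p_major = p_minor * sample_uniform(rng, cfg.pupil_major_factor)
    p_amp = sample_log_uniform(rng, cfg.pupil_amp_range)
    p_theta = float(rng.uniform(0.0, math.pi))
    l_p = sample_exponential_luminance(rng, cfg.pupil_lum_scale, cfg.pupil_lum_offset)
    px, py = _sample_center(rng, cfg.width, cfg.height, cfg.stage, cfg.center_halfspan)

    pupil = GaussianFeature(
        x_c=px, y_c=py, r_minor=p_minor, r_major=p_major, A=p_amp,
        theta=p_theta, L=l_p, polarity="dark",
    )

    n_cr = 1 if cfg.stage == 2 else int(rng.integers(cfg.n_cr_range[0], cfg.n_cr_range[1] + 1))
    keepout = (px, py, p_major) if cfg.cr_clear_of_pupil else None
    crs = sample_nonoverlapping_crs(
        n_cr, cfg.cr_minor_range, cfg.cr_major_factor, cfg.cr_amp_range,
        cfg.width, cfg.height, rng, l_cr=cfg.l_cr, keepout=keepout,
        margin=cfg.cr_margin,
    )

    l_i = sample_uniform(rng, cfg.iris_lum)
    sigma_n = sample_uniform(rng, cfg.noise_range)
    spec = SceneSpec(
        width=cfg.width, height=cfg.height,
        background=UniformBackground(L=l_i),
        layers=(pupil, *crs), sigma_n=sigma_n,
    )
    image = compose_scene(spec, noise_seed_from(rng)) if render else None
    return LabeledImage(
        image=image,
        pupil_center=(px, py),
        cr_labels=[
            CRLabel(identity=i, x=c.x_c, y=c.y_c) for i, c in enumerate(crs)
        ],
        params={
            "pupil": pupil, "crs": crs, "L_p": l_p, "L_i": l_i,
            "sigma_n": sigma_n, "scene": spec,
        },
    )
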