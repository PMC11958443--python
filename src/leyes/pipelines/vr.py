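"""Synthetic pipelines for VR-headset eye images.

Three generators:

* ``gen_eds2019_scene`` -- full-eye segmentation scenes: bright sclera
  background, soft-edged iris ellipse, irregular collarette polygon, dark
  pupil, and one to eight bright CRs.  Emits a pupil segmentation mask.
* ``gen_chugh_scene`` -- 128x128 scenes with a five-CR house constellation,
  per-CR dropout, spurious reflections, and a gradient background.
* ``gen_eds2020_scene`` -- as Chugh but with an eight-CR octagon
  constellation, near-zero rotation, 20% dropout, and Weibull pupil
  luminance.

Each constellation pipeline has a second-stage variant with fewer spurious
reflections (and, for the house, reduced dropout and rotation), used for the
fine-tuning stage of two-stage training.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from ..render import (
    CollarettePolygon,
    GaussianFeature,
    GradientBackground,
    SoftEdgeEllipse,
    UniformBackground,
    SceneSpec,
    compose_scene,
    eval_gaussian_at,
    eval_gaussian_field,
    freeze_collarette,
)
from .base import (
    CRLabel,
    LabeledImage,
    PlacementError,
    image_center,
    noise_seed_from,
    sample_exponential_luminance,
    sample_log_uniform,
    sample_normal_luminance,
    sample_uniform,
    sample_weibull_luminance,
)
from .constellations import (
    HouseConstellationSpec,
    OctagonConstellationSpec,
    build_house_constellation,
    build_octagon_constellation,
    sample_house_spec,
    sample_octagon_spec,
)
from .highres import sample_nonoverlapping_crs

__all__ = [
    "EDS2019Config",
    "ConstellationConfig",
    "gen_eds2019_scene",
    "gen_chugh_scene",
    "gen_eds2020_scene",
    "sample_spurious",
]


# ---------------------------------------------------------------------------
# OpenEDS-2019-style segmentation scenes


@dataclass(frozen=True)
class EDS2019Config:
    """Parameter ranges for the full-eye segmentation scenes.

    Luminances: sclera ~ Normal(217, 26), iris ~ Normal(77, 16), collarette
    at [1.25, 1.6] times the iris luminance, pupil ~ Normal(34, 15), CRs at
    full white.  The pupil plateau is constrained to lie fully inside the
    iris interior (its major radius is capped at ``pupil_fit_margin`` times
    the iris minor radius and its center offset limited accordingly).
    """

    width: int = 192
    height: int = 192
    sclera_lum: tuple[float, float] = (217.0, 26.0)      # mean, sd
    iris_minor_range: tuple[float, float] = (30.0, 42.5)
    iris_major_factor: tuple[float, float] = (1.0, 1.3)
    iris_lum: tuple[float, float] = (77.0, 16.0)         # mean, sd
    iris_edge_range: tuple[float, float] = (8.0, 20.0)
    col_vertices: tuple[int, int] = (13, 24)
    col_radius_factor: tuple[float, float] = (0.3, 0.6)  # of iris major radius
    col_jitter: tuple[float, float] = (0.05, 0.2)
    col_lum_factor: tuple[float, float] = (1.25, 1.6)    # of iris luminance
    col_edge_range: tuple[float, float] = (1.0, 4.0)
    pupil_minor_range: tuple[float, float] = (10.0, 30.0)
    pupil_major_factor: tuple[float, float] = (1.0, 1.3)
    pupil_amp_range: tuple[float, float] = (2.0, 2000.0)
    pupil_lum: tuple[float, float] = (34.0, 15.0)        # mean, sd
    pupil_fit_margin: float = 0.95
    n_cr_range: tuple[int, int] = (1, 8)
    cr_minor_range: tuple[float, float] = (0.8, 4.0)
    cr_major_factor: tuple[float, float] = (1.0, 1.4)
    cr_amp_range: tuple[float, float] = (2.0, 20000.0)
    l_cr: float = 255.0
    noise_range: tuple[float, float] = (0.0, 15.0)


def gen_eds2019_scene(
    cfg: EDS2019Config, rng: np.random.Generator, render: bool = True
) -> LabeledImage:
    """Sclera -> iris -> collarette -> pupil -> CRs, with a pupil mask.

    The pupil mask marks pixels where the pupil's clipped field is at least
    0.5 (the half-blend contour).
    """
    w, h = cfg.width, cfg.height
    cx, cy = image_center(w, h)

    l_s = sample_normal_luminance(rng, *cfg.sclera_lum)
    i_minor = sample_uniform(rng, cfg.iris_minor_range)
    i_major = i_minor * sample_uniform(rng, cfg.iris_major_factor)
    i_theta = float(rng.uniform(0.0, math.pi))
    l_i = sample_normal_luminance(rng, *cfg.iris_lum)
    i_edge = sample_uniform(rng, cfg.iris_edge_range)
    # keep the whole iris (including its soft edge) on the canvas
    span = max(0.0, min(w, h) / 2.0 - i_major - i_edge - 2.0)
    ix = float(rng.uniform(cx - span, cx + span))
    iy = float(rng.uniform(cy - span, cy + span))
    iris = SoftEdgeEllipse(
        x_c=ix, y_c=iy, r_minor=i_minor, r_major=i_major, theta=i_theta,
        L=l_i, edge_width=i_edge,
    )

    # collarette close to the iris center, riding on the iris
    off_r = 0.05 * i_minor * math.sqrt(rng.uniform())
    off_a = rng.uniform(0.0, 2.0 * math.pi)
    col = CollarettePolygon(
        x_c=ix + off_r * math.cos(off_a),
        y_c=iy + off_r * math.sin(off_a),
        n_vertices=int(rng.integers(cfg.col_vertices[0], cfg.col_vertices[1] + 1)),
        r_col=i_major * sample_uniform(rng, cfg.col_radius_factor),
        jitter_lo=cfg.col_jitter[0],
        jitter_hi=cfg.col_jitter[1],
        L=min(255.0, l_i * sample_uniform(rng, cfg.col_lum_factor)),
        edge_width=sample_uniform(rng, cfg.col_edge_range),
    )
    frozen_col = freeze_collarette(col, rng)

    # pupil: plateau fully inside the iris interior
    p_minor = sample_uniform(rng, cfg.pupil_minor_range)
    p_major = p_minor * sample_uniform(rng, cfg.pupil_major_factor)
    p_major = min(p_major, cfg.pupil_fit_margin * i_minor)
    p_minor = min(p_minor, p_major)
    max_off = max(0.0, i_minor - p_major)
    po_r = max_off * math.sqrt(rng.uniform())
    po_a = rng.uniform(0.0, 2.0 * math.pi)
    px, py = ix + po_r * math.cos(po_a), iy + po_r * math.sin(po_a)
    pupil = GaussianFeature(
        x_c=px, y_c=py, r_minor=p_minor, r_major=p_major,
        A=sample_log_uniform(rng, cfg.pupil_amp_range),
        theta=float(rng.uniform(0.0, math.pi)),
        L=sample_normal_luminance(rng, *cfg.pupil_lum),
        polarity="dark",
    )

    n_cr = int(rng.integers(cfg.n_cr_range[0], cfg.n_cr_range[1] + 1))
    crs = sample_nonoverlapping_crs(
        n_cr, cfg.cr_minor_range, cfg.cr_major_factor, cfg.cr_amp_range,
        w, h, rng, l_cr=cfg.l_cr,
    )

    sigma_n = sample_uniform(rng, cfg.noise_range)
    spec = SceneSpec(
        width=w, height=h, background=UniformBackground(L=l_s),
        layers=(iris, frozen_col, pupil, *crs), sigma_n=sigma_n,
    )
    mask = np.minimum(eval_gaussian_field(pupil, w, h), 1.0) >= 0.5
    image = compose_scene(spec, noise_seed_from(rng)) if render else None
    return LabeledImage(
        image=image,
        pupil_center=(px, py),
        cr_labels=[CRLabel(identity=i, x=c.x_c, y=c.y_c) for i, c in enumerate(crs)],
        masks={"pupil": mask},
        params={
            "iris": iris, "collarette": col, "pupil": pupil, "crs": crs,
            "L_s": l_s, "L_i": l_i, "sigma_n": sigma_n, "scene": spec,
        },
    )


# ---------------------------------------------------------------------------
# constellation scenes (house / octagon)


@dataclass(frozen=True)
class ConstellationConfig:
    """Parameter ranges for the 128x128 constellation scenes.

    ``kind`` selects the illuminator pattern ("house" with 5 CRs or
    "octagon" with 8).  ``pupil_lum`` selects the pupil-luminance model:
    "exponential" (scale 10, offset 1) or "weibull" (shape 2, scale 25,
    offset 18).
    """

    kind: str = "house"
    d: int = 128
    pupil_minor_range: tuple[float, float] = (6.0, 22.5)
    pupil_major_factor: tuple[float, float] = (1.0, 1.3)
    pupil_amp_range: tuple[float, float] = (200.0, 100000.0)
    pupil_lum: str = "exponential"
    pupil_pos_span: float = 0.2          # fraction of d, around image center
    constellation_offset_sd: float = 0.05  # fraction of d, around pupil center
    cr_minor_range: tuple[float, float] = (1.0, 2.5)
    cr_major_factor: tuple[float, float] = (1.0, 1.1)
    cr_amp_range: tuple[float, float] = (200.0, 100000.0)
    l_cr: float = 255.0
    dropout: float = 0.16
    phi_max: float = 45.0
    n_spur_max: int = 5
    spur_minor_range: tuple[float, float] = (1.0, 2.5)
    spur_major_factor: tuple[float, float] = (1.0, 2.5)
    bg_lum_range: tuple[float, float] = (63.0, 178.0)
    noise_range: tuple[float, float] = (0.0, 30.0)
    max_placement_attempts: int = 500

    @classmethod
    def chugh(cls, stage: int = 1, **overrides) -> "ConstellationConfig":
        cfg = cls(kind="house", **overrides)
        if stage == 2:
            cfg = replace(cfg, dropout=0.10, phi_max=35.0, n_spur_max=3)
        return cfg

    @classmethod
    def eds2020(cls, stage: int = 1, **overrides) -> "ConstellationConfig":
        cfg = cls(
            kind="octagon", pupil_lum="weibull", dropout=0.20, phi_max=0.57,
            **overrides,
        )
        if stage == 2:
            cfg = replace(cfg, n_spur_max=3)
        return cfg


def sample_spurious(
    n: int,
    pupil: GaussianFeature,
    width: int,
    height: int,
    rng: np.random.Generator,
    minor_range: tuple[float, float] = (1.0, 2.5),
    major_factor: tuple[float, float] = (1.0, 2.5),
    amp_range: tuple[float, float] = (200.0, 100000.0),
    l_cr: float = 255.0,
    max_attempts: int = 10000,
) -> list[GaussianFeature]:
    """Place spurious (non-illuminator) reflections away from the pupil.

    Candidate positions are drawn uniformly and accepted with probability
    ``1 - min(G_pupil(x, y), 1)`` where ``G_pupil`` is the pupil's Gaussian
    field, so spurious reflections never land on the pupil plateau and are
    unlikely near it.
    """
    out: list[GaussianFeature] = []
    for _ in range(n):
        for attempt in range(max_attempts):
            x = float(rng.uniform(0.0, width - 1.0))
            y = float(rng.uniform(0.0, height - 1.0))
            p_accept = 1.0 - min(float(eval_gaussian_at(pupil, x, y)), 1.0)
            if rng.random() < p_accept:
                break
        else:
            raise PlacementError(
                f"could not place spurious reflection after {max_attempts} attempts"
            )
        mn = sample_uniform(rng, minor_range)
        out.append(
            GaussianFeature(
                x_c=x, y_c=y, r_minor=mn,
                r_major=mn * sample_uniform(rng, major_factor),
                A=sample_log_uniform(rng, amp_range),
                theta=float(rng.uniform(0.0, math.pi)),
                L=l_cr, polarity="bright",
            )
        )
    return out


def _gen_constellation_scene(
    cfg: ConstellationConfig, rng: np.random.Generator, render: bool
) -> LabeledImage:
    d = cfg.d
    cx, cy = image_center(d, d)

    # pupil shape and luminance
    p_minor = sample_uniform(rng, cfg.pupil_minor_range)
    p_major = p_minor * sample_uniform(rng, cfg.pupil_major_factor)
    p_amp = sample_log_uniform(rng, cfg.pupil_amp_range)
    p_theta = float(rng.uniform(0.0, math.pi))
    if cfg.pupil_lum == "exponential":
        l_p = sample_exponential_luminance(rng)
    elif cfg.pupil_lum == "weibull":
        l_p = sample_weibull_luminance(rng)
    else:
        raise ValueError(f"unknown pupil luminance model {cfg.pupil_lum!r}")

    # constellation dimensions, then joint placement of pupil center and
    # constellation centroid so every vertex lands on the canvas
    if cfg.kind == "house":
        base_spec = sample_house_spec(rng, center=(0.0, 0.0), d=d, phi_max=cfg.phi_max)
        base_pts = build_house_constellation(base_spec)
    elif cfg.kind == "octagon":
        base_spec = sample_octagon_spec(rng, center=(0.0, 0.0), d=d, phi_max=cfg.phi_max)
        base_pts = build_octagon_constellation(base_spec)
    else:
        raise ValueError(f"unknown constellation kind {cfg.kind!r}")

    span = cfg.pupil_pos_span * d
    sd = cfg.constellation_offset_sd * d
    for attempt in range(cfg.max_placement_attempts):
        px = float(rng.uniform(cx - span, cx + span))
        py = float(rng.uniform(cy - span, cy + span))
        ox = px + float(rng.normal(0.0, sd))
        oy = py + float(rng.normal(0.0, sd))
        pts = base_pts + np.array([ox, oy])
        if (
            pts[:, 0].min() >= 0.0 and pts[:, 0].max() <= d - 1.0
            and pts[:, 1].min() >= 0.0 and pts[:, 1].max() <= d - 1.0
        ):
            break
    else:
        raise PlacementError("could not fit the constellation on the canvas")

    pupil = GaussianFeature(
        x_c=px, y_c=py, r_minor=p_minor, r_major=p_major, A=p_amp,
        theta=p_theta, L=l_p, polarity="dark",
    )

    # per-CR independent dropout
    present = rng.random(len(pts)) >= cfg.dropout
    cr_features: list[GaussianFeature] = []
    cr_labels: list[CRLabel] = []
    for i, (vx, vy) in enumerate(pts):
        if present[i]:
            mn = sample_uniform(rng, cfg.cr_minor_range)
            cr_features.append(
                GaussianFeature(
                    x_c=float(vx), y_c=float(vy), r_minor=mn,
                    r_major=mn * sample_uniform(rng, cfg.cr_major_factor),
                    A=sample_log_uniform(rng, cfg.cr_amp_range),
                    theta=float(rng.uniform(0.0, math.pi)),
                    L=cfg.l_cr, polarity="bright",
                )
            )
            cr_labels.append(CRLabel(identity=i, x=float(vx), y=float(vy)))
        else:
            cr_labels.append(CRLabel(identity=i, x=float(vx), y=float(vy), absent=True))

    n_spur = int(rng.integers(1, cfg.n_spur_max + 1))
    spurious = sample_spurious(
        n_spur, pupil, d, d, rng,
        minor_range=cfg.spur_minor_range,
        major_factor=cfg.spur_major_factor,
        amp_range=cfg.cr_amp_range,
        l_cr=cfg.l_cr,
    )

    bg = GradientBackground(
        L0=sample_uniform(rng, cfg.bg_lum_range),
        L1=sample_uniform(rng, cfg.bg_lum_range),
        angle=float(rng.uniform(0.0, 2.0 * math.pi)),
    )
    sigma_n = sample_uniform(rng, cfg.noise_range)
    spec = SceneSpec(
        width=d, height=d, background=bg,
        layers=(pupil, *cr_features, *spurious), sigma_n=sigma_n,
    )
    image = compose_scene(spec, noise_seed_from(rng)) if render else None
    return LabeledImage(
        image=image,
        pupil_center=(px, py),
        cr_labels=cr_labels,
        params={
            "pupil": pupil, "constellation": base_spec,
            "vertices": pts, "spurious": spurious, "sigma_n": sigma_n,
            "phi": base_spec.phi, "scene": spec,
        },
    )


def gen_chugh_scene(
    cfg: Optional[ConstellationConfig] = None,
    stage: int = 1,
    rng: Optional[np.random.Generator] = None,
    render: bool = True,
) -> LabeledImage:
    """Generate one five-CR house-constellation scene (128x128)."""
    if rng is None:
        raise ValueError("rng is required")
    if cfg is None:
        cfg = ConstellationConfig.chugh(stage=stage)
    return _gen_constellation_scene(cfg, rng, render)


def gen_eds2020_scene(
    cfg: Optional[ConstellationConfig] = None,
    stage: int = 1,
    rng: Optional[np.random.Generator] = None,
    render: bool = True,
) -> LabeledImage:
    """Generate one eight-CR octagon-constellation scene (128x128)."""
    if rng is None:
        raise ValueError("rng is required")
    if cfg is None:
        cfg = ConstellationConfig.eds2020(stage=stage)
    return _gen_constellation_scene(cfg, rng, render)
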