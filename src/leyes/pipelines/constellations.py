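"""Illuminator-constellation geometry for the VR pipelines.

Multi-illuminator eye trackers project a fixed pattern of corneal
reflections.  Two patterns are modeled:

* a five-vertex "house" (rectangle with an apex above the middle of the top
  edge, bottom width reduced by a factor), CR identities starting at the
  topmost vertex and proceeding clockwise;
* a regular octagon, identities starting at the bottom-right vertex and
  proceeding clockwise.

Coordinates follow the image convention (x right, y down), so "clockwise" on
screen corresponds to increasing angle from +x toward +y.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "HouseConstellationSpec",
    "OctagonConstellationSpec",
    "build_house_constellation",
    "build_octagon_constellation",
    "sample_house_spec",
    "sample_octagon_spec",
]


@dataclass(frozen=True)
class HouseConstellationSpec:
    """Five IR lights forming a house-shaped polygon.

    ``w``: width of the rectangle; ``f_b``: bottom-width reduction factor;
    ``h``: rectangle height; ``h_r``: roof height above the top edge;
    ``phi``: rotation in degrees about the polygon centroid.
    """

    w: float
    f_b: float
    h: float
    h_r: float
    phi: float = 0.0
    center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0 or self.h_r <= 0:
            raise ValueError("w, h, h_r must be positive")
        if not (0.0 < self.f_b <= 1.0):
            raise ValueError("f_b must lie in (0, 1]")


@dataclass(frozen=True)
class OctagonConstellationSpec:
    """Eight IR lights on a regular octagon of circumradius ``m``."""

    m: float
    phi: float = 0.0
    center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.m <= 0:
            raise ValueError("m must be positive")


def _rotate_about(points: np.ndarray, pivot: np.ndarray, phi_deg: float) -> np.ndarray:
    phi = math.radians(phi_deg)
    rot = np.array(
        [[math.cos(phi), -math.sin(phi)], [math.sin(phi), math.cos(phi)]]
    )
    return (points - pivot) @ rot.T + pivot


def build_house_constellation(spec: HouseConstellationSpec) -> np.ndarray:
    """Ordered (5, 2) CR positions: apex first, then clockwise.

    Unrotated layout (y down): apex at (0, -h/2 - h_r), top corners at
    (+-w/2, -h/2), bottom corners at (+-f_b*w/2, +h/2); order is
    [apex, top-right, bottom-right, bottom-left, top-left].  The polygon is
    rotated by ``phi`` degrees about its centroid, then translated by
    ``center``.
    """
    w, h, hr, fb = spec.w, spec.h, spec.h_r, spec.f_b
    pts = np.array(
        [
            [0.0, -h / 2.0 - hr],          # roof apex (topmost)
            [w / 2.0, -h / 2.0],           # top-right
            [fb * w / 2.0, h / 2.0],       # bottom-right
            [-fb * w / 2.0, h / 2.0],      # bottom-left
            [-w / 2.0, -h / 2.0],          # top-left
        ]
    )
    pts = _rotate_about(pts, pts.mean(axis=0), spec.phi)
    return pts + np.asarray(spec.center, dtype=float)


def build_octagon_constellation(spec: OctagonConstellationSpec) -> np.ndarray:
    """Ordered (8, 2) CR positions: bottom-right vertex first, clockwise.

    Vertices sit at angles 22.5 + 45*k degrees (measured from +x toward +y,
    i.e., screen-clockwise) at distance ``m`` from the center, then the whole
    polygon is rotated by ``phi`` degrees about the center.
    """
    angles = np.radians(22.5 + 45.0 * np.arange(8) + spec.phi)
    pts = spec.m * np.column_stack([np.cos(angles), np.sin(angles)])
    return pts + np.asarray(spec.center, dtype=float)


def sample_house_spec(
    rng: np.random.Generator,
    center: tuple[float, float],
    d: float = 128.0,
    phi_max: float = 45.0,
) -> HouseConstellationSpec:
    """Draw house dimensions: w in [0.1d, 0.45d], f_b in [0.05, 0.2],
    h in [0.5w, 0.6w], h_r in [0.2w, 0.5w], phi in +-[0, phi_max] deg."""
    w = float(rng.uniform(0.1 * d, 0.45 * d))
    return HouseConstellationSpec(
        w=w,
        f_b=float(rng.uniform(0.05, 0.2)),
        h=float(rng.uniform(0.5 * w, 0.6 * w)),
        h_r=float(rng.uniform(0.2 * w, 0.5 * w)),
        phi=float(rng.choice([-1.0, 1.0]) * rng.uniform(0.0, phi_max)),
        center=center,
    )


def sample_octagon_spec(
    rng: np.random.Generator,
    center: tuple[float, float],
    d: float = 128.0,
    phi_max: float = 0.57,
) -> OctagonConstellationSpec:
    """Draw octagon radius m in [0.15d, 0.4d] and phi in +-[0, phi_max] deg."""
    return OctagonConstellationSpec(
        m=float(rng.uniform(0.15 * d, 0.4 * d)),
        phi=float(rng.choice([-1.0, 1.0]) * rng.uniform(0.0, phi_max)),
        center=center,
    )
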