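"""Deterministic rendering primitives for abstract synthetic eye images.

Blob-like features (pupils, corneal reflections) are anisotropic 2D Gaussians

    G(x, y) = A * exp(-a*(x-x_c)^2 - b*(x-x_c)*(y-y_c) - c*(y-y_c)^2)

whose quadratic-form coefficients a, b, c follow from the orientation theta
and the per-axis spreads sigma_minor, sigma_major.  The spreads are not free
parameters: they are derived from the desired *luminance-plateau* radii via

    sigma = r / sqrt(2 * ln(A))

so that the field equals exactly 1 at distance r from the center along each
principal axis, regardless of the amplitude A.  Clipping the field at 1 then
yields a plateau of constant luminance with radius r whose edge steepness is
controlled by A alone.

Coordinate convention (used everywhere, including labels): 0-based pixel
indices, a pixel samples its center at integer coordinates, x increases
rightward and y downward, and theta is measured from the +x axis toward +y.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy import ndimage
from scipy.interpolate import CubicSpline
from skimage.draw import polygon2mask

__all__ = [
    "GaussianFeature",
    "SoftEdgeEllipse",
    "CollarettePolygon",
    "FrozenCollarette",
    "UniformBackground",
    "SplitLineBackground",
    "GradientBackground",
    "BackgroundModel",
    "SceneSpec",
    "RenderedImage",
    "plateau_sigma",
    "gaussian_coefficients",
    "eval_gaussian_field",
    "eval_gaussian_at",
    "render_soft_ellipse",
    "soft_ellipse_coefficient",
    "freeze_collarette",
    "collarette_outline",
    "render_collarette",
    "add_pixel_noise",
    "compose_scene",
]


# ---------------------------------------------------------------------------
# feature types


def plateau_sigma(r: float, A: float) -> float:
    """Gaussian spread that puts the luminance-plateau edge at radius ``r``.

    Returns ``r / sqrt(2 ln A)``; the Gaussian with this spread and amplitude
    ``A`` equals exactly 1 at distance ``r`` from the center along the axis.

    Raises
    ------
    ValueError
        If ``A <= 1`` (the plateau is undefined) or ``r <= 0``.
    """
    if A <= 1.0:
        raise ValueError(f"amplitude must exceed 1 for a plateau, got A={A}")
    if r <= 0.0:
        raise ValueError(f"plateau radius must be positive, got r={r}")
    return r / math.sqrt(2.0 * math.log(A))


@dataclass(frozen=True)
class GaussianFeature:
    """One blob-like feature: a clipped anisotropic 2D Gaussian.

    ``r_minor``/``r_major`` are the plateau radii along the principal axes;
    ``L`` is the plateau luminance on the 8-bit scale.  ``polarity`` selects
    the compositing rule: bright features take ``max(image, L*field)``, dark
    features blend the image toward ``L`` by the clipped field.
    """

    x_c: float
    y_c: float
    r_minor: float
    r_major: float
    A: float
    theta: float = 0.0
    L: float = 255.0
    polarity: str = "bright"

    def __post_init__(self) -> None:
        if self.A <= 1.0:
            raise ValueError("amplitude A must exceed 1")
        if not (0.0 < self.r_minor <= self.r_major):
            raise ValueError("need 0 < r_minor <= r_major")
        if not (0.0 <= self.L <= 255.0):
            raise ValueError("plateau luminance must lie in [0, 255]")
        if self.polarity not in ("bright", "dark"):
            raise ValueError(f"unknown polarity {self.polarity!r}")

    @property
    def sigma_minor(self) -> float:
        return plateau_sigma(self.r_minor, self.A)

    @property
    def sigma_major(self) -> float:
        return plateau_sigma(self.r_major, self.A)

    @property
    def center(self) -> tuple[float, float]:
        return (self.x_c, self.y_c)


def gaussian_coefficients(
    theta: float, sigma_minor: float, sigma_major: float
) -> tuple[float, float, float]:
    """Quadratic-form coefficients (a, b, c) of the rotated 2D Gaussian.

    The exponent is ``-(a*dx^2 + b*dx*dy + c*dy^2)``, with the
    ``sigma_minor`` axis along ``(cos theta, sin theta)``.  The cross
    coefficient is ``sin(2 theta) * (1/(2 sigma_minor^2) -
    1/(2 sigma_major^2))``; this (rather than the half-size variant that
    appears when the cross term is written as ``2b*dx*dy``) is what makes
    the quadratic form an exact rotation, so the field equals 1 at distance
    r along each principal axis for every orientation.
    """
    ct2 = math.cos(theta) ** 2
    st2 = math.sin(theta) ** 2
    s2t = math.sin(2.0 * theta)
    ia = 1.0 / (2.0 * sigma_minor**2)
    ib = 1.0 / (2.0 * sigma_major**2)
    a = ct2 * ia + st2 * ib
    b = s2t * (ia - ib)
    c = st2 * ia + ct2 * ib
    return a, b, c


def eval_gaussian_field(
    feature: GaussianFeature, width: int, height: int
) -> np.ndarray:
    """Evaluate the unclipped Gaussian field on a ``height x width`` canvas."""
    a, b, c = gaussian_coefficients(
        feature.theta, feature.sigma_minor, feature.sigma_major
    )
    dx = np.arange(width, dtype=np.float64) - feature.x_c
    dy = (np.arange(height, dtype=np.float64) - feature.y_c)[:, None]
    return feature.A * np.exp(-a * dx**2 - b * dx * dy - c * dy**2)


def eval_gaussian_at(feature: GaussianFeature, x, y):
    """Evaluate the unclipped Gaussian field at arbitrary points."""
    a, b, c = gaussian_coefficients(
        feature.theta, feature.sigma_minor, feature.sigma_major
    )
    dx = np.asarray(x, dtype=np.float64) - feature.x_c
    dy = np.asarray(y, dtype=np.float64) - feature.y_c
    return feature.A * np.exp(-a * dx**2 - b * dx * dy - c * dy**2)


# ---------------------------------------------------------------------------
# soft-edged ellipse and collarette


@dataclass(frozen=True)
class SoftEdgeEllipse:
    """Filled ellipse whose edge fades out over ``edge_width`` px.

    The blend coefficient is 1 strictly inside the ellipse, 0 outside the
    ellipse grown by ``edge_width``, and follows a raised cosine
    ``(1 + cos(pi*t))/2`` across the transition band, parameterized along the
    outward ray from the center.
    """

    x_c: float
    y_c: float
    r_minor: float
    r_major: float
    theta: float = 0.0
    L: float = 128.0
    edge_width: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.r_minor <= self.r_major):
            raise ValueError("need 0 < r_minor <= r_major")
        if self.edge_width < 0.0:
            raise ValueError("edge_width must be >= 0")


def soft_ellipse_coefficient(e: SoftEdgeEllipse, x, y) -> np.ndarray:
    """Raised-cosine blend coefficient of a soft-edged ellipse at points."""
    dx = np.asarray(x, dtype=np.float64) - e.x_c
    dy = np.asarray(y, dtype=np.float64) - e.y_c
    dx, dy = np.broadcast_arrays(dx, dy)
    # components along the minor (u) and major (v) principal axes
    ct, st = math.cos(e.theta), math.sin(e.theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    r_px = np.hypot(dx, dy)
    with np.errstate(invalid="ignore", divide="ignore"):
        du = np.where(r_px > 0, u / r_px, 1.0)
        dv = np.where(r_px > 0, v / r_px, 0.0)
        # Euclidean distance from center to the (inner/outer) ellipse
        # boundary along this pixel's direction
        r_in = 1.0 / np.sqrt((du / e.r_minor) ** 2 + (dv / e.r_major) ** 2)
        r_out = 1.0 / np.sqrt(
            (du / (e.r_minor + e.edge_width)) ** 2
            + (dv / (e.r_major + e.edge_width)) ** 2
        )
    coeff = np.zeros(dx.shape, dtype=np.float64)
    inside = r_px <= r_in
    coeff[inside] = 1.0
    if e.edge_width > 0:
        band = (~inside) & (r_px < r_out)
        t = (r_px[band] - r_in[band]) / (r_out[band] - r_in[band])
        coeff[band] = 0.5 * (1.0 + np.cos(np.pi * t))
    return coeff


def render_soft_ellipse(
    e: SoftEdgeEllipse, width: int, height: int
) -> np.ndarray:
    """Blend-coefficient field in [0, 1] on the pixel grid."""
    x = np.arange(width, dtype=np.float64)
    y = np.arange(height, dtype=np.float64)[:, None]
    return soft_ellipse_coefficient(e, x, y)


@dataclass(frozen=True)
class CollarettePolygon:
    """Distribution spec for an irregular collarette polygon.

    ``n_vertices`` base vertices are placed around the center at mean distance
    ``r_col``, each perturbed radially by a magnitude drawn uniformly from
    ``[jitter_lo, jitter_hi] * r_col`` with random sign.  The polygon outline
    is smoothed by a periodic cubic spline sampled at five times the vertex
    count, then filled at luminance ``L`` with a raised-cosine edge.
    """

    x_c: float
    y_c: float
    n_vertices: int
    r_col: float
    jitter_lo: float = 0.05
    jitter_hi: float = 0.2
    L: float = 128.0
    edge_width: float = 0.0

    def __post_init__(self) -> None:
        if self.n_vertices < 3:
            raise ValueError("need at least 3 vertices")
        if self.r_col <= 0.0:
            raise ValueError("r_col must be positive")


@dataclass(frozen=True)
class FrozenCollarette:
    """A collarette with sampled per-vertex radii (render-deterministic)."""

    x_c: float
    y_c: float
    radii: tuple[float, ...]
    phase: float
    L: float
    edge_width: float


def freeze_collarette(
    c: CollarettePolygon, rng: np.random.Generator
) -> FrozenCollarette:
    """Draw the per-vertex radial jitter and starting phase."""
    mag = rng.uniform(c.jitter_lo, c.jitter_hi, size=c.n_vertices) * c.r_col
    sign = rng.choice([-1.0, 1.0], size=c.n_vertices)
    radii = c.r_col + sign * mag
    phase = rng.uniform(0.0, 2.0 * np.pi)
    return FrozenCollarette(
        x_c=c.x_c, y_c=c.y_c, radii=tuple(radii), phase=phase,
        L=c.L, edge_width=c.edge_width,
    )


def collarette_outline(c: FrozenCollarette) -> np.ndarray:
    """Closed smooth outline, sampled at five times the vertex count.

    Returns an ``(5n, 2)`` array of (x, y) points whose first and last points
    coincide (periodic cubic spline through the jittered vertices).
    """
    n = len(c.radii)
    angles = c.phase + 2.0 * np.pi * np.arange(n) / n
    pts = np.column_stack(
        [c.x_c + c.radii * np.cos(angles), c.y_c + c.radii * np.sin(angles)]
    )
    # periodic parameterization by vertex index
    t = np.arange(n + 1, dtype=np.float64)
    closed = np.vstack([pts, pts[:1]])
    spl = CubicSpline(t, closed, bc_type="periodic", axis=0)
    return spl(np.linspace(0.0, float(n), 5 * n))


def render_collarette(
    c: Union[CollarettePolygon, FrozenCollarette],
    width: int,
    height: int,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Blend-coefficient field and outline vertices for a collarette.

    A :class:`CollarettePolygon` (distribution spec) requires ``rng`` to draw
    the vertex jitter; a :class:`FrozenCollarette` renders deterministically.
    """
    if isinstance(c, CollarettePolygon):
        if rng is None:
            raise ValueError("rendering a CollarettePolygon requires an rng")
        c = freeze_collarette(c, rng)
    outline = collarette_outline(c)
    mask = polygon2mask((height, width), outline[:, ::-1])
    coeff = mask.astype(np.float64)
    if c.edge_width > 0:
        dist = ndimage.distance_transform_edt(~mask)
        band = (~mask) & (dist < c.edge_width)
        coeff[band] = 0.5 * (1.0 + np.cos(np.pi * dist[band] / c.edge_width))
    return coeff, outline


# ---------------------------------------------------------------------------
# backgrounds


@dataclass(frozen=True)
class UniformBackground:
    L: float = 128.0

    def evaluate(self, width: int, height: int) -> np.ndarray:
        return np.full((height, width), float(self.L), dtype=np.float64)


@dataclass(frozen=True)
class SplitLineBackground:
    """Canvas divided by a straight line into a dark and a light side.

    The line passes through ``(x0, y0)`` with direction angle ``angle``; the
    dark side is the half-plane with negative signed offset along the line
    normal ``(-sin(angle), cos(angle))``.
    """

    x0: float
    y0: float
    angle: float
    L_dark: float
    L_light: float

    def evaluate(self, width: int, height: int) -> np.ndarray:
        dx = np.arange(width, dtype=np.float64) - self.x0
        dy = (np.arange(height, dtype=np.float64) - self.y0)[:, None]
        s = -dx * math.sin(self.angle) + dy * math.cos(self.angle)
        return np.where(s < 0, float(self.L_dark), float(self.L_light))


@dataclass(frozen=True)
class GradientBackground:
    """Luminance varying linearly between two values along a random axis.

    The ramp spans the canvas diagonal extent so both endpoint luminances are
    reached at the far corners for any axis angle.
    """

    L0: float
    L1: float
    angle: float

    def evaluate(self, width: int, height: int) -> np.ndarray:
        cx, cy = (width - 1) / 2.0, (height - 1) / 2.0
        dx = np.arange(width, dtype=np.float64) - cx
        dy = (np.arange(height, dtype=np.float64) - cy)[:, None]
        s = dx * math.cos(self.angle) + dy * math.sin(self.angle)
        diag = math.hypot(width, height)
        t = np.clip(s / diag + 0.5, 0.0, 1.0)
        return self.L0 + (self.L1 - self.L0) * t


BackgroundModel = Union[UniformBackground, SplitLineBackground, GradientBackground]

Layer = Union[GaussianFeature, SoftEdgeEllipse, FrozenCollarette]


# ---------------------------------------------------------------------------
# scene composition


@dataclass(frozen=True)
class SceneSpec:
    """Full description of one synthetic image.

    Rendering is a pure function of the spec and an explicit noise seed; all
    stochastic choices (feature parameters, collarette jitter) are frozen in
    the layer objects.
    """

    width: int
    height: int
    background: BackgroundModel
    layers: tuple = ()
    sigma_n: float = 0.0

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("canvas must be at least 1x1")
        if self.sigma_n < 0.0:
            raise ValueError("sigma_n must be >= 0")


@dataclass(frozen=True)
class RenderedImage:
    """8-bit quantized image with values in {0, 1/255, ..., 1}."""

    pixels: np.ndarray

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    def to_uint8(self) -> np.ndarray:
        return np.round(self.pixels * 255.0).astype(np.uint8)


def add_pixel_noise(
    image: np.ndarray, sigma_n: float, seed
) -> np.ndarray:
    """Add i.i.d. per-pixel Gaussian noise N(0, sigma_n^2) on the 8-bit scale.

    Deterministic given ``seed``; ``sigma_n=0`` returns the input unchanged.
    """
    if sigma_n < 0.0:
        raise ValueError("sigma_n must be >= 0")
    if sigma_n == 0.0:
        return image
    rng = np.random.default_rng(seed)
    return image + rng.normal(0.0, sigma_n, size=image.shape)


def _apply_layer(img: np.ndarray, layer: Layer, width: int, height: int) -> np.ndarray:
    if isinstance(layer, GaussianFeature):
        cf = np.minimum(eval_gaussian_field(layer, width, height), 1.0)
        if layer.polarity == "bright":
            return np.maximum(img, layer.L * cf)
        return img - (img - layer.L) * cf
    if isinstance(layer, SoftEdgeEllipse):
        cf = render_soft_ellipse(layer, width, height)
        return img - (img - layer.L) * cf
    if isinstance(layer, FrozenCollarette):
        cf, _ = render_collarette(layer, width, height)
        return img - (img - layer.L) * cf
    raise TypeError(f"unsupported layer type {type(layer).__name__}")


def compose_scene(spec: SceneSpec, noise_seed=0) -> RenderedImage:
    """Render a scene: background, ordered layers, noise, 8-bit quantization.

    Dark features and soft-edged shapes blend the running image toward their
    luminance by the clipped field (so the plateau luminance is exact
    regardless of what lies beneath); bright features apply
    ``max(image, L * field)``.  Noise is added before the final clip to
    [0, 255]; the result is scaled to [0, 1] and discretized to 256 levels
    with round-half-away-from-zero.
    """
    w, h = spec.width, spec.height
    img = spec.background.evaluate(w, h).astype(np.float64)
    for layer in spec.layers:
        img = _apply_layer(img, layer, w, h)
    img = add_pixel_noise(img, spec.sigma_n, noise_seed)
    img = np.clip(img, 0.0, 255.0)
    # round half away from zero (values are >= 0 here, so this is floor(x+1/2))
    quant = np.floor(img + 0.5) / 255.0
    return RenderedImage(pixels=quant)
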