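"""Classical thresholding baseline and mask-based cutout preparation.

The baseline binarizes an 8-bit eye image at fixed dark (pupil) and bright
(CR) thresholds, fills holes in the resulting blobs, selects candidates by
size, shape and relative-location criteria, and reports feature centers as
blob centers of mass.  It also prepares masked fixed-size cutouts around the
detected centers: CR cutouts get a black circular mask, pupil cutouts a
middle-grey elliptical mask 1.4 times the fitted pupil ellipse.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage.measure import regionprops, label as sk_label

from .postprocess import EllipseFit, extract_cutout, fit_ellipse_to_mask

__all__ = [
    "ThresholdConfig",
    "DetectResult",
    "FitFailure",
    "threshold_detect",
    "make_cr_cutout",
    "make_pupil_cutout",
]


class FitFailure(RuntimeError):
    """Raised when an ellipse cannot be fit to a degenerate pupil blob."""


@dataclass(frozen=True)
class ThresholdConfig:
    """Thresholds and selection criteria for the baseline detector.

    Intensities are on the 8-bit scale.  The CR's relative-location rule
    accepts a bright blob only if its center lies within
    ``relative_location_factor`` times the pupil blob's bounding radius of
    the pupil center; set the factor to ``None`` to disable the rule (e.g.,
    for scenes where the CR is known to sit away from the pupil).
    """

    pupil_threshold: float = 50.0
    cr_threshold: float = 200.0
    pupil_area: tuple[float, float] = (50.0, 50000.0)
    cr_area: tuple[float, float] = (3.0, 5000.0)
    max_axis_ratio: float = 3.0
    relative_location_factor: Optional[float] = 1.5
    cutout_size: int = 180
    cr_mask_radius: float = 32.0
    pupil_mask_scale: float = 1.4


@dataclass
class DetectResult:
    pupil_center: Optional[tuple[float, float]]
    cr_center: Optional[tuple[float, float]]
    pupil_mask: Optional[np.ndarray]
    cr_mask: Optional[np.ndarray]


def _as_8bit(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=np.float64)
    if img.size and img.max() <= 1.0:
        img = img * 255.0
    return img


def _candidate_blobs(binary: np.ndarray, area_range, max_ratio):
    binary = ndimage.binary_fill_holes(binary)
    labeled = sk_label(binary)
    out = []
    for region in regionprops(labeled):
        if not (area_range[0] <= region.area <= area_range[1]):
            continue
        if region.axis_minor_length > 0:
            if region.axis_major_length / region.axis_minor_length > max_ratio:
                continue
        out.append((region, labeled))
    return out


def _bounding_radius(mask: np.ndarray, center: tuple[float, float]) -> float:
    ys, xs = np.nonzero(mask)
    return float(np.hypot(xs - center[0], ys - center[1]).max())


def threshold_detect(image: np.ndarray, cfg: ThresholdConfig) -> DetectResult:
    """Detect pupil (dark) and CR (bright) centers by fixed thresholding.

    The pupil is the largest qualifying dark blob; the CR is the largest
    qualifying bright blob, restricted (when the relative-location rule is
    active and a pupil was found) to blobs near the pupil.  Missing features
    are reported as ``None``.
    """
    img = _as_8bit(image)

    pupil_center = pupil_mask = None
    pupil_candidates = _candidate_blobs(
        img <= cfg.pupil_threshold, cfg.pupil_area, cfg.max_axis_ratio
    )
    if pupil_candidates:
        region, labeled = max(pupil_candidates, key=lambda rl: rl[0].area)
        pupil_mask = labeled == region.label
        cy, cx = ndimage.center_of_mass(pupil_mask)
        pupil_center = (float(cx), float(cy))

    cr_center = cr_mask = None
    cr_candidates = _candidate_blobs(
        img >= cfg.cr_threshold, cfg.cr_area, cfg.max_axis_ratio
    )
    if cr_candidates:
        if cfg.relative_location_factor is not None and pupil_center is not None:
            limit = cfg.relative_location_factor * _bounding_radius(
                pupil_mask, pupil_center
            )
            near = []
            for region, labeled in cr_candidates:
                cy, cx = region.centroid
                if np.hypot(cx - pupil_center[0], cy - pupil_center[1]) <= limit:
                    near.append((region, labeled))
            cr_candidates = near
        if cr_candidates:
            region, labeled = max(cr_candidates, key=lambda rl: rl[0].area)
            cr_mask = labeled == region.label
            cy, cx = ndimage.center_of_mass(cr_mask)
            cr_center = (float(cx), float(cy))

    return DetectResult(
        pupil_center=pupil_center, cr_center=cr_center,
        pupil_mask=pupil_mask, cr_mask=cr_mask,
    )


def make_cr_cutout(
    image: np.ndarray, cr_center: tuple[float, float],
    cfg: ThresholdConfig = ThresholdConfig(),
) -> np.ndarray:
    """Fixed-size cutout around the CR with a black circular mask.

    Pixels farther than ``cr_mask_radius`` from the cutout center are set to
    0; the boundary (distance exactly equal to the radius) is retained.
    Border-exceeding cutouts use edge-replication padding.
    """
    img = _as_8bit(image)
    _, patch = extract_cutout(img, cr_center, cfg.cutout_size)
    n = cfg.cutout_size
    cy = cx = n // 2
    yy, xx = np.ogrid[:n, :n]
    outside = np.hypot(xx - cx, yy - cy) > cfg.cr_mask_radius
    patch = patch.copy()
    patch[outside] = 0.0
    return patch


def make_pupil_cutout(
    image: np.ndarray, pupil_blob: np.ndarray,
    cfg: ThresholdConfig = ThresholdConfig(),
) -> tuple[np.ndarray, EllipseFit]:
    """Fixed-size cutout around the pupil with a grey elliptical mask.

    An ellipse is fit to the binarized pupil blob's boundary; pixels outside
    the ellipse scaled by ``pupil_mask_scale`` are set to middle grey (128).
    Raises :class:`FitFailure` for degenerate blobs.
    """
    img = _as_8bit(image)
    cy, cx = ndimage.center_of_mass(pupil_blob)
    ellipse = fit_ellipse_to_mask(pupil_blob)
    if ellipse is None:
        raise FitFailure("pupil blob too degenerate for an ellipse fit")
    spec, patch = extract_cutout(img, (cx, cy), cfg.cutout_size)
    n = cfg.cutout_size
    yy, xx = np.indices((n, n), dtype=np.float64)
    # pixel position in full-image coordinates
    fx, fy = xx + spec.x0, yy + spec.y0
    ct, st = np.cos(ellipse.theta), np.sin(ellipse.theta)
    dx, dy = fx - ellipse.x_c, fy - ellipse.y_c
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    s = cfg.pupil_mask_scale
    rho = (u / (s * ellipse.r_major)) ** 2 + (v / (s * ellipse.r_minor)) ** 2
    patch = patch.copy()
    patch[rho > 1.0] = 128.0
    return patch, ellipse
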