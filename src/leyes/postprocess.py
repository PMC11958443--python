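"""Model-output post-processing for heatmap and segmentation models.

Covers the inference-side pipeline: per-feature heatmap peak extraction,
selection of the two most confident corneal reflections, frame validity
exclusion, probability-map-to-pupil conversion (binarize, fill holes, pick a
blob, center of mass, ellipse fit), confidence-gated adaptive cutouts around
an external pupil prior, and edge-proximity re-centering of cutouts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage.measure import EllipseModel, find_contours, regionprops, label as sk_label

__all__ = [
    "Peak",
    "PeakSet",
    "PupilPrior",
    "CutoutSpec",
    "BlobCriteria",
    "EllipseFit",
    "PupilFit",
    "InvalidFrame",
    "extract_peaks",
    "select_best_two",
    "check_validity",
    "downscale_by_two",
    "extract_cutout",
    "adaptive_cutout",
    "prob_map_to_pupil",
    "load_pupil_priors",
    "recenter_if_near_edge",
]


class InvalidFrame(RuntimeError):
    """Raised when a frame cannot be processed (e.g., no pupil found)."""


@dataclass(frozen=True)
class Peak:
    """Location and value of a heatmap's global maximum."""

    x: int
    y: int
    value: float


@dataclass(frozen=True)
class PeakSet:
    """Per-feature heatmap maxima, in heatmap order."""

    peaks: tuple[Peak, ...]

    def __len__(self) -> int:
        return len(self.peaks)

    def __getitem__(self, i: int) -> Peak:
        return self.peaks[i]

    @property
    def values(self) -> np.ndarray:
        return np.array([p.value for p in self.peaks])


@dataclass(frozen=True)
class PupilPrior:
    """External pupil detection: center (px, full-resolution) + confidence."""

    x: float
    y: float
    confidence: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError("confidence must lie in [0, 1]")


@dataclass(frozen=True)
class CutoutSpec:
    """Integer-origin crop in downscaled-image coordinates."""

    x0: int
    y0: int
    size: int
    downscale: int = 2

    def to_full(self, x: float, y: float) -> tuple[float, float]:
        """Map cutout-local coordinates to the full-resolution frame."""
        return ((self.x0 + x) * self.downscale, (self.y0 + y) * self.downscale)

    def to_local(self, x: float, y: float) -> tuple[float, float]:
        """Map full-resolution coordinates into the cutout frame."""
        return (x / self.downscale - self.x0, y / self.downscale - self.y0)


def extract_peaks(heatmaps: Sequence[np.ndarray]) -> PeakSet:
    """Per heatmap, the position and value of the global maximum.

    Ties are broken by the smallest row, then smallest column index
    (C-order argmax).
    """
    if len(heatmaps) == 0:
        raise ValueError("need at least one heatmap")
    peaks = []
    for m in heatmaps:
        m = np.asarray(m)
        if m.size == 0:
            raise ValueError("empty heatmap")
        idx = int(np.argmax(m))
        r, c = np.unravel_index(idx, m.shape)
        peaks.append(Peak(x=int(c), y=int(r), value=float(m[r, c])))
    return PeakSet(peaks=tuple(peaks))


def select_best_two(peaks: PeakSet) -> list[tuple[int, Peak]]:
    """The two CR identities with the largest max-logits.

    Returns [(identity, peak), (identity, peak)] in descending-logit order;
    ties are broken toward the lower identity index.
    """
    if len(peaks) < 2:
        raise ValueError("need at least two CR heatmaps")
    order = sorted(range(len(peaks)), key=lambda i: (-peaks[i].value, i))
    return [(i, peaks[i]) for i in order[:2]]


def check_validity(peaks: PeakSet, threshold: float = 1.0) -> bool:
    """A frame is valid iff at least two CR max-logits are >= threshold."""
    return int(np.sum(peaks.values >= threshold)) >= 2 if len(peaks) else False


# ---------------------------------------------------------------------------
# cutouts


def downscale_by_two(image: np.ndarray) -> np.ndarray:
    """Downscale by a factor of two using 2x2 block means."""
    h, w = image.shape
    h2, w2 = h // 2 * 2, w // 2 * 2
    v = image[:h2, :w2].astype(np.float64)
    return v.reshape(h2 // 2, 2, w2 // 2, 2).mean(axis=(1, 3))


def extract_cutout(
    image: np.ndarray, center: tuple[float, float], size: int,
    downscale: int = 1,
) -> tuple[CutoutSpec, np.ndarray]:
    """Fixed-size crop centered on the rounded center, edge-padded at borders."""
    cx, cy = int(round(center[0])), int(round(center[1]))
    x0, y0 = cx - size // 2, cy - size // 2
    h, w = image.shape
    pad_l = max(0, -x0)
    pad_t = max(0, -y0)
    pad_r = max(0, x0 + size - w)
    pad_b = max(0, y0 + size - h)
    if pad_l or pad_t or pad_r or pad_b:
        image = np.pad(image, ((pad_t, pad_b), (pad_l, pad_r)), mode="edge")
    patch = image[y0 + pad_t : y0 + pad_t + size, x0 + pad_l : x0 + pad_l + size]
    return CutoutSpec(x0=x0, y0=y0, size=size, downscale=downscale), patch


def adaptive_cutout(
    image: np.ndarray,
    prior: Optional[PupilPrior],
    threshold: float,
    size: int,
    fallback_locator: Callable[[np.ndarray], Optional[tuple[float, float]]],
) -> tuple[CutoutSpec, np.ndarray]:
    """Confidence-gated cutout around an external pupil prior.

    The image is downscaled by a factor of two, then: if the prior's
    confidence is at least ``threshold``, the cutout is centered on the
    prior's center; otherwise a naive centered cutout is taken, the
    ``fallback_locator`` (a first inference pass) estimates the pupil center
    on it, and a second cutout is centered there.  A ``None`` locator result
    raises :class:`InvalidFrame`.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    small = downscale_by_two(image)
    h, w = small.shape
    if prior is not None and prior.confidence >= threshold:
        center = (prior.x / 2.0, prior.y / 2.0)
        return extract_cutout(small, center, size, downscale=2)
    naive_center = ((w - 1) / 2.0, (h - 1) / 2.0)
    spec, patch = extract_cutout(small, naive_center, size, downscale=2)
    located = fallback_locator(patch)
    if located is None:
        raise InvalidFrame("fallback pupil locator failed on the naive cutout")
    center = (spec.x0 + located[0], spec.y0 + located[1])
    return extract_cutout(small, center, size, downscale=2)


# ---------------------------------------------------------------------------
# probability map -> pupil


@dataclass(frozen=True)
class BlobCriteria:
    """Shape/size acceptance criteria for candidate pupil blobs."""

    min_area: float = 25.0
    max_area: float = 10000.0
    max_axis_ratio: float = 3.0


@dataclass(frozen=True)
class EllipseFit:
    x_c: float
    y_c: float
    r_major: float
    r_minor: float
    theta: float


@dataclass(frozen=True)
class PupilFit:
    center: tuple[float, float]
    ellipse: EllipseFit
    mask: np.ndarray


def fit_ellipse_to_mask(mask: np.ndarray) -> Optional[EllipseFit]:
    """Least-squares ellipse fit to the blob boundary (sub-pixel contour)."""
    contours = find_contours(mask.astype(float), 0.5)
    if not contours:
        return None
    pts = max(contours, key=len)[:, ::-1]  # (x, y)
    if len(np.unique(pts, axis=0)) < 5:
        return None
    model = EllipseModel.from_estimate(pts)
    if not model:
        return None
    xc, yc = model.center
    a, b = model.axis_lengths
    theta = model.theta
    r_major, r_minor = (a, b) if a >= b else (b, a)
    if a < b:
        theta += np.pi / 2.0
    return EllipseFit(x_c=float(xc), y_c=float(yc),
                      r_major=float(r_major), r_minor=float(r_minor),
                      theta=float(theta))


def prob_map_to_pupil(
    prob_map: np.ndarray,
    criteria: BlobCriteria = BlobCriteria(),
    threshold: float = 0.99,
) -> Optional[PupilFit]:
    """Segmentation probability map -> pupil center and fitted ellipse.

    Binarize at ``threshold``, fill holes, keep blobs passing the shape/size
    criteria, take the largest, and return its center of mass plus a
    least-squares ellipse fit to its boundary.  Returns ``None`` when no
    blob survives.
    """
    binary = np.asarray(prob_map) >= threshold
    if not binary.any():
        return None
    binary = ndimage.binary_fill_holes(binary)
    labeled = sk_label(binary)
    best = None
    for region in regionprops(labeled):
        if not (criteria.min_area <= region.area <= criteria.max_area):
            continue
        if region.axis_minor_length > 0:
            ratio = region.axis_major_length / region.axis_minor_length
            if ratio > criteria.max_axis_ratio:
                continue
        elif region.area > 1:
            continue
        if best is None or region.area > best.area:
            best = region
    if best is None:
        return None
    mask = labeled == best.label
    cy, cx = ndimage.center_of_mass(mask)
    ellipse = fit_ellipse_to_mask(mask)
    if ellipse is None:
        # degenerate boundary: fall back to moment-based axes
        ellipse = EllipseFit(
            x_c=float(cx), y_c=float(cy),
            r_major=best.axis_major_length / 2.0,
            r_minor=best.axis_minor_length / 2.0,
            theta=float(best.orientation),
        )
    return PupilFit(center=(float(cx), float(cy)), ellipse=ellipse, mask=mask)


def load_pupil_priors(csv_path) -> dict[str, PupilPrior]:
    """Adapter for an external pupil detector run offline.

    Reads a CSV with columns filename, x, y, confidence and returns one
    :class:`PupilPrior` per frame, keyed by filename.  Any detector that
    reports a center and a [0, 1] confidence (e.g., an ellipse-fitting
    pupil finder) can feed the adaptive-cutout logic this way.
    """
    import pandas as pd

    df = pd.read_csv(csv_path)
    required = {"filename", "x", "y", "confidence"}
    if not required <= set(df.columns):
        raise ValueError(f"prior CSV needs columns {sorted(required)}")
    return {
        str(row.filename): PupilPrior(
            x=float(row.x), y=float(row.y),
            confidence=float(np.clip(row.confidence, 0.0, 1.0)),
        )
        for row in df.itertuples()
    }


def recenter_if_near_edge(
    cutout: CutoutSpec, center: tuple[float, float], major_radius: float
) -> CutoutSpec:
    """Re-center the cutout when the pupil sits too close to its edge.

    ``center`` is in cutout-local coordinates.  If the distance from the
    center to the nearest cutout edge is strictly smaller than the ellipse's
    major-axis radius, a new cutout centered on the pupil estimate is
    returned; otherwise the cutout is unchanged.  At most one re-centering
    pass is applied.
    """
    cx, cy = center
    edge_dist = min(cx, cy, cutout.size - cx, cutout.size - cy)
    if edge_dist < major_radius:
        nx0 = cutout.x0 + int(round(cx)) - cutout.size // 2
        ny0 = cutout.y0 + int(round(cy)) - cutout.size // 2
        return CutoutSpec(x0=nx0, y0=ny0, size=cutout.size,
                          downscale=cutout.downscale)
    return cutout
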