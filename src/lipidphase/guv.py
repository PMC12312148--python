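"""GUV membrane profiling: circle detection, angular intensity, domains.

A giant unilamellar vesicle (GUV) imaged at its equator appears as a bright
ring. The pipeline mirrors a classic single-vesicle analysis:

1. Gaussian-smooth the micrograph (default sigma 1 px).
2. Detect the vesicle as a circle with a circular Hough transform.
3. At equal angular increments, search for the intensity maximum along rays
   through the circle centre within ±10 px of the detected perimeter.
4. Rasterize the maxima, dilate, fill holes, skeletonize to a 1-px closed
   membrane curve.
5. Read the gray value of every skeleton pixel together with its angle
   about the circle centroid (counterclockwise from +x, y pointing up).
6. Flag bright membrane domains as contiguous angular runs whose intensity
   exceeds a fold threshold (default 2x) over the median profile level.

Angles are degrees in [0, 360). Pixel size defaults to 64 nm/px.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import feature, measure, morphology, transform

__all__ = [
    "Micrograph",
    "VesicleCircle",
    "DomainInterval",
    "GuvProfile",
    "DetectionError",
    "smooth_image",
    "detect_vesicle_circle",
    "radial_max_positions",
    "build_membrane_mask",
    "angular_profile",
    "detect_domains",
    "profile_vesicle",
]


class DetectionError(RuntimeError):
    """No acceptable circle found in the image."""


@dataclass(frozen=True)
class Micrograph:
    """Single-channel fluorescence image with a physical pixel size."""

    pixels: np.ndarray
    pixel_size_nm: float = 64.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        object.__setattr__(self, "pixels", px)
        if px.ndim != 2:
            raise ValueError("image must be single-channel 2D")
        if px.shape[0] < 64 or px.shape[1] < 64:
            raise ValueError("image must be at least 64x64 px")
        if np.any(px < 0):
            raise ValueError("intensities must be nonnegative")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel size must be positive")


@dataclass(frozen=True)
class VesicleCircle:
    """Detected vesicle outline: continuous centre (x, y) and radius, in px."""

    center_xy: tuple[float, float]
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")


@dataclass(frozen=True)
class DomainInterval:
    """Angular extent of one bright membrane domain."""

    start_deg: float
    end_deg: float
    mean_fold: float

    @property
    def span_deg(self) -> float:
        return (self.end_deg - self.start_deg) % 360.0 or 360.0

    @property
    def center_deg(self) -> float:
        return (self.start_deg + self.span_deg / 2.0) % 360.0


@dataclass(frozen=True)
class GuvProfile:
    """Per-angle membrane intensity with the geometry it was read from."""

    angle: np.ndarray
    intensity: np.ndarray
    membrane_xy: np.ndarray
    circle: VesicleCircle
    domains: list[DomainInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        a = np.asarray(self.angle, dtype=float)
        i = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "angle", a)
        object.__setattr__(self, "intensity", i)
        if a.shape != i.shape or a.ndim != 1:
            raise ValueError("angle and intensity must be 1D of equal length")
        if np.any(np.diff(a) < 0):
            raise ValueError("angles must be sorted ascending")


def smooth_image(img: Micrograph, sigma: float = 1.0) -> Micrograph:
    """Gaussian smoothing with reflective boundaries; sigma = 0 is identity."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return Micrograph(img.pixels.copy(), img.pixel_size_nm)
    sm = ndimage.gaussian_filter(img.pixels, sigma=sigma, mode="reflect")
    return Micrograph(np.clip(sm, 0, None), img.pixel_size_nm)


def detect_vesicle_circle(
    img: Micrograph,
    r_range: tuple[int, int] = (20, 100),
    accumulator_threshold: float = 0.25,
    canny_sigma: float = 2.0,
) -> VesicleCircle:
    """Circular Hough detection of the dominant ring.

    Edges come from a Canny filter on the (already smoothed) image; the
    Hough accumulator is scanned over integer radii in ``r_range`` and the
    strongest peak is kept. The centre is refined to sub-pixel precision by
    the intensity-weighted centroid of a 5x5 accumulator neighbourhood.

    Raises :class:`DetectionError` when no accumulator peak reaches
    ``accumulator_threshold`` (normalized counts).
    """
    px = img.pixels
    span = px.max() - px.min()
    if span <= 0:
        raise DetectionError("image has no contrast")
    norm = (px - px.min()) / span
    edges = feature.canny(norm, sigma=canny_sigma)
    if not edges.any():
        raise DetectionError("no edges found")
    radii = np.arange(int(r_range[0]), int(r_range[1]) + 1)
    acc = transform.hough_circle(edges, radii)
    _, cx, cy, rad = transform.hough_circle_peaks(
        acc, radii, total_num_peaks=1, normalize=True
    )
    if len(cx) == 0:
        raise DetectionError("no circle candidates")
    ir = int(np.flatnonzero(radii == rad[0])[0])
    peak_val = acc[ir, cy[0], cx[0]]
    if peak_val < accumulator_threshold:
        raise DetectionError(
            f"best accumulator peak {peak_val:.3f} below threshold"
        )
    # sub-pixel centre from accumulator mass around the peak
    a = acc[ir]
    y0, x0 = int(cy[0]), int(cx[0])
    win = a[
        max(y0 - 2, 0) : y0 + 3,
        max(x0 - 2, 0) : x0 + 3,
    ]
    yy, xx = np.mgrid[max(y0 - 2, 0) : y0 + 3, max(x0 - 2, 0) : x0 + 3][
        :, : win.shape[0], : win.shape[1]
    ]
    m = win.sum()
    cx_f = float((win * xx).sum() / m)
    cy_f = float((win * yy).sum() / m)
    # Canny edges sit on the ring's slopes, so the accumulator radius can
    # lock onto an edge rather than the intensity crest; refine against the
    # angle-averaged radial profile
    r_ref = _refine_radius(px, (cx_f, cy_f), float(rad[0]))
    return VesicleCircle(center_xy=(cx_f, cy_f), radius=r_ref)


def _refine_radius(
    px: np.ndarray, center: tuple[float, float], r0: float, half_window: float = 8.0
) -> float:
    """Radius of maximum angle-averaged intensity near the Hough estimate."""
    cx, cy = center
    radii = np.arange(max(r0 - half_window, 1.0), r0 + half_window + 0.25, 0.25)
    angles = np.linspace(0.0, 2.0 * np.pi, 360, endpoint=False)
    x = cx + radii[:, None] * np.cos(angles)[None, :]
    y = cy - radii[:, None] * np.sin(angles)[None, :]
    h, w = px.shape
    np.clip(x, 0, w - 1, out=x)
    np.clip(y, 0, h - 1, out=y)
    prof = ndimage.map_coordinates(px, [y.ravel(), x.ravel()], order=1).reshape(
        radii.size, angles.size
    ).mean(axis=1)
    k = int(np.argmax(prof))
    if 0 < k < prof.size - 1:
        # parabolic sub-sample interpolation
        denom = prof[k - 1] - 2 * prof[k] + prof[k + 1]
        if denom < 0:
            k_off = 0.5 * (prof[k - 1] - prof[k + 1]) / denom
            return float(radii[k] + np.clip(k_off, -1, 1) * 0.25)
    return float(radii[k])


def _bilinear(px: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    # map_coordinates expects (row, col) = (y, x)
    return ndimage.map_coordinates(px, [y, x], order=1, mode="nearest")


def radial_max_positions(
    img: Micrograph,
    circle: VesicleCircle,
    n_angles: int = 360,
    window_px: float = 10.0,
    ray_length_factor: float = 5.0,
    step_px: float = 0.25,
) -> np.ndarray:
    """Membrane points from a radial maximum search.

    For each of ``n_angles`` equally spaced angles a ray of total length
    ``ray_length_factor`` x radius is drawn through the circle centre and
    the image is sampled bilinearly along it; the returned point is the
    sample of maximum intensity within ±``window_px`` of the perimeter
    radius. Angles whose search window leaves the image are skipped.

    Returns an (n, 2) array of (x, y) pixel coordinates.
    """
    if n_angles < 36:
        raise ValueError("need at least 36 angular increments")
    cx, cy = circle.center_xy
    r = circle.radius
    half_len = ray_length_factor * r / 2.0
    r_lo = max(r - window_px, 0.0)
    r_hi = min(r + window_px, half_len)
    radii = np.arange(r_lo, r_hi + step_px, step_px)
    h, w = img.pixels.shape
    pts = []
    for ang in np.linspace(0.0, 2.0 * np.pi, n_angles, endpoint=False):
        dx, dy = np.cos(ang), np.sin(ang)
        # y axis points up: image row decreases with increasing y
        x = cx + radii * dx
        y_img = cy - radii * dy
        inside = (x >= 0) & (x <= w - 1) & (y_img >= 0) & (y_img <= h - 1)
        if not inside.all():
            continue
        vals = _bilinear(img.pixels, x, y_img)
        k = int(np.argmax(vals))
        pts.append((x[k], y_img[k]))
    return np.array(pts, dtype=float).reshape(-1, 2)


def build_membrane_mask(
    points: np.ndarray,
    shape: tuple[int, int],
    dilation_radius: int = 2,
    min_hole_area: int = 50,
) -> tuple[np.ndarray, bool]:
    """Closed 1-px membrane curve from sampled membrane points.

    Points are rasterized, dilated with a disk, small holes filled, and the
    result skeletonized. Returns ``(skeleton, closed)`` where ``closed``
    reports whether the skeleton forms a single closed loop (Euler
    characteristic 0 under full connectivity).
    """
    points = np.asarray(points, dtype=float)
    if points.shape[0] < 3:
        raise ValueError("need at least 3 membrane points")
    mask = np.zeros(shape, dtype=bool)
    rows = np.clip(np.round(points[:, 1]).astype(int), 0, shape[0] - 1)
    cols = np.clip(np.round(points[:, 0]).astype(int), 0, shape[1] - 1)
    mask[rows, cols] = True
    mask = morphology.dilation(mask, morphology.disk(dilation_radius))
    mask = morphology.remove_small_holes(mask, max_size=min_hole_area)
    skel = morphology.skeletonize(mask)
    closed = bool(measure.euler_number(skel, connectivity=2) == 0)
    return skel, closed


def angular_profile(
    img: Micrograph, skeleton: np.ndarray, circle: VesicleCircle
) -> GuvProfile:
    """Gray value vs angle for every skeleton pixel.

    Angle is measured counterclockwise from the +x axis about the circle
    centroid with y up (image rows point down). Output is sorted by angle;
    pixels landing on identical angles are averaged.
    """
    rows, cols = np.nonzero(skeleton)
    cx, cy = circle.center_xy
    x = cols - cx
    y = cy - rows  # y up
    ang = np.degrees(np.arctan2(y, x)) % 360.0
    vals = img.pixels[rows, cols]
    order = np.argsort(ang, kind="stable")
    ang, vals = ang[order], vals[order]
    xy = np.stack([cols[order].astype(float), rows[order].astype(float)], axis=1)
    uniq, inverse, counts = np.unique(ang, return_inverse=True, return_counts=True)
    if uniq.size != ang.size:
        sums = np.zeros(uniq.size)
        np.add.at(sums, inverse, vals)
        vals = sums / counts
        xy_sum = np.zeros((uniq.size, 2))
        np.add.at(xy_sum, inverse, xy)
        xy = xy_sum / counts[:, None]
        ang = uniq
    return GuvProfile(angle=ang, intensity=vals, membrane_xy=xy, circle=circle)


def detect_domains(
    profile: GuvProfile,
    fold_threshold: float = 2.0,
    min_span_deg: float = 5.0,
) -> list[DomainInterval]:
    """Bright-domain detection on an angular profile.

    The baseline is the median profile intensity. Contiguous angular runs
    (circular, i.e. allowed to wrap through 0°) of at least ``min_span_deg``
    where the intensity reaches ``fold_threshold`` x baseline are reported
    with their extent and mean fold-elevation.
    """
    if len(profile.angle) == 0:
        return []
    baseline = float(np.median(profile.intensity))
    if baseline <= 0:
        return []
    above = profile.intensity >= fold_threshold * baseline
    if not above.any():
        return []
    if above.all():
        fold = float(np.mean(profile.intensity) / baseline)
        return [DomainInterval(0.0, 360.0, fold)]
    n = above.size
    # circular run detection: roll so the scan starts outside a run
    start0 = int(np.flatnonzero(~above)[0])
    idx = np.arange(n)
    rolled = (idx + start0) % n
    runs: list[list[int]] = []
    cur: list[int] = []
    for j in rolled:
        if above[j]:
            cur.append(j)
        elif cur:
            runs.append(cur)
            cur = []
    if cur:
        runs.append(cur)
    out = []
    for run in runs:
        a0 = profile.angle[run[0]]
        a1 = profile.angle[run[-1]]
        span = (a1 - a0) % 360.0
        if span < min_span_deg:
            continue
        fold = float(np.mean(profile.intensity[run]) / baseline)
        out.append(DomainInterval(float(a0), float(a1), fold))
    out.sort(key=lambda d: d.start_deg)
    return out


def profile_vesicle(
    img: Micrograph,
    r_range: tuple[int, int] = (20, 100),
    sigma: float = 1.0,
    n_angles: int = 360,
    fold_threshold: float = 2.0,
) -> GuvProfile:
    """End-to-end pipeline: smooth, detect, profile, flag domains."""
    sm = smooth_image(img, sigma=sigma)
    circle = detect_vesicle_circle(sm, r_range=r_range)
    pts = radial_max_positions(sm, circle, n_angles=n_angles)
    skel, _closed = build_membrane_mask(pts, sm.pixels.shape)
    prof = angular_profile(sm, skel, circle)
    domains = detect_domains(prof, fold_threshold=fold_threshold)
    return GuvProfile(
        angle=prof.angle,
        intensity=prof.intensity,
        membrane_xy=prof.membrane_xy,
        circle=circle,
        domains=domains,
    )
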