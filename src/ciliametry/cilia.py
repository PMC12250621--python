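"""Cilia detection and morphometry on ADCY3-channel images.

The pipeline has three phases: (1) contour extraction — Gaussian blur,
Canny edges with a median-relative threshold pair, morphological closing
(2x2) and erosion (1x1, identity by default), then external contours of the
connected foreground; (2) contour filtering on physical length and aspect
ratio; (3) measurement — minimum-area rotated rectangle for length, width
and raw axis angle, brightest-pixel base localization inside the filled
contour mask, and base-to-tip angle finalization with hemisphere mirroring.

Coordinate conventions
----------------------
Pixel coordinates are (x, y) = (column, row) with the row index increasing
downward.  All angles are computed after flipping to the y-up mathematical
convention: 0 deg points toward the image right and angles grow counter-
clockwise.  For left-hemisphere images the finalized angle is mirrored
across the vertical axis (theta -> 180 - theta, mod 360) so that angles are
effectively clockwise and medial/lateral directions are comparable across
hemispheres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from shapely.geometry import LineString, MultiPoint, Polygon
from skimage import feature, measure

from .io import CiliumRecord, Image2D, logger


@dataclass(frozen=True)
class Contour:
    """Boundary of one candidate object.

    ``points`` is the ordered sub-pixel boundary polyline in (x, y) pixel
    coordinates; ``filled_rc`` holds the (row, col) coordinates of every
    pixel inside the filled object, used for masks and centroids.
    """

    points: np.ndarray      # (n, 2) float, ordered boundary, (x, y)
    filled_rc: np.ndarray   # (m, 2) int, filled-interior pixel coords

    def __post_init__(self) -> None:
        if len(self.points) < 3:
            raise ValueError("a contour needs at least 3 boundary points")

    @property
    def centroid_xy(self) -> tuple[float, float]:
        rc = self.filled_rc
        return float(rc[:, 1].mean()), float(rc[:, 0].mean())


@dataclass(frozen=True)
class DetectionParams:
    """Tunable thresholds of the cilia detector (defaults follow the pipeline)."""

    canny_lower_factor: float = 0.67
    canny_upper_factor: float = 1.33
    canny_sigma: float = 1.0
    close_kernel: tuple[int, int] = (2, 2)
    erode_kernel: tuple[int, int] = (1, 1)
    erode_iterations: int = 1
    min_length_um: float = 1.0
    max_length_um: float = 15.0
    min_aspect: float = 1.5
    gaussian_blur_kernel: int = 3
    axis_aligned_box: bool = False       # use axis-aligned bounding box instead of min-area rect
    base_in_bounding_box: bool = False   # search brightest pixel in box instead of mask
    drop_border_contours: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.min_length_um < self.max_length_um:
            raise ValueError("need 0 < min_length_um < max_length_um")
        if self.min_aspect < 1:
            raise ValueError("min_aspect must be >= 1")
        if self.canny_lower_factor <= 0 or self.canny_upper_factor <= 0:
            raise ValueError("Canny factors must be > 0")
        if self.gaussian_blur_kernel < 1 or self.gaussian_blur_kernel % 2 == 0:
            raise ValueError("gaussian_blur_kernel must be odd and >= 1")


def gaussian_kernel_1d(ksize: int) -> np.ndarray:
    """Normalized 1D Gaussian taps for an odd kernel size.

    Sigma follows the conventional size-derived default
    ``0.3 * ((ksize - 1) / 2 - 1) + 0.8``.
    """
    sigma = 0.3 * ((ksize - 1) * 0.5 - 1) + 0.8
    x = np.arange(ksize) - (ksize - 1) / 2
    k = np.exp(-(x ** 2) / (2 * sigma ** 2))
    return k / k.sum()


def preprocess(image: Image2D, params: DetectionParams = DetectionParams()) -> Image2D:
    """Gaussian-blur the image (separable k x k kernel, mirrored borders)."""
    k = gaussian_kernel_1d(params.gaussian_blur_kernel)
    px = image.pixels.astype(np.float64)
    px = ndimage.correlate1d(px, k, axis=0, mode="mirror")
    px = ndimage.correlate1d(px, k, axis=1, mode="mirror")
    return replace(image, pixels=px)


def _binary_foreground(pixels: np.ndarray, params: DetectionParams) -> np.ndarray:
    med = float(np.median(pixels))
    low = params.canny_lower_factor * med
    high = params.canny_upper_factor * med
    edges = feature.canny(
        pixels.astype(np.float64),
        sigma=params.canny_sigma,
        low_threshold=low,
        high_threshold=high,
        use_quantiles=False,
    )
    edges = ndimage.binary_closing(edges, structure=np.ones(params.close_kernel, bool))
    if params.erode_kernel != (1, 1):  # a (1,1) kernel is the identity
        edges = ndimage.binary_erosion(edges, structure=np.ones(params.erode_kernel, bool),
                                       iterations=params.erode_iterations)
    return edges


def canny_thresholds(pixels: np.ndarray, params: DetectionParams = DetectionParams()) -> tuple[float, float]:
    """(lower, upper) hysteresis thresholds: factors times the median intensity."""
    med = float(np.median(pixels))
    return params.canny_lower_factor * med, params.canny_upper_factor * med


def contours_from_mask(mask: np.ndarray) -> list[Contour]:
    """External contours of the connected components of a binary mask.

    Interior holes are filled; each component contributes one ordered
    sub-pixel boundary (its longest 0.5-level iso-contour).
    """
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), int))
    slices = ndimage.find_objects(labels)
    out: list[Contour] = []
    for i, sl in enumerate(slices, start=1):
        comp = labels[sl] == i
        filled = ndimage.binary_fill_holes(comp)
        rc = np.argwhere(filled)
        rc[:, 0] += sl[0].start
        rc[:, 1] += sl[1].start
        padded = np.pad(filled.astype(float), 1)
        traces = measure.find_contours(padded, 0.5)
        if not traces:
            continue
        boundary = max(traces, key=len) - 1.0  # undo padding offset
        boundary[:, 0] += sl[0].start
        boundary[:, 1] += sl[1].start
        points = boundary[:, ::-1]             # (row, col) -> (x, y)
        if len(points) < 3:
            continue
        out.append(Contour(points=points, filled_rc=rc))
    return out


def extract_cilia_contours(image: Image2D,
                           params: DetectionParams = DetectionParams()) -> list[Contour]:
    """Phase 1: Canny + closing + erosion, then external contours."""
    binary = _binary_foreground(np.asarray(image.pixels), params)
    contours = contours_from_mask(binary)
    if params.drop_border_contours:
        h, w = image.shape
        margin = 2  # the edge detector itself excludes a ~2 px border
        contours = [
            c for c in contours
            if c.filled_rc[:, 0].min() >= margin and c.filled_rc[:, 1].min() >= margin
            and c.filled_rc[:, 0].max() < h - margin and c.filled_rc[:, 1].max() < w - margin
        ]
    return contours


def _min_area_rect(points: np.ndarray) -> tuple[float, float, float]:
    """(long_side_px, short_side_px, raw_angle_deg) of the minimum-area
    rotated rectangle enclosing ``points`` ((x, y), image coords).

    The raw angle is the orientation of the long axis in the y-up math
    convention, reduced modulo 180.  Collinear input yields width 0.
    """
    geom = MultiPoint(points).minimum_rotated_rectangle
    if isinstance(geom, LineString):
        (x0, y0), (x1, y1) = geom.coords[0], geom.coords[-1]
        length = math.hypot(x1 - x0, y1 - y0)
        ang = math.degrees(math.atan2(-(y1 - y0), x1 - x0)) % 180.0
        return length, 0.0, ang
    if not isinstance(geom, Polygon):  # single point
        return 0.0, 0.0, 0.0
    corners = np.asarray(geom.exterior.coords)[:4]
    e1 = corners[1] - corners[0]
    e2 = corners[2] - corners[1]
    s1, s2 = np.linalg.norm(e1), np.linalg.norm(e2)
    if s1 >= s2:
        long_side, short_side, axis = s1, s2, e1
    else:
        long_side, short_side, axis = s2, s1, e2
    ang = math.degrees(math.atan2(-axis[1], axis[0])) % 180.0
    return float(long_side), float(short_side), ang


def _axis_aligned_box(points: np.ndarray) -> tuple[float, float, float]:
    dx = float(points[:, 0].max() - points[:, 0].min())
    dy = float(points[:, 1].max() - points[:, 1].min())
    if dx >= dy:
        return dx, dy, 0.0
    return dy, dx, 90.0


def measure_cilium(contour: Contour, pixel_size_um: float,
                   params: DetectionParams = DetectionParams()) -> tuple[float, float, float]:
    """Phase 3a: (length_um, width_um, raw_angle_deg) from the bounding rectangle.

    Width 0 marks a degenerate (collinear) contour; callers should skip it.
    """
    if params.axis_aligned_box:
        long_px, short_px, ang = _axis_aligned_box(contour.points)
    else:
        long_px, short_px, ang = _min_area_rect(contour.points)
    return long_px * pixel_size_um, short_px * pixel_size_um, ang


def filter_cilia_contours(contours: list[Contour], image: Image2D,
                          params: DetectionParams = DetectionParams()) -> list[Contour]:
    """Phase 2: keep contours with min_length < L <= max_length (um) and
    aspect ratio L/W >= min_aspect; input order preserved."""
    kept = []
    for c in contours:
        length_um, width_um, _ = measure_cilium(c, image.pixel_size_um, params)
        if not params.min_length_um < length_um <= params.max_length_um:
            continue
        if width_um <= 0:
            logger.debug("degenerate contour (zero width) dropped")
            continue
        if length_um / width_um < params.min_aspect:
            continue
        kept.append(c)
    return kept


def locate_base(contour: Contour, image: Image2D,
                params: DetectionParams = DetectionParams()) -> tuple[int, int]:
    """Phase 3b: brightest pixel inside the filled contour mask, as (x, y).

    The basal body is assumed to be the most intensely stained part of the
    cilium.  Ties break to the smallest row, then the smallest column.
    """
    px = np.asarray(image.pixels)
    rc = contour.filled_rc
    if params.base_in_bounding_box:
        r0, r1 = rc[:, 0].min(), rc[:, 0].max()
        c0, c1 = rc[:, 1].min(), rc[:, 1].max()
        rr, cc = np.mgrid[r0:r1 + 1, c0:c1 + 1]
        rc = np.column_stack([rr.ravel(), cc.ravel()])
    if len(rc) == 0:
        raise ValueError("empty contour mask")
    order = np.lexsort((rc[:, 1], rc[:, 0]))  # raster order: row, then column
    rc = rc[order]
    vals = px[rc[:, 0], rc[:, 1]]
    best = int(np.argmax(vals))  # argmax returns the first maximum
    return int(rc[best, 1]), int(rc[best, 0])


def finalize_angle(raw_angle_deg: float, base_xy, centroid_xy, hemisphere: str) -> float:
    """Phase 3c: orient the axis angle from base toward tip, in [0, 360).

    The long-axis direction at ``raw_angle_deg`` is flipped by 180 deg when
    it points away from the base->centroid vector (y-up convention).  Left-
    hemisphere angles are then mirrored across the vertical axis.
    """
    bx, by = base_xy
    cx, cy = centroid_xy
    dx, dy = cx - bx, -(cy - by)  # flip image y-down to math y-up
    if dx == 0 and dy == 0:
        raise ValueError("base coincides with centroid; angle undefined")
    rad = math.radians(raw_angle_deg)
    if math.cos(rad) * dx + math.sin(rad) * dy < 0:
        raw_angle_deg += 180.0
    angle = raw_angle_deg % 360.0
    if hemisphere == "left":
        angle = (180.0 - angle) % 360.0
    return angle


def detect_cilia(image: Image2D, params: DetectionParams = DetectionParams(),
                 section_id: str = "", region_label: str = "",
                 zt: float = 0.0) -> list[CiliumRecord]:
    """Run the full three-phase pipeline on one ADCY3 image.

    Deterministic for fixed input and parameters.  Per-contour measurement
    failures are logged and skipped rather than propagated.
    """
    blurred = preprocess(image, params)
    contours = extract_cilia_contours(blurred, params)
    contours = filter_cilia_contours(contours, image, params)
    records: list[CiliumRecord] = []
    for c in contours:
        try:
            length_um, width_um, raw_angle = measure_cilium(c, image.pixel_size_um, params)
            base = locate_base(c, blurred, params)
            centroid = c.centroid_xy
            angle = finalize_angle(raw_angle, base, centroid, image.hemisphere)
        except ValueError as exc:
            logger.info("skipping contour: %s", exc)
            continue
        records.append(CiliumRecord(
            id=len(records),
            length_um=length_um,
            width_um=width_um,
            angle_deg=angle,
            base_xy=(float(base[0]), float(base[1])),
            centroid_xy=centroid,
            section_id=section_id,
            region_label=region_label,
            hemisphere=image.hemisphere,
            zt=zt,
        ))
    logger.info("detected %d cilia (%d candidate contours)", len(records), len(contours))
    return records
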