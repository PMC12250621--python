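"""DAPI nuclei detection for cilia-density quantification.

Three phases: (1) contour extraction — CLAHE, adaptive local-mean
thresholding, Euclidean distance transform (normalized to [0, 1] and
thresholded), dilation, external contours of the sure foreground;
(2) clustering — DBSCAN over contour centroids, each cluster merged into
the convex hull of all member points; (3) filtering on area and
circularity (4*pi*A / P^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from shapely.geometry import MultiPoint, Polygon
from sklearn.cluster import DBSCAN
from skimage import exposure
from skimage.filters import threshold_local

from .cilia import Contour, contours_from_mask
from .io import CellRecord, Image2D, logger


@dataclass(frozen=True)
class NucleiParams:
    clahe_clip: float = 2.0
    clahe_tile: tuple[int, int] = (8, 8)
    adaptive_block: int = 41
    adaptive_C: float = -10.0
    dist_thresh: float = 0.2
    dilate_kernel: tuple[int, int] = (3, 3)
    dilate_iterations: int = 1
    dbscan_eps_px: float = 30.0
    dbscan_min_samples: int = 1
    min_area_px: float = 20.0
    max_area_px: float = 1000.0
    min_circularity: float = 0.01

    def __post_init__(self) -> None:
        if self.min_area_px >= self.max_area_px:
            raise ValueError("min_area_px must be < max_area_px")
        if self.adaptive_block % 2 == 0:
            raise ValueError("adaptive_block must be odd")


def circularity(area: float, perimeter: float) -> float:
    """4*pi*Area / Perimeter^2 — 1 for an ideal disk, pi/4 for a square."""
    if perimeter <= 0:
        raise ValueError("perimeter must be positive")
    return 4.0 * np.pi * area / perimeter ** 2


def segment_nuclei_foreground(image: Image2D,
                              params: NucleiParams = NucleiParams()) -> np.ndarray:
    """Sure-foreground binary mask of nuclei.

    CLAHE -> adaptive mean threshold (block 41, offset -10 relative to the
    local mean) -> Euclidean distance transform normalized by its global
    maximum -> fixed threshold -> one dilation.  The sure-background and
    unknown regions are derivable from this mask but unused downstream.
    """
    px = np.asarray(image.pixels, dtype=np.float64)
    peak = px.max()
    if peak <= 0:
        return np.zeros(px.shape, bool)
    # CLAHE; the conventional clip limit counts multiples of the uniform
    # histogram bin, equalize_adapthist wants the bin-mass fraction: clip/256.
    norm = px / peak
    tiles_r, tiles_c = params.clahe_tile
    kernel = (max(1, px.shape[0] // tiles_r), max(1, px.shape[1] // tiles_c))
    eq = exposure.equalize_adapthist(norm, kernel_size=kernel,
                                     clip_limit=min(1.0, params.clahe_clip / 256.0))
    eq = eq * 255.0
    # adaptive mean threshold: foreground where pixel > local_mean - C
    local = threshold_local(eq, block_size=params.adaptive_block, method="mean",
                            offset=params.adaptive_C)
    binary = eq > local
    dist = ndimage.distance_transform_edt(binary)
    dmax = dist.max()
    if dmax <= 0:
        return np.zeros(px.shape, bool)
    fg = (dist / dmax) > params.dist_thresh
    fg = ndimage.binary_dilation(fg, structure=np.ones(params.dilate_kernel, bool),
                                 iterations=params.dilate_iterations)
    return fg


def extract_cell_contours(mask: np.ndarray) -> list[Contour]:
    """External contours (one per connected component; holes ignored)."""
    return contours_from_mask(mask)


def cluster_and_merge(contours: list[Contour],
                      params: NucleiParams = NucleiParams()) -> list[Contour]:
    """DBSCAN contour centroids (eps px, Euclidean) and merge each cluster
    into the convex hull of all member boundary points."""
    if not contours:
        return []
    centroids = np.array([c.centroid_xy for c in contours])
    labels = DBSCAN(eps=params.dbscan_eps_px,
                    min_samples=params.dbscan_min_samples).fit_predict(centroids)
    merged: list[Contour] = []
    for lab in np.unique(labels):
        members = [c for c, l in zip(contours, labels) if l == lab]
        pts = np.vstack([c.points for c in members])
        hull = MultiPoint(pts).convex_hull
        if not isinstance(hull, Polygon):
            logger.debug("degenerate hull skipped (collinear cluster)")
            continue
        hull_pts = np.asarray(hull.exterior.coords)[:-1]
        rc = np.vstack([c.filled_rc for c in members])
        merged.append(Contour(points=hull_pts, filled_rc=rc))
    return merged


def filter_cells(hulls: list[Contour],
                 params: NucleiParams = NucleiParams()) -> list[CellRecord]:
    """Keep hulls with min_area <= A <= max_area and circularity >= threshold."""
    records: list[CellRecord] = []
    for c in hulls:
        poly = Polygon(c.points)
        area = poly.area
        perimeter = poly.length
        if perimeter <= 0:
            logger.info("zero-perimeter hull skipped")
            continue
        circ = circularity(area, perimeter)
        if not params.min_area_px <= area <= params.max_area_px:
            continue
        if circ < params.min_circularity:
            continue
        cx, cy = poly.centroid.x, poly.centroid.y
        records.append(CellRecord(
            id=len(records),
            hull=c.points.copy(),
            centroid_xy=(float(cx), float(cy)),
            area_px2=float(area),
            perimeter_px=float(perimeter),
            circularity=float(circ),
        ))
    return records


def detect_cells(image: Image2D, params: NucleiParams = NucleiParams()) -> list[CellRecord]:
    """Full DAPI pipeline: segment -> contours -> cluster/merge -> filter."""
    mask = segment_nuclei_foreground(image, params)
    contours = extract_cell_contours(mask)
    hulls = cluster_and_merge(contours, params)
    records = filter_cells(hulls, params)
    logger.info("detected %d cells (%d raw contours, %d merged hulls)",
                len(records), len(contours), len(hulls))
    return records
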