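"""Synthetic micrographs, time series, and connectivity matrices with known
ground truth.

Every generator is a pure function of its parameters and seed.  Cilia are
rendered as anti-aliased capsules whose end-to-end extent equals the true
base-to-tip length (the round caps are inset), with a brighter blob at the
base so brightest-pixel base localization is well-posed; nuclei are
non-overlapping bright disks.  The rendered cilium angle equals the
two-argument arctangent of (tip - base) in the y-up math convention
exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import Image2D
from .network import ConnectivityMatrix


@dataclass(frozen=True)
class TrueCilium:
    base_xy: tuple[float, float]
    tip_xy: tuple[float, float]
    length_um: float
    angle_deg: float
    peak_intensity: float
    radius_px: float


@dataclass(frozen=True)
class TrueNucleus:
    center_xy: tuple[float, float]
    radius_px: float


@dataclass
class GroundTruthScene:
    image_shape: tuple[int, int]
    pixel_size_um: float
    cilia: list[TrueCilium] = field(default_factory=list)
    nuclei: list[TrueNucleus] = field(default_factory=list)
    noise_mean: float = 0.0
    noise_sd: float = 0.0
    psf_sigma_px: float = 0.0
    seed: int = 0


def _segment_distance_field(shape, p0, p1, pad: float):
    """Distance from each pixel (in a window around the segment) to segment
    p0-p1; returns (rows, cols, distances)."""
    x0, y0 = p0
    x1, y1 = p1
    rmin = max(0, int(min(y0, y1) - pad))
    rmax = min(shape[0] - 1, int(max(y0, y1) + pad) + 1)
    cmin = max(0, int(min(x0, x1) - pad))
    cmax = min(shape[1] - 1, int(max(x0, x1) + pad) + 1)
    rr, cc = np.mgrid[rmin:rmax + 1, cmin:cmax + 1]
    px, py = cc.astype(float), rr.astype(float)
    vx, vy = x1 - x0, y1 - y0
    seg_len2 = vx * vx + vy * vy
    if seg_len2 == 0:
        d = np.hypot(px - x0, py - y0)
    else:
        t = np.clip(((px - x0) * vx + (py - y0) * vy) / seg_len2, 0.0, 1.0)
        d = np.hypot(px - (x0 + t * vx), py - (y0 + t * vy))
    return rr, cc, d


def _min_segment_separation(a0, a1, b0, b1) -> float:
    """Minimum distance between two 2D segments (endpoint/projection checks)."""
    def pt_seg(p, q0, q1):
        vx, vy = q1[0] - q0[0], q1[1] - q0[1]
        l2 = vx * vx + vy * vy
        if l2 == 0:
            return math.hypot(p[0] - q0[0], p[1] - q0[1])
        t = max(0.0, min(1.0, ((p[0] - q0[0]) * vx + (p[1] - q0[1]) * vy) / l2))
        return math.hypot(p[0] - (q0[0] + t * vx), p[1] - (q0[1] + t * vy))

    def orient(p, q, r):
        return (q[0] - p[0]) * (r[1] - p[1]) - (q[1] - p[1]) * (r[0] - p[0])

    # proper intersection -> distance 0
    d1, d2 = orient(a0, a1, b0), orient(a0, a1, b1)
    d3, d4 = orient(b0, b1, a0), orient(b0, b1, a1)
    if ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0)):
        return 0.0
    return min(pt_seg(a0, b0, b1), pt_seg(a1, b0, b1),
               pt_seg(b0, a0, a1), pt_seg(b1, a0, a1))


def synth_cilia_image(n: int,
                      image_shape: tuple[int, int] = (1024, 1024),
                      pixel_size_um: float = 0.5,
                      length_range_um: tuple[float, float] = (2.0, 12.0),
                      radius_range_px: tuple[float, float] = (0.8, 1.2),
                      shaft_intensity: float = 120.0,
                      base_boost: float = 110.0,
                      background: float = 40.0,
                      noise_gain: float = 4.0,
                      read_noise_sd: float = 2.0,
                      psf_sigma_px: float = 0.8,
                      min_sep_px: float = 20.0,
                      border_px: float = 16.0,
                      hemisphere: str = "right",
                      seed: int = 0,
                      max_tries: int = 20000) -> tuple[Image2D, GroundTruthScene]:
    """Render ``n`` well-separated synthetic cilia with known ground truth.

    Each cilium is a straight capsule of random length (uniform in
    ``length_range_um``), random orientation (uniform on [0, 360)), and
    random half-width; the capsule's end-to-end extent equals the true
    length and a brighter base blob (peak >= 1.5x shaft) marks the base.
    Centerlines of distinct cilia are at least ``min_sep_px`` apart.

    Noise is photon-limited: each pixel gets Gaussian noise with variance
    ``read_noise_sd**2 + noise_gain * signal``, the usual Gaussian
    approximation of shot noise plus camera read noise, so the signal-to-
    noise ratio at the shaft is ``shaft_intensity / sqrt(noise_gain *
    (background + shaft_intensity))`` (~5 at the defaults).
    """
    rng = np.random.default_rng(seed)
    h, w = image_shape
    placed: list[tuple] = []
    cilia: list[TrueCilium] = []
    tries = 0
    while len(cilia) < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {n} cilia with separation {min_sep_px}px "
                f"in a {image_shape} image")
        length_um = rng.uniform(*length_range_um)
        angle = rng.uniform(0.0, 360.0)
        radius = rng.uniform(*radius_range_px)
        length_px = length_um / pixel_size_um
        bx = rng.uniform(border_px, w - 1 - border_px)
        by = rng.uniform(border_px, h - 1 - border_px)
        rad = math.radians(angle)
        tx = bx + length_px * math.cos(rad)
        ty = by - length_px * math.sin(rad)  # image y grows downward
        if not (border_px <= tx <= w - 1 - border_px and
                border_px <= ty <= h - 1 - border_px):
            continue
        seg = ((bx, by), (tx, ty))
        if any(_min_segment_separation(*seg, *other) < min_sep_px for other in placed):
            continue
        placed.append(seg)
        cilia.append(TrueCilium(
            base_xy=(bx, by), tip_xy=(tx, ty),
            length_um=length_um, angle_deg=angle,
            peak_intensity=shaft_intensity + base_boost,
            radius_px=radius,
        ))

    canvas = np.zeros(image_shape, dtype=np.float64)
    for c in cilia:
        (bx, by), (tx, ty) = c.base_xy, c.tip_xy
        ux, uy = tx - bx, ty - by
        norm = math.hypot(ux, uy)
        ux, uy = ux / norm, uy / norm
        r = c.radius_px
        # inset the round caps so the rendered extent equals the true length
        p0 = (bx + r * ux, by + r * uy)
        p1 = (tx - r * ux, ty - r * uy)
        rr, cc, d = _segment_distance_field(image_shape, p0, p1, pad=r + 3)
        coverage = np.clip(r + 0.5 - d, 0.0, 1.0)  # anti-aliased capsule
        np.maximum.at(canvas, (rr, cc), shaft_intensity * coverage)
        # brighter basal blob centered one radius inside the base end
        rr2, cc2, d2 = _segment_distance_field(image_shape, p0, p0, pad=6)
        blob = base_boost * np.exp(-(d2 ** 2) / (2 * 1.5 ** 2))
        np.add.at(canvas, (rr2, cc2), blob)

    if psf_sigma_px > 0:
        canvas = ndimage.gaussian_filter(canvas, psf_sigma_px, mode="mirror")
    canvas += background
    sd = np.sqrt(read_noise_sd ** 2 + noise_gain * np.maximum(canvas, 0.0))
    canvas += rng.normal(0.0, 1.0, size=image_shape) * sd
    pixels = np.clip(np.round(canvas), 0, 255).astype(np.uint8)

    scene = GroundTruthScene(
        image_shape=image_shape, pixel_size_um=pixel_size_um, cilia=cilia,
        noise_mean=background,
        noise_sd=float(np.sqrt(read_noise_sd ** 2 + noise_gain * background)),
        psf_sigma_px=psf_sigma_px,
        seed=seed,
    )
    return Image2D(pixels, pixel_size_um, hemisphere, "ADCY3"), scene


def synth_nuclei_image(n: int,
                       image_shape: tuple[int, int] = (1024, 1024),
                       pixel_size_um: float = 0.5,
                       radius_range_px: tuple[float, float] = (6.0, 10.0),
                       intensity: float = 180.0,
                       background: float = 15.0,
                       noise_sd: float = 8.0,
                       min_center_sep_px: float = 45.0,
                       border_px: float = 20.0,
                       seed: int = 0,
                       max_tries: int = 20000) -> tuple[Image2D, GroundTruthScene]:
    """Render ``n`` non-overlapping bright disks (DAPI-like nuclei).

    Center separation exceeds the downstream DBSCAN merge radius so each
    disk remains its own cluster.
    """
    rng = np.random.default_rng(seed)
    h, w = image_shape
    centers: list[tuple[float, float]] = []
    nuclei: list[TrueNucleus] = []
    tries = 0
    while len(nuclei) < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(f"could not place {n} nuclei")
        r = rng.uniform(*radius_range_px)
        cx = rng.uniform(border_px, w - 1 - border_px)
        cy = rng.uniform(border_px, h - 1 - border_px)
        if any(math.hypot(cx - ox, cy - oy) < min_center_sep_px for ox, oy in centers):
            continue
        centers.append((cx, cy))
        nuclei.append(TrueNucleus(center_xy=(cx, cy), radius_px=r))

    canvas = np.zeros(image_shape, dtype=np.float64)
    for nuc in nuclei:
        cx, cy = nuc.center_xy
        rr, cc, d = _segment_distance_field(image_shape, (cx, cy), (cx, cy),
                                            pad=nuc.radius_px + 3)
        coverage = np.clip(nuc.radius_px + 0.5 - d, 0.0, 1.0)
        np.maximum.at(canvas, (rr, cc), intensity * coverage)
    canvas += background
    canvas += rng.normal(0.0, noise_sd, size=image_shape)
    pixels = np.clip(np.round(canvas), 0, 255).astype(np.uint8)
    scene = GroundTruthScene(image_shape=image_shape, pixel_size_um=pixel_size_um,
                             nuclei=nuclei, noise_mean=background, noise_sd=noise_sd,
                             seed=seed)
    return Image2D(pixels, pixel_size_um, "right", "DAPI"), scene


def synth_timeseries(rhythm_params: dict,
                     sections_per_zt: int = 4,
                     zt_grid: Sequence[float] = tuple(range(0, 24, 2)),
                     seed: int = 0) -> pd.DataFrame:
    """Section-level cosine time series per region.

    ``rhythm_params`` maps region -> dict(mesor, amplitude, phase, noise_sd).
    Each (region, ZT) gets ``sections_per_zt`` sections with value
    mesor + amplitude*cos(2*pi*(t - phase)/24) + N(0, noise_sd).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for region, pars in rhythm_params.items():
        mesor = pars["mesor"]
        amplitude = pars.get("amplitude", 0.0)
        phase = pars.get("phase", 0.0)
        noise_sd = pars.get("noise_sd", 0.0)
        for zt in zt_grid:
            signal = mesor + amplitude * math.cos(2 * math.pi * (zt - phase) / 24.0)
            for s in range(sections_per_zt):
                value = signal + rng.normal(0.0, noise_sd)
                rows.append({
                    "region_label": region, "zt": float(zt),
                    "section_id": f"{region}_zt{zt:g}_s{s}",
                    "n_cilia": 1, "mean_length_um": value,
                    "circ_mean_angle_deg": value % 360.0,
                    "hemisphere": "right",
                })
    return pd.DataFrame(rows)


def synth_connectivity(communities: dict[str, int],
                       w_in: float = 1.0,
                       w_out: float = 0.05,
                       noise_cv: float = 0.1,
                       flag_base_rate: float = 0.1,
                       flag_enrichment: dict[tuple[int, int], float] | None = None,
                       seed: int = 0) -> tuple[ConnectivityMatrix, dict[tuple[str, str], bool]]:
    """Planted-partition connectivity plus optional enriched correlation flags.

    Within-community weights ~ w_in, between ~ w_out, both with
    multiplicative lognormal noise.  Flags are Bernoulli(base rate), with
    per-community-pair rate multipliers from ``flag_enrichment``.
    """
    if not w_in > w_out >= 0:
        raise ValueError("need w_in > w_out >= 0")
    rng = np.random.default_rng(seed)
    regions = sorted(communities)
    n = len(regions)
    W = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            base = w_in if communities[regions[i]] == communities[regions[j]] else w_out
            W[i, j] = base * rng.lognormal(0.0, noise_cv) if base > 0 else 0.0
    flags: dict[tuple[str, str], bool] = {}
    enrich = flag_enrichment or {}
    for i in range(n):
        for j in range(i + 1, n):
            ci, cj = communities[regions[i]], communities[regions[j]]
            key = (min(ci, cj), max(ci, cj))
            rate = min(1.0, flag_base_rate * enrich.get(key, 1.0))
            flags[(regions[i], regions[j])] = bool(rng.random() < rate)
    return ConnectivityMatrix(regions=regions, W=W, communities=dict(communities)), flags


# ---------------------------------------------------------------------------
# Default detection benchmark ("bench-v1"): 20 images, 1024x1024 px at
# 0.5 um/px, ~25 well-separated cilia each, SNR ~ 5, seed 42.

BENCH_V1 = dict(
    n_images=20,
    n_cilia=25,
    image_shape=(1024, 1024),
    pixel_size_um=0.5,
    length_range_um=(4.0, 12.0),
    min_sep_px=20.0,
    seed=42,
)


def bench_v1_scenes(seed: int = 42, n_images: int | None = None):
    """Yield (image, scene) pairs of the default benchmark.

    Per-image seeds are drawn from a seed sequence rooted at ``seed`` so the
    whole benchmark is reproducible from one integer.
    """
    cfg = dict(BENCH_V1)
    if n_images is not None:
        cfg["n_images"] = n_images
    child_seeds = np.random.SeedSequence(seed).spawn(cfg["n_images"])
    for ss in child_seeds:
        sub = int(ss.generate_state(1)[0])
        yield synth_cilia_image(
            n=cfg["n_cilia"],
            image_shape=cfg["image_shape"],
            pixel_size_um=cfg["pixel_size_um"],
            length_range_um=cfg["length_range_um"],
            min_sep_px=cfg["min_sep_px"],
            seed=sub,
        )
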