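"""Scoring of detections against ground truth: recall, length/angle MAE,
and the 2D-projection length-error estimate."""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np

from .circular import circular_diff
from .io import CiliumRecord, logger
from .synth import GroundTruthScene, TrueCilium


@dataclass(frozen=True)
class ValidationReport:
    n_truth: int
    n_detected: int
    n_matched: int
    recall: float
    mae_length_um: float
    mae_angle_deg: float
    match_dist_px: float

    def as_dict(self) -> dict:
        return asdict(self)


def match_detections(detected: Sequence[CiliumRecord],
                     truth: Sequence[TrueCilium],
                     max_dist_px: float = 5.0) -> list[tuple[int, int, float]]:
    """Greedy nearest-neighbor matching on base positions.

    Candidate (detection, truth) pairs within ``max_dist_px`` are sorted by
    distance (ties by index) and accepted greedily, each side used at most
    once.  Returns (detected_idx, truth_idx, distance) triples.
    """
    candidates = []
    for i, d in enumerate(detected):
        for j, t in enumerate(truth):
            dist = math.hypot(d.base_xy[0] - t.base_xy[0], d.base_xy[1] - t.base_xy[1])
            if dist <= max_dist_px:
                candidates.append((dist, i, j))
    candidates.sort()
    used_d: set[int] = set()
    used_t: set[int] = set()
    matches = []
    for dist, i, j in candidates:
        if i in used_d or j in used_t:
            continue
        used_d.add(i)
        used_t.add(j)
        matches.append((i, j, dist))
    return matches


def score(matches: Sequence[tuple[int, int, float]],
          detected: Sequence[CiliumRecord],
          truth: Sequence[TrueCilium],
          max_dist_px: float = 5.0) -> ValidationReport:
    """Recall and mean absolute errors over matched pairs.

    Angular error uses the wrapped circular difference (359 vs 1 deg is a
    2-deg error, not 358).
    """
    if not truth:
        raise ValueError("cannot score against empty ground truth")
    if matches:
        dl = [abs(detected[i].length_um - truth[j].length_um) for i, j, _ in matches]
        da = [circular_diff(detected[i].angle_deg, truth[j].angle_deg)
              for i, j, _ in matches]
        mae_l, mae_a = float(np.mean(dl)), float(np.mean(da))
    else:
        mae_l = mae_a = float("nan")
    return ValidationReport(
        n_truth=len(truth),
        n_detected=len(detected),
        n_matched=len(matches),
        recall=len(matches) / len(truth),
        mae_length_um=mae_l,
        mae_angle_deg=mae_a,
        match_dist_px=max_dist_px,
    )


def score_scene(detected: Sequence[CiliumRecord], scene: GroundTruthScene,
                max_dist_px: float = 5.0) -> ValidationReport:
    matches = match_detections(detected, scene.cilia, max_dist_px)
    return score(matches, detected, scene.cilia, max_dist_px)


def projection_error(true_length_um: float, depth_extent_um: float) -> float:
    """In-plane length of a 3D segment of length L spanning depth dz:
    sqrt(L^2 - dz^2) (Pythagorean projection; always <= L)."""
    if not 0 <= depth_extent_um <= true_length_um:
        raise ValueError("need 0 <= depth_extent_um <= true_length_um")
    return math.sqrt(true_length_um ** 2 - depth_extent_um ** 2)


def run_benchmark(seed: int = 42, n_images: int | None = None,
                  max_dist_px: float = 5.0) -> ValidationReport:
    """Detect cilia on the default synthetic benchmark and score the pooled
    detections against the pooled ground truth."""
    from .cilia import DetectionParams, detect_cilia
    from .synth import bench_v1_scenes

    params = DetectionParams()
    all_matches: list[tuple[int, int, float]] = []
    pooled_detected: list[CiliumRecord] = []
    pooled_truth: list[TrueCilium] = []
    for image, scene in bench_v1_scenes(seed=seed, n_images=n_images):
        detected = detect_cilia(image, params)
        matches = match_detections(detected, scene.cilia, max_dist_px)
        off_d, off_t = len(pooled_detected), len(pooled_truth)
        all_matches.extend((i + off_d, j + off_t, d) for i, j, d in matches)
        pooled_detected.extend(detected)
        pooled_truth.extend(scene.cilia)
    report = score(all_matches, pooled_detected, pooled_truth, max_dist_px)
    logger.info("benchmark: recall=%.4f mae_length=%.3f um mae_angle=%.3f deg",
                report.recall, report.mae_length_um, report.mae_angle_deg)
    return report
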