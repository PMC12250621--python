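"""Density, per-section aggregation, region averaging, and length histograms."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .circular import circular_mean
from .io import CiliumRecord


@dataclass(frozen=True)
class SectionSummary:
    """Per-section means — the unit of all downstream statistics."""

    section_id: str
    region_label: str
    zt: float
    n_cilia: int
    mean_length_um: float
    circ_mean_angle_deg: float
    hemisphere: str


@dataclass(frozen=True)
class DensityResult:
    region_label: str
    n_cilia: int
    n_cells: int
    density_pct: float


def cilia_density(n_cilia: int, n_cells: int) -> float:
    """Percentage of stained cilia relative to the number of stained cells."""
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    if n_cilia < 0:
        raise ValueError("counts must be non-negative")
    return 100.0 * n_cilia / n_cells


def summarize_section(records: Sequence[CiliumRecord]) -> SectionSummary:
    """Arithmetic mean of lengths and circular mean of angles of one section."""
    if not records:
        raise ValueError("cannot summarize an empty section")
    section_ids = {r.section_id for r in records}
    if len(section_ids) != 1:
        raise ValueError(f"records span multiple sections: {sorted(section_ids)}")
    first = records[0]
    return SectionSummary(
        section_id=first.section_id,
        region_label=first.region_label,
        zt=first.zt,
        n_cilia=len(records),
        mean_length_um=float(np.mean([r.length_um for r in records])),
        circ_mean_angle_deg=circular_mean([r.angle_deg for r in records]),
        hemisphere=first.hemisphere,
    )


def summarize_sections(records: Sequence[CiliumRecord]) -> list[SectionSummary]:
    """Group records by (region, section, hemisphere) and summarize each group."""
    groups: dict[tuple, list[CiliumRecord]] = {}
    for r in records:
        groups.setdefault((r.region_label, r.section_id, r.hemisphere), []).append(r)
    return [summarize_section(g) for g in (groups[k] for k in sorted(groups))]


def sections_to_frame(sections: Iterable[SectionSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in sections])


def region_average(records: Sequence[CiliumRecord],
                   method: Literal["direct", "section_based"] = "direct",
                   measure: Literal["length", "angle"] = "length",
                   ) -> tuple[float, float]:
    """Per-region mean and SEM under either averaging scheme.

    ``direct`` averages every cilium individually; ``section_based`` first
    collapses each section to one value and averages those (SEM over
    sections).  Angle means are circular at both levels.
    """
    if not records:
        raise ValueError("empty input")
    if method == "direct":
        if measure == "length":
            vals = np.array([r.length_um for r in records], dtype=float)
            mean = float(vals.mean())
        else:
            vals = np.array([r.angle_deg for r in records], dtype=float)
            mean = circular_mean(vals)
        n = len(vals)
        sem = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
        return mean, sem
    if method == "section_based":
        sections = summarize_sections(records)
        if measure == "length":
            vals = np.array([s.mean_length_um for s in sections], dtype=float)
            mean = float(vals.mean())
        else:
            vals = np.array([s.circ_mean_angle_deg for s in sections], dtype=float)
            mean = circular_mean(vals)
        n = len(vals)
        sem = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
        return mean, sem
    raise ValueError(f"unknown method {method!r}")


def length_histogram(lengths_um, bin_width_um: float = 0.6,
                     origin: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Percent-frequency histogram of lengths in fixed-width bins anchored at
    ``origin``; returns (bin_edges, percent_per_bin) over the occupied range.

    Percentages sum to 100 (up to rounding) for non-empty input.
    """
    if bin_width_um <= 0:
        raise ValueError("bin_width_um must be positive")
    x = np.asarray(lengths_um, dtype=float)
    if x.size == 0:
        return np.array([origin, origin + bin_width_um]), np.array([])
    lo = int(np.floor((x.min() - origin) / bin_width_um))
    hi = int(np.floor((x.max() - origin) / bin_width_um)) + 1
    edges = origin + bin_width_um * np.arange(lo, hi + 1)
    counts, _ = np.histogram(x, bins=edges)
    return edges, 100.0 * counts / x.size
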