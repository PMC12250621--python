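"""Circular (angular) statistics: mean direction, wrapped differences, rose bins."""

from __future__ import annotations

import numpy as np

#: Resultant-vector lengths below this are treated as an undefined mean
#: (e.g., a perfectly antipodal angle set).
RESULTANT_EPS = 1e-12


class UndefinedCircularMeanError(ValueError):
    """Raised when the resultant vector of an angle set is (numerically) zero."""


def circular_mean(angles_deg) -> float:
    """Mean direction of angles in degrees, in [0, 360).

    Angles are mapped to unit vectors; the mean sine and cosine feed a
    two-argument arctangent, converted back to degrees with 360 added to
    negative values.
    """
    a = np.asarray(angles_deg, dtype=float)
    if a.size == 0:
        raise ValueError("circular_mean of empty set")
    rad = np.deg2rad(a)
    mean_sin = np.sin(rad).mean()
    mean_cos = np.cos(rad).mean()
    if np.hypot(mean_sin, mean_cos) < RESULTANT_EPS:
        raise UndefinedCircularMeanError(
            "resultant vector length below tolerance; mean direction undefined"
        )
    deg = np.rad2deg(np.arctan2(mean_sin, mean_cos))
    if deg < 0:
        deg += 360.0
    return float(deg % 360.0)


def circular_diff(a_deg: float, b_deg: float) -> float:
    """Wrapped absolute angular difference in [0, 180]."""
    d = abs(float(a_deg) - float(b_deg)) % 360.0
    return min(d, 360.0 - d)


def rose_histogram(angles_deg, bin_deg: int = 30) -> np.ndarray:
    """Counts of angles per ``bin_deg``-wide bin [0, b), [b, 2b), ...

    360 must be divisible by ``bin_deg``; counts sum to the number of angles.
    """
    if bin_deg <= 0 or 360 % bin_deg != 0:
        raise ValueError(f"bin width {bin_deg} must evenly divide 360")
    a = np.mod(np.asarray(angles_deg, dtype=float), 360.0)
    nbins = 360 // bin_deg
    counts, _ = np.histogram(a, bins=nbins, range=(0.0, 360.0))
    return counts
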