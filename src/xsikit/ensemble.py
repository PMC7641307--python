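"""Peaks, conformer populations and free-energy differences from distributions.

A recovered distance distribution typically shows one peak per conformer;
the area under each peak measures that conformer's population, and the
ratio of populations gives the stacking free-energy preference through
Delta-Delta-G = R T ln(p_major / p_minor).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .maxent import DistanceDistribution

#: gas constant, kcal / (mol K)
R_KCAL = 1.9872e-3
#: standard-state temperature, K (configurable in delta_g)
T_STANDARD = 298.15


@dataclass
class Peak:
    """One resolved population: mode, boundaries, area, mean and width."""

    mode: float     # Angstrom, at grid resolution (no sub-grid interpolation)
    left: float     # Angstrom, inter-peak minimum or support edge
    right: float
    area: float     # probability mass in [left, right]
    mean: float     # Angstrom
    sd: float       # Angstrom


@dataclass
class EnsembleSummary:
    """Peaks ordered by area with population fractions and Delta-Delta-G."""

    peaks: list[Peak]                    # descending area
    fractions: tuple[float, ...]         # renormalized, descending
    delta_g_kcal: float | None           # None for a single-state ensemble
    condition: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "mode_A": [p.mode for p in self.peaks],
            "left_A": [p.left for p in self.peaks],
            "right_A": [p.right for p in self.peaks],
            "area": [p.area for p in self.peaks],
            "fraction": list(self.fractions),
            "mean_A": [p.mean for p in self.peaks],
            "sd_A": [p.sd for p in self.peaks],
        })


def _segment_peak(d: np.ndarray, w: np.ndarray, lo: int, hi: int) -> Peak:
    """Build a Peak from the inclusive index range [lo, hi]."""
    seg_w = w[lo:hi + 1]
    seg_d = d[lo:hi + 1]
    area = float(seg_w.sum())
    mode = float(seg_d[int(np.argmax(seg_w))])
    if area > 0:
        mean = float(np.sum(seg_d * seg_w) / area)
        sd = float(np.sqrt(max(np.sum((seg_d - mean) ** 2 * seg_w) / area, 0.0)))
    else:
        mean, sd = mode, 0.0
    return Peak(mode=mode, left=float(seg_d[0]), right=float(seg_d[-1]),
                area=area, mean=mean, sd=sd)


def find_peaks(dist: DistanceDistribution, min_area: float = 0.02) -> list[Peak]:
    """Partition a distribution into peaks at inter-peak minima.

    Local maxima of the weight vector define candidate modes (plateaus
    count once); the boundary between adjacent modes sits at the minimum
    between them.  Peaks with area below ``min_area`` — typically ripple
    from the inversion — are merged into the nearest retained peak.  A
    flat or single-mode distribution yields one peak spanning the support.
    Peaks are returned ordered by position.
    """
    d, w = dist.d, dist.weights
    if d.size == 0 or w.sum() <= 0:
        raise ValueError("empty distribution")

    # strict local maxima with plateau handling
    modes: list[int] = []
    i = 0
    n = w.size
    while i < n:
        j = i
        while j + 1 < n and w[j + 1] == w[i]:
            j += 1
        left_ok = i == 0 or w[i - 1] < w[i]
        right_ok = j == n - 1 or w[j + 1] < w[i]
        if left_ok and right_ok and w[i] > 0:
            modes.append(i)
        i = j + 1
    if not modes:
        modes = [int(np.argmax(w))]

    # boundaries at the minimum between consecutive modes
    segments: list[tuple[int, int]] = []
    start = 0
    for k in range(len(modes) - 1):
        cut = modes[k] + int(np.argmin(w[modes[k]:modes[k + 1] + 1]))
        segments.append((start, cut))
        start = cut + 1
    segments.append((start, n - 1))
    peaks = [_segment_peak(d, w, lo, hi) for lo, hi in segments]

    # merge sub-threshold peaks into the nearest retained neighbor
    while len(peaks) > 1:
        areas = [p.area for p in peaks]
        k = int(np.argmin(areas))
        if areas[k] >= min_area:
            break
        lo_k, hi_k = segments[k]
        if k == 0:
            into = 1
        elif k == len(peaks) - 1:
            into = k - 1
        else:
            into = k - 1 if abs(peaks[k - 1].mode - peaks[k].mode) <= \
                abs(peaks[k + 1].mode - peaks[k].mode) else k + 1
        lo_i, hi_i = segments[into]
        merged = (min(lo_k, lo_i), max(hi_k, hi_i))
        segments[min(k, into)] = merged
        del segments[max(k, into)]
        peaks = [_segment_peak(d, w, lo, hi) for lo, hi in segments]
    return peaks


def population_fractions(peaks: list[Peak]) -> tuple[float, ...]:
    """Peak areas renormalized over retained peaks, ordered major -> minor."""
    if not peaks:
        raise ValueError("need at least one peak")
    areas = np.array(sorted((p.area for p in peaks), reverse=True))
    return tuple(areas / areas.sum())


def delta_g(p_major: float, p_minor: float,
            temperature: float = T_STANDARD) -> float:
    """Free-energy preference R T ln(p_major / p_minor) in kcal/mol."""
    if p_major <= 0 or p_minor <= 0:
        raise ValueError("populations must be positive")
    return R_KCAL * temperature * float(np.log(p_major / p_minor))


def summarize(dist: DistanceDistribution, min_area: float = 0.02,
              temperature: float = T_STANDARD,
              condition: dict | None = None) -> EnsembleSummary:
    """Full ensemble summary: peaks by area, fractions, and Delta-Delta-G."""
    peaks = sorted(find_peaks(dist, min_area=min_area),
                   key=lambda p: p.area, reverse=True)
    fractions = population_fractions(peaks)
    ddg = delta_g(fractions[0], fractions[1], temperature) if len(peaks) > 1 else None
    return EnsembleSummary(peaks=peaks, fractions=fractions, delta_g_kcal=ddg,
                           condition=dict(condition or {}))
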