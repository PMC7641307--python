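"""Two-state smFRET trace idealization and dwell-time kinetics.

The junction interconverts between two stacked conformers: isoI (large
inter-dye distance, low FRET) and isoII (small inter-dye distance, high
FRET).  A transparent threshold idealizer with a minimum-dwell filter
assigns each frame to a state; rate constants follow from the mean dwell
time in each state with a dead-time correction for the events the filter
cannot detect.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: low-FRET state index (isoI) and high-FRET state index (isoII)
ISO_I, ISO_II = 0, 1


@dataclass
class StateModel:
    """Two-state kinetic model: FRET efficiencies and interconversion rates."""

    e_low: float = 0.14        # isoI efficiency
    e_high: float = 0.58       # isoII efficiency
    k_i_to_ii: float = 45.6    # 1/s, isoI -> isoII (forward)
    k_ii_to_i: float = 7.9     # 1/s, isoII -> isoI

    def __post_init__(self) -> None:
        for e in (self.e_low, self.e_high):
            if not 0.0 <= e <= 1.0:
                raise ValueError("FRET efficiencies must lie in [0, 1]")
        if self.k_i_to_ii <= 0 or self.k_ii_to_i <= 0:
            raise ValueError("rate constants must be positive")

    @property
    def threshold(self) -> float:
        """Midpoint discrimination threshold between the two state means."""
        return 0.5 * (self.e_low + self.e_high)


@dataclass
class FretTrace:
    """Donor/acceptor intensity time series at a uniform frame rate.

    ``true_states``/``true_occupancy`` hold the latent simulated path when
    the trace comes from the generator; they are None for measured data.
    """

    times: np.ndarray
    donor: np.ndarray
    acceptor: np.ndarray
    fps: float
    true_states: np.ndarray | None = None
    true_occupancy: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        if not (self.times.shape == self.donor.shape == self.acceptor.shape):
            raise ValueError("times, donor and acceptor must have equal length")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if np.any(self.donor < 0) or np.any(self.acceptor < 0):
            raise ValueError("intensities must be non-negative")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class DwellSummary:
    """Dwell-time lists, rate estimates and occupancies from idealized traces."""

    dwells_i: list[float]            # seconds, state isoI (complete dwells)
    dwells_ii: list[float]           # seconds, state isoII
    n_transitions: int
    k_i_to_ii: float                 # 1/s
    k_ii_to_i: float                 # 1/s
    se_i_to_ii: float
    se_ii_to_i: float
    occupancy: tuple[float, float]   # (isoI, isoII) frame fractions

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "quantity": ["k_I_to_II", "k_II_to_I", "occ_isoI", "occ_isoII",
                         "n_transitions", "n_dwells_I", "n_dwells_II"],
            "value": [self.k_i_to_ii, self.k_ii_to_i, self.occupancy[0],
                      self.occupancy[1], self.n_transitions,
                      len(self.dwells_i), len(self.dwells_ii)],
            "se": [self.se_i_to_ii, self.se_ii_to_i, np.nan, np.nan,
                   np.nan, np.nan, np.nan],
        })


def fret_efficiency(donor: np.ndarray, acceptor: np.ndarray) -> np.ndarray:
    """Proximity-ratio FRET efficiency E = I_A / (I_A + I_D) per frame.

    Frames with zero total intensity are flagged as NaN (missing).
    """
    donor = np.asarray(donor, dtype=float)
    acceptor = np.asarray(acceptor, dtype=float)
    total = donor + acceptor
    with np.errstate(invalid="ignore", divide="ignore"):
        e = np.where(total > 0, acceptor / np.where(total > 0, total, 1.0), np.nan)
    return e


def idealize(efficiency: np.ndarray, threshold: float = 0.36,
             min_dwell_frames: int = 2) -> np.ndarray:
    """Threshold classification followed by suppression of short excursions.

    Frames with E above the threshold are assigned to the high-FRET state
    (isoII = 1).  Runs shorter than ``min_dwell_frames`` are merged into
    their neighbors, shortest first (ties: leftmost), which removes
    single-frame noise spikes deterministically.  NaN frames inherit the
    previous frame's class.
    """
    e = np.asarray(efficiency, dtype=float)
    if e.size < min_dwell_frames:
        raise ValueError("trace shorter than the minimum dwell")
    states = np.where(e > threshold, ISO_II, ISO_I)
    nan_mask = ~np.isfinite(e)
    if nan_mask.any():
        idx = np.where(nan_mask, 0, np.arange(e.size))
        np.maximum.accumulate(idx, out=idx)
        states = states[idx]

    runs = _run_lengths(states)
    while len(runs) > 1:
        lengths = [r[1] for r in runs]
        shortest = int(np.argmin(lengths))
        if lengths[shortest] >= min_dwell_frames:
            break
        state, length, start = runs[shortest]
        states[start:start + length] = 1 - state
        runs = _run_lengths(states)
    return states


def _run_lengths(states: np.ndarray) -> list[tuple[int, int, int]]:
    """Run-length encode a state sequence as (state, length, start) triples."""
    change = np.flatnonzero(np.diff(states)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [states.size]])
    return [(int(states[s]), int(e - s), int(s)) for s, e in zip(starts, ends)]


def estimate_rates(states: np.ndarray | Sequence[np.ndarray], fps: float,
                   min_dwell_frames: int = 2,
                   dead_time: float | None = None) -> DwellSummary:
    """Dwell-time rate estimation from one or several idealized traces.

    The first and last run of each trace are censored (their full duration
    is unobserved) and discarded.  Because the idealizer cannot detect
    dwells shorter than about ``min_dwell_frames - 0.5`` frames, observed
    dwell durations are left-truncated; for exponential dwells the unbiased
    mean is the observed mean minus that dead time, so
    ``k = 1 / (mean(dwell) - (min_dwell_frames - 0.5)/fps)`` with standard
    error ``k / sqrt(n_dwells)``.  Pass ``dead_time`` explicitly (e.g. 0.0)
    to override that default correction.  Occupancies are frame fractions
    over all idealized frames.
    """
    traces = [states] if isinstance(states, np.ndarray) else list(states)
    if not traces:
        raise ValueError("no traces given")
    if dead_time is None:
        dead_time = (min_dwell_frames - 0.5) / fps
    dwells: dict[int, list[float]] = {ISO_I: [], ISO_II: []}
    n_transitions = 0
    frame_counts = np.zeros(2)
    for seq in traces:
        seq = np.asarray(seq)
        runs = _run_lengths(seq)
        n_transitions += max(len(runs) - 1, 0)
        frame_counts[0] += np.sum(seq == ISO_I)
        frame_counts[1] += np.sum(seq == ISO_II)
        for state, length, _ in runs[1:-1]:     # drop censored first/last dwells
            dwells[state].append(length / fps)
    if not dwells[ISO_I] or not dwells[ISO_II]:
        raise ValueError("no complete dwells in at least one state")

    rates, ses = {}, {}
    for state in (ISO_I, ISO_II):
        arr = np.array(dwells[state])
        mean = max(arr.mean() - dead_time, 1.0 / (len(arr) * fps))
        rates[state] = 1.0 / mean
        ses[state] = rates[state] / np.sqrt(len(arr))
    occ = frame_counts / frame_counts.sum()
    return DwellSummary(
        dwells_i=dwells[ISO_I], dwells_ii=dwells[ISO_II],
        n_transitions=n_transitions,
        k_i_to_ii=rates[ISO_I], k_ii_to_i=rates[ISO_II],
        se_i_to_ii=ses[ISO_I], se_ii_to_i=ses[ISO_II],
        occupancy=(float(occ[0]), float(occ[1])),
    )


def equilibrium_populations(k_i_to_ii: float, k_ii_to_i: float) -> tuple[float, float]:
    """Stationary populations (p_isoI, p_isoII) of the two-state chain.

    Detailed balance gives p_II = k_I->II / (k_I->II + k_II->I); only the
    rate ratio matters.
    """
    if k_i_to_ii <= 0 or k_ii_to_i <= 0:
        raise ValueError("rate constants must be positive")
    p_ii = k_i_to_ii / (k_i_to_ii + k_ii_to_i)
    return 1.0 - p_ii, p_ii


def write_trace(trace: FretTrace, path: str | Path) -> None:
    """Write a trace as CSV with columns time_s, donor, acceptor."""
    df = pd.DataFrame({"time_s": trace.times, "donor": trace.donor,
                       "acceptor": trace.acceptor})
    df.to_csv(path, index=False, float_format="%.17g")


def read_trace(path: str | Path) -> FretTrace:
    """Read a (time_s, donor, acceptor) CSV; fps inferred from the time step."""
    df = pd.read_csv(path)
    times = df["time_s"].to_numpy(dtype=float)
    if times.size < 2:
        raise ValueError("trace needs at least two frames")
    dt = np.diff(times)
    if not np.allclose(dt, dt[0], rtol=1e-6):
        raise ValueError("trace sampling is not uniform")
    return FretTrace(times=times, donor=df["donor"].to_numpy(dtype=float),
                     acceptor=df["acceptor"].to_numpy(dtype=float),
                     fps=1.0 / float(dt[0]))
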