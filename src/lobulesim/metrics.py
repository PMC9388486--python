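"""Summary statistics of simulated trajectories.

These operate on the per-step time-course table produced by the engine
(one row per step) or on bare 1-D series, and implement the quantities
used to characterise fibrosis dynamics: blank (cell-free) area, onset and
peak steps of a time course, and the dominant period of an oscillating
series such as the dead-cell count under periodic dosing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .lattice import EMPTY, LobuleGrid


def blank_area(grid: LobuleGrid) -> int:
    """Number of sites with no space-occupying agent (structural sites,
    which always carry their vein/portal agent, never count)."""
    return int((grid.occupancy == EMPTY).sum())


def onset_step(series, fraction: float = 0.05) -> int | None:
    """First step at which ``series`` strictly exceeds ``fraction`` of its
    final value; None if the final value is zero (or negative)."""
    s = np.asarray(series, dtype=float)
    if len(s) == 0:
        return None
    final = s[-1]
    if final <= 0:
        return None
    above = np.nonzero(s > fraction * final)[0]
    return int(above[0]) if len(above) else None


def peak_step(series) -> int:
    """Argmax of the series; the earliest step on ties."""
    s = np.asarray(series, dtype=float)
    if len(s) == 0:
        raise ValueError("empty series")
    return int(np.argmax(s))


def dominant_period(series, noise_floor_fraction: float = 0.10) -> float | None:
    """Median gap between successive local maxima above a noise floor.

    The floor is ``noise_floor_fraction`` of the global maximum; series
    with fewer than two qualifying maxima have no defined period.
    """
    s = np.asarray(series, dtype=float)
    if len(s) == 0 or s.max() <= 0:
        return None
    floor = noise_floor_fraction * s.max()
    peaks, _ = find_peaks(s, height=floor)
    if len(peaks) < 2:
        return None
    return float(np.median(np.diff(peaks)))


def last_positive_step(series) -> int | None:
    """Last step at which the series is >= 1 (e.g. last step with any dead
    cell present); None if it never is."""
    s = np.asarray(series, dtype=float)
    idx = np.nonzero(s >= 1)[0]
    return int(idx[-1]) if len(idx) else None


def largest_increase_step(series, after: int = 0) -> int | None:
    """Step of the largest single-step (forward-difference) increase,
    considering differences landing strictly after step ``after``; the
    earliest step on ties.  None for series shorter than 2 points."""
    s = np.asarray(series, dtype=float)
    if len(s) < 2:
        return None
    diffs = np.diff(s)  # diffs[i] = s[i+1] - s[i], the increase at step i+1
    steps = np.arange(1, len(s))
    mask = steps > after
    if not mask.any():
        return None
    i = int(np.argmax(diffs[mask]))
    return int(steps[mask][i])


def ensemble_mean(values) -> float:
    """Mean over per-seed statistics, ignoring undefined (None) entries."""
    vals = [v for v in values if v is not None]
    if not vals:
        raise ValueError("no defined values in ensemble")
    return float(np.mean(vals))


def tidy_timecourses(tables: dict[int, pd.DataFrame]) -> pd.DataFrame:
    """Stack per-seed time-course tables into tidy long format:
    one row per (seed, step, variable)."""
    frames = []
    for seed, tc in tables.items():
        melted = tc.melt(id_vars="step", var_name="variable", value_name="value")
        melted.insert(0, "seed", seed)
        frames.append(melted)
    return pd.concat(frames, ignore_index=True)
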