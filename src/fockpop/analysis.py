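"""Oscillation statistics of density trajectories.

The headline quantity is the oscillation interval of the global human
density relative to the carrying capacity ``K``: the min and max of
``n^(a)(t)/K`` over the established oscillatory regime (an initial
transient, 5% of the horizon by default, is excluded).  Major peaks and
valleys — the ones almost reaching the interval limits — are counted
with a relative ``closeness`` filter on top of plain local-extremum
detection, and the smoothing of the global curve with growing cell count
is summarized by the standard deviation of ``n^(a)(t)/K``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .dynamics import Trajectory

__all__ = [
    "OscillationSummary",
    "oscillation_interval",
    "count_extremes",
    "smoothing_metric",
    "compare_reference",
]


@dataclass(frozen=True)
class OscillationSummary:
    """Oscillation interval and spread of a global density series."""

    min_ratio: float
    max_ratio: float
    std_ratio: float
    n_major_peaks: int = 0
    n_major_valleys: int = 0


def _window_series(
    traj: Trajectory, window: tuple[float, float] | None, transient_frac: float
) -> tuple[np.ndarray, np.ndarray]:
    t = traj.times
    g = traj.global_a
    if window is None:
        t0 = t[0] + transient_frac * (t[-1] - t[0])
        window = (t0, t[-1])
    lo, hi = window
    mask = (t >= lo) & (t <= hi)
    if mask.sum() < 2:
        raise ValueError(f"window {window} selects fewer than 2 samples")
    return t[mask], g[mask]


def _carrying_capacity(traj: Trajectory) -> float:
    K = traj.meta.get("K_total")
    if K is None:
        params = traj.meta.get("params")
        K = getattr(params, "K_total", None)
    if K is None:
        raise ValueError("carrying capacity not present in trajectory metadata")
    return float(K)


def oscillation_interval(
    traj: Trajectory,
    window: tuple[float, float] | None = None,
    transient_frac: float = 0.05,
    K: float | None = None,
) -> OscillationSummary:
    """Min/max/std of the global human density divided by ``K``.

    ``window`` restricts the analysis to a time range; by default the
    first ``transient_frac`` of the run is discarded so the statistics
    describe the established oscillatory regime.
    """
    _, g = _window_series(traj, window, transient_frac)
    K = _carrying_capacity(traj) if K is None else float(K)
    r = g / K
    peaks, valleys = count_extremes(traj, window=window, transient_frac=transient_frac)
    return OscillationSummary(
        min_ratio=float(r.min()),
        max_ratio=float(r.max()),
        std_ratio=float(r.std()),
        n_major_peaks=peaks,
        n_major_valleys=valleys,
    )


def count_extremes(
    traj: Trajectory,
    closeness: float = 0.10,
    min_separation: float = 0.02,
    window: tuple[float, float] | None = None,
    transient_frac: float = 0.05,
) -> tuple[int, int]:
    """Number of major peaks and valleys of the global human density.

    A local maximum (minimum) counts as major when its height is within
    ``closeness * (max - min)`` of the window maximum (minimum), i.e. it
    almost reaches the interval limit.  Extrema closer in time than
    ``min_separation`` times the window length are merged, keeping the
    most extreme one.  Invariant under adding constants to, or rescaling
    the amplitude of, the series.
    """
    if not 0 < closeness < 1:
        raise ValueError(f"closeness must be in (0, 1), got {closeness}")
    t, g = _window_series(traj, window, transient_frac)
    rng = g.max() - g.min()
    if rng == 0:
        return 0, 0
    span = t[-1] - t[0]
    dt_med = np.median(np.diff(t))
    distance = max(1, int(round(min_separation * span / dt_med)))
    # the prominence floor drops ripple extremes riding on a large swing
    peaks, _ = find_peaks(g, distance=distance, prominence=closeness * rng)
    valleys, _ = find_peaks(-g, distance=distance, prominence=closeness * rng)
    n_peaks = int(np.sum(g[peaks] >= g.max() - closeness * rng)) if peaks.size else 0
    n_valleys = int(np.sum(g[valleys] <= g.min() + closeness * rng)) if valleys.size else 0
    return n_peaks, n_valleys


def smoothing_metric(
    trajs,
    transient_frac: float = 0.05,
) -> pd.DataFrame:
    """Spread of the global density ratio versus lattice cell count.

    Accepts no-migration runs over different cell counts (same
    parameters) and tabulates ``std(n^(a)/K)`` sorted by cell count —
    the quantification of local oscillations averaging out on larger
    lattices.
    """
    rows = []
    for traj in trajs:
        scenario = traj.meta.get("scenario")
        if scenario is not None and scenario != "no_migration":
            raise ValueError(
                f"smoothing_metric expects no-migration runs, got {scenario!r}"
            )
        summ = oscillation_interval(traj, transient_frac=transient_frac)
        rows.append(
            {
                "n_cells": traj.n_cells,
                "seed": traj.meta.get("seed"),
                "std_ratio": summ.std_ratio,
                "min_ratio": summ.min_ratio,
                "max_ratio": summ.max_ratio,
            }
        )
    return pd.DataFrame(rows).sort_values("n_cells", ignore_index=True)


def compare_reference(
    traj: Trajectory,
    ref_times,
    ref_values,
    K_ref: float,
    closeness: float = 0.10,
    min_separation: float = 0.02,
    transient_frac: float = 0.05,
) -> dict:
    """Compare a model run against a reference demographic curve.

    The reference is a two-column time series with its own carrying
    capacity ``K_ref``; both curves are reduced to their oscillation
    interval (min/max relative to the respective ``K``) and major
    extreme counts, and the report carries the absolute differences.
    """
    ref_times = np.asarray(ref_times, dtype=float)
    ref_values = np.asarray(ref_values, dtype=float)
    if ref_times.ndim != 1 or ref_times.shape != ref_values.shape or ref_times.size < 2:
        raise ValueError("reference curve must be two equal-length 1-D arrays, >= 2 points")
    if not K_ref > 0:
        raise ValueError("K_ref must be positive")

    model = oscillation_interval(traj, transient_frac=transient_frac)

    # wrap the reference as a single-cell trajectory to reuse the analyzers
    ref_traj = Trajectory(
        times=ref_times,
        n_a=ref_values[:, None],
        n_b=np.zeros_like(ref_values)[:, None],
        norm=np.ones_like(ref_values),
        meta={"K_total": K_ref, "scenario": "reference"},
    )
    ref = oscillation_interval(ref_traj, transient_frac=0.0)
    ref_peaks, ref_valleys = count_extremes(
        ref_traj, closeness=closeness, min_separation=min_separation, transient_frac=0.0
    )
    model_peaks, model_valleys = count_extremes(
        traj, closeness=closeness, min_separation=min_separation,
        transient_frac=transient_frac,
    )
    return {
        "model_interval": (model.min_ratio, model.max_ratio),
        "reference_interval": (ref.min_ratio, ref.max_ratio),
        "interval_difference": (
            abs(model.min_ratio - ref.min_ratio),
            abs(model.max_ratio - ref.max_ratio),
        ),
        "model_extremes": (model_peaks, model_valleys),
        "reference_extremes": (ref_peaks, ref_valleys),
        "extreme_difference": (
            abs(model_peaks - ref_peaks),
            abs(model_valleys - ref_valleys),
        ),
    }
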