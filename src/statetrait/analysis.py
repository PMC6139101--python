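"""Reporting transforms: z-scores, gliding-window smoothing, transition summaries.

Published trajectories are displayed as z-transformed series (whole-run
mean 0, sample SD 1) and occasionally smoothed by an overlapping gliding
window (width 3, arithmetic mean).  Pre/post summaries quantify an order
transition as the change of per-variable level across two disjoint
iteration intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import STATE_VARS
from .engine import Trajectory

log = logging.getLogger(__name__)


@dataclass
class SeriesView:
    """A (possibly transformed) view of one time series."""

    values: np.ndarray
    transform: str = "raw"          # one of raw, z, smoothed
    source: str = ""                # originating variable / scenario id

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)


def z_transform(series, source: str = "") -> SeriesView:
    """Standardize a series to mean 0 and sample (n−1) SD 1 over its full length.

    A constant series has no scale; it maps to all zeros with a logged
    warning rather than dividing by zero.
    """
    x = np.asarray(getattr(series, "values", series), dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError(f"z-transform needs a 1-d series of length >= 2, got {x.shape}")
    sd = x.std(ddof=1)
    if x.max() == x.min() or sd == 0.0:  # constant series: no scale to divide by
        log.warning("z_transform: constant series %s mapped to all zeros", source or "?")
        return SeriesView(np.zeros_like(x), transform="z", source=source)
    return SeriesView((x - x.mean()) / sd, transform="z", source=source)


def moving_average(series, width: int = 3, source: str = "") -> SeriesView:
    """Centered gliding-window arithmetic mean (default width 3).

    Endpoints use the truncated available window, so the output has the
    same length as the input and a constant series passes through
    unchanged.
    """
    x = np.asarray(getattr(series, "values", series), dtype=float)
    if width % 2 == 0 or width < 1:
        raise ValueError(f"window width must be odd and positive, got {width}")
    if x.ndim != 1 or width > len(x):
        raise ValueError(
            f"window width {width} exceeds series length {len(x)}"
        )
    sm = pd.Series(x).rolling(window=width, center=True, min_periods=1).mean()
    return SeriesView(sm.to_numpy(), transform="smoothed", source=source)


def _check_interval(interval, T: int, what: str) -> tuple[int, int]:
    lo, hi = int(interval[0]), int(interval[1])
    if not 0 <= lo < hi <= T:
        raise ValueError(
            f"{what} interval ({lo}, {hi}) is not within the trajectory [0, {T}]"
        )
    return lo, hi


def transition_summary(
    trajectory: Trajectory,
    pre: tuple[int, int],
    post: tuple[int, int],
    view: str = "z",
) -> pd.DataFrame:
    """Per-variable pre/post means, SDs and post-minus-pre differences.

    Intervals are inclusive iteration ranges ``(lo, hi)`` and must be
    disjoint.  ``view`` selects z-transformed (default) or raw series;
    the z-transform is computed over the whole run, so pre/post
    differences keep their sign across views.
    """
    if view not in ("z", "raw"):
        raise ValueError(f"view must be 'z' or 'raw', got {view!r}")
    if hasattr(trajectory, "series"):
        T = trajectory.T
        get = trajectory.series
    else:  # a trajectory DataFrame as written by write_trajectory
        frame = trajectory
        T = len(frame) - 1
        get = lambda v: np.asarray(frame[v], dtype=float)  # noqa: E731
    p_lo, p_hi = _check_interval(pre, T, "pre")
    q_lo, q_hi = _check_interval(post, T, "post")
    if max(p_lo, q_lo) <= min(p_hi, q_hi):
        raise ValueError(
            f"pre ({p_lo}, {p_hi}) and post ({q_lo}, {q_hi}) intervals overlap"
        )
    rows = []
    for v in STATE_VARS:
        series = get(v)
        if view == "z":
            series = z_transform(series, source=v).values
        a = series[p_lo:p_hi + 1]
        b = series[q_lo:q_hi + 1]
        rows.append({
            "variable": v,
            "pre_mean": a.mean(), "pre_sd": a.std(ddof=1),
            "post_mean": b.mean(), "post_sd": b.std(ddof=1),
            "diff": b.mean() - a.mean(),
        })
    return pd.DataFrame(rows).set_index("variable")


def plot_trajectory(trajectory: Trajectory, path=None, z: bool = True):
    """State traces with trait overlays (optional; needs matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(2, 1, sharex=True, figsize=(9, 6))
    t = np.arange(trajectory.T + 1)
    for v in STATE_VARS:
        y = trajectory.series(v)
        if z:
            y = z_transform(y, source=v).values
        ax1.plot(t, y, label=v, lw=0.8)
    ax1.set_ylabel("states (z)" if z else "states")
    ax1.legend(ncol=5, fontsize=8)
    for p in ("a", "c", "r", "m"):
        ax2.plot(t, trajectory.series(p), label=p)
    ax2.set_ylabel("traits")
    ax2.set_xlabel("iteration (day)")
    ax2.set_ylim(0, 1)
    ax2.legend(ncol=4, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
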