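"""Motion and scanner-stability confounds: framewise displacement from
realignment parameters, and the weekly phantom intensity series, each with
a linear-trend check.

A linear trend found in a network outcome measure is only interpretable if
neither subject motion nor scanner drift shows one; these series are the
negative controls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import InvalidArgumentError, OutcomeSeries, SessionCalendar

BRAIN_RADIUS_MM = 50.0


@dataclass
class FDSeries:
    per_frame: np.ndarray  # mm, first frame 0 by convention
    mean_fd: float
    max_fd: float


def framewise_displacement(
    realignment: np.ndarray, radius_mm: float = BRAIN_RADIUS_MM
) -> FDSeries:
    """Per-frame head displacement from a frames x 6 realignment table.

    Columns: tx, ty, tz in mm; rx, ry, rz in radians. FD_t is the sum of the
    absolute differenced translations plus the absolute differenced rotations
    converted to mm as arc length on a sphere of ``radius_mm`` (default
    50 mm brain radius). FD of the first frame is 0 by convention.
    """
    rp = np.asarray(realignment, dtype=float)
    if rp.ndim != 2 or rp.shape[1] != 6:
        raise InvalidArgumentError("realignment table must be frames x 6")
    if rp.shape[0] < 2:
        raise InvalidArgumentError("need at least 2 frames")
    d = np.abs(np.diff(rp, axis=0))
    fd = d[:, :3].sum(axis=1) + radius_mm * d[:, 3:].sum(axis=1)
    fd = np.r_[0.0, fd]
    return FDSeries(per_frame=fd, mean_fd=float(fd.mean()), max_fd=float(fd.max()))


def read_realignment(path: str) -> np.ndarray:
    """Read a whitespace-delimited 6-column realignment table (rp_*.txt dialect)."""
    table = pd.read_csv(path, sep=r"\s+", header=None).to_numpy(dtype=float)
    if table.shape[1] != 6:
        raise InvalidArgumentError(f"expected 6 columns, got {table.shape[1]}")
    return table


def weekly_fd_series(
    motion_tables: list[np.ndarray],
    calendar: SessionCalendar,
    summary: str = "mean",
    radius_mm: float = BRAIN_RADIUS_MM,
) -> OutcomeSeries:
    """Per-session FD summary (mean over frames, or max) as a weekly series."""
    if len(motion_tables) != calendar.n_observed:
        raise InvalidArgumentError("one motion table per observed week required")
    if summary not in ("mean", "max"):
        raise InvalidArgumentError("summary must be 'mean' or 'max'")
    vals = []
    for rp in motion_tables:
        fd = framewise_displacement(rp, radius_mm=radius_mm)
        vals.append(fd.mean_fd if summary == "mean" else fd.max_fd)
    return OutcomeSeries(calendar=calendar, values=np.asarray(vals), measure_kind="fd")


def phantom_series(
    volumes: list[np.ndarray],
    calendar: SessionCalendar,
    mask: np.ndarray | None = None,
) -> OutcomeSeries:
    """Weekly mean in-mask intensity of phantom stability scans."""
    if not volumes:
        raise InvalidArgumentError("no phantom volumes")
    if len(volumes) != calendar.n_observed:
        raise InvalidArgumentError("one phantom volume per observed week required")
    vals = []
    for vol in volumes:
        v = np.asarray(vol, dtype=float)
        vals.append(float(v[mask].mean() if mask is not None else v.mean()))
    return OutcomeSeries(calendar=calendar, values=np.asarray(vals), measure_kind="phantom")


def confound_trend_check(series: OutcomeSeries):
    """Linear-trend test of a confound series (delegates to the trend fitter)."""
    from .timeseries import fit_linear_trend

    return fit_linear_trend(series)
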