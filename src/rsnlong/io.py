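"""On-disk formats: NIfTI volumes, TSV calendars/series/matrices, JSON sidecars."""

from __future__ import annotations

import json
from datetime import date
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import BNCMatrix, OutcomeSeries, SessionCalendar
from .synthetic import DEFAULT_START_DATE, week_dates

_FLOAT_FMT = "%.10g"  # fixed formatting keeps same-seed runs byte-identical


def save_nifti(volume: np.ndarray, path: str | Path, voxel_size_mm: float = 3.0) -> None:
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine), str(path))


def load_nifti(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())


def save_calendar_tsv(
    calendar: SessionCalendar, path: str | Path, start: date = DEFAULT_START_DATE
) -> None:
    dates = week_dates(calendar, start=start)
    df = pd.DataFrame(
        {
            "week_index": calendar.observed_weeks,
            "date_iso": [d.isoformat() for d in dates],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def load_calendar_tsv(path: str | Path, total_weeks: int | None = None) -> SessionCalendar:
    df = pd.read_csv(path, sep="\t")
    weeks = df["week_index"].to_numpy(dtype=int)
    if total_weeks is None:
        total_weeks = int(weeks.max()) + 1
    return SessionCalendar(total_weeks=total_weeks, observed_weeks=weeks)


def save_series_tsv(
    series: OutcomeSeries, path: str | Path, start: date = DEFAULT_START_DATE
) -> None:
    dates = week_dates(series.calendar, start=start)
    df = pd.DataFrame(
        {
            "week_index": series.weeks,
            "date_iso": [d.isoformat() for d in dates],
            "value": series.values,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def load_series_tsv(
    path: str | Path, total_weeks: int | None = None, **kwargs
) -> OutcomeSeries:
    df = pd.read_csv(path, sep="\t")
    cal = SessionCalendar(
        total_weeks=total_weeks or int(df["week_index"].max()) + 1,
        observed_weeks=df["week_index"].to_numpy(dtype=int),
    )
    return OutcomeSeries(calendar=cal, values=df["value"].to_numpy(dtype=float), **kwargs)


def save_bnc_tsv(bnc: BNCMatrix, path: str | Path) -> None:
    df = pd.DataFrame(bnc.matrix, index=list(bnc.networks), columns=list(bnc.networks))
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def save_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonify))


def _jsonify(x):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    raise TypeError(f"not JSON serializable: {type(x)}")
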