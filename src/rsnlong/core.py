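"""Shared domain types and errors for the longitudinal RSN pipeline.

The study design these types describe is a single subject scanned (nearly)
weekly over a multi-year span: a calendar of intended weekly sessions with
some weeks missed, per-session network spatial maps and time courses, and
weekly outcome-measure series aligned to that calendar.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


class InvalidArgumentError(ValueError):
    """An argument violates an operation's preconditions."""


class EstimationError(RuntimeError):
    """A statistical estimation step could not produce a valid result."""


class UndefinedStatisticError(ArithmeticError):
    """The requested statistic is undefined for this input (e.g. CV at mean 0)."""


@dataclass(frozen=True)
class SessionCalendar:
    """Weekly acquisition calendar: which of ``total_weeks`` weeks were scanned.

    Week indices count calendar weeks from the first session (t = 0), not
    session ordinals, so a missed scan leaves a gap in ``observed_weeks``.
    """

    total_weeks: int
    observed_weeks: np.ndarray  # sorted int array, values in [0, total_weeks-1]

    def __post_init__(self) -> None:
        obs = np.asarray(self.observed_weeks, dtype=int)
        object.__setattr__(self, "observed_weeks", obs)
        if self.total_weeks < 1:
            raise InvalidArgumentError("total_weeks must be >= 1")
        if obs.size < 1 or obs.size > self.total_weeks:
            raise InvalidArgumentError(
                f"need 1..{self.total_weeks} observed weeks, got {obs.size}"
            )
        if obs.min() < 0 or obs.max() > self.total_weeks - 1:
            raise InvalidArgumentError("observed week index out of range")
        if np.any(np.diff(obs) <= 0):
            raise InvalidArgumentError("observed_weeks must be strictly increasing")

    @property
    def n_observed(self) -> int:
        return int(self.observed_weeks.size)

    @property
    def missing_weeks(self) -> np.ndarray:
        mask = np.ones(self.total_weeks, dtype=bool)
        mask[self.observed_weeks] = False
        return np.nonzero(mask)[0]

    def observed_mask(self) -> np.ndarray:
        mask = np.zeros(self.total_weeks, dtype=bool)
        mask[self.observed_weeks] = True
        return mask


@dataclass
class OutcomeSeries:
    """One outcome measure's weekly values at the observed weeks of a calendar.

    ``measure_kind`` is one of ``eta_sq`` (spatial similarity to the mean map),
    ``rms_bold`` (temporal fluctuation magnitude, % signal change) or ``bnc``
    (between-network time-course correlation).
    """

    calendar: SessionCalendar
    values: np.ndarray
    measure_kind: str = "generic"
    network: str | None = None
    network2: str | None = None
    ground_truth: "object | None" = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (self.calendar.n_observed,):
            raise InvalidArgumentError(
                f"values shape {v.shape} does not match "
                f"{self.calendar.n_observed} observed weeks"
            )
        self.values = v

    @property
    def weeks(self) -> np.ndarray:
        return self.calendar.observed_weeks


@dataclass
class RSNMap:
    """A spatial network map (z-scored weights) on a voxel mask."""

    values: np.ndarray  # 1-D, one value per in-mask voxel
    mask: np.ndarray | None = None  # boolean volume; None for abstract maps
    network_label: str = ""
    session_id: str = "aggregate"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise InvalidArgumentError("map values must be finite")


@dataclass
class BNCMatrix:
    """Symmetric between-network connectivity (Pearson r) matrix."""

    networks: Sequence[str]
    matrix: np.ndarray
    undefined_pairs: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        k = len(self.networks)
        if m.shape != (k, k):
            raise InvalidArgumentError("matrix shape must match network labels")
        self.matrix = m

    def pair(self, i: int, j: int) -> float:
        return float(self.matrix[i, j])
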