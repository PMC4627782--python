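"""Network outcome measures: spatial similarity (eta-squared), overlap maps,
temporal fluctuation magnitude (RMS % signal change), and between-network
connectivity (BNC)."""

from __future__ import annotations

import numpy as np

from .core import BNCMatrix, InvalidArgumentError, RSNMap, UndefinedStatisticError


def eta_squared(a: np.ndarray, b: np.ndarray) -> float:
    """Spatial similarity of two maps in [0, 1].

    eta^2 = 1 - sum_i[(a_i - m_i)^2 + (b_i - m_i)^2] /
                sum_i[(a_i - Mbar)^2 + (b_i - Mbar)^2]

    where m_i = (a_i + b_i)/2 is the voxelwise mean image and Mbar its grand
    mean. 1 means identical images, 0 no similarity; unlike a correlation it
    is sensitive to differences in the actual values, not just their pattern.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape or a.size < 2:
        raise InvalidArgumentError("maps must have equal length >= 2")
    m = 0.5 * (a + b)
    grand = m.mean()
    denom = np.sum((a - grand) ** 2 + (b - grand) ** 2)
    if denom == 0:
        raise UndefinedStatisticError(
            "eta-squared undefined: both maps constant and equal to the grand mean"
        )
    num = np.sum((a - m) ** 2 + (b - m) ** 2)
    return float(1.0 - num / denom)


def mean_map(maps: list[RSNMap] | list[np.ndarray]) -> RSNMap:
    """Voxelwise average of session maps (the group/study mean map)."""
    if not maps:
        raise InvalidArgumentError("empty map list")
    arrays = [m.values if isinstance(m, RSNMap) else np.asarray(m, float) for m in maps]
    mask = maps[0].mask if isinstance(maps[0], RSNMap) else None
    label = maps[0].network_label if isinstance(maps[0], RSNMap) else ""
    return RSNMap(
        values=np.mean(arrays, axis=0), mask=mask, network_label=label, session_id="mean"
    )


def overlap_map(
    maps: list[RSNMap] | list[np.ndarray], z_threshold: float = 1.0
) -> np.ndarray:
    """Percentage of sessions in which each voxel's z-score exceeds the threshold.

    Session maps are thresholded (z > z_threshold, default 1), the binary
    maps summed, divided by the number of sessions and multiplied by 100.
    """
    if not maps:
        raise InvalidArgumentError("empty map list")
    arrays = [m.values if isinstance(m, RSNMap) else np.asarray(m, float) for m in maps]
    stacked = np.vstack(arrays)
    return 100.0 * np.mean(stacked > z_threshold, axis=0)


def rms_percent_bold(timecourse: np.ndarray) -> float:
    """Temporal fluctuation magnitude: quadratic mean (RMS) of a % signal
    change time course."""
    tc = np.asarray(timecourse, dtype=float).ravel()
    if tc.size == 0:
        raise InvalidArgumentError("empty time course")
    return float(np.sqrt(np.mean(tc**2)))


def bnc_matrix(timecourses: np.ndarray, networks: list[str] | None = None) -> BNCMatrix:
    """Between-network connectivity: Pearson r of network time courses.

    ``timecourses`` is components x time. Pairs involving a constant time
    course are undefined and returned as NaN with the pair flagged.
    """
    tc = np.asarray(timecourses, dtype=float)
    if tc.ndim != 2 or tc.shape[1] < 2:
        raise InvalidArgumentError("need a components x time matrix with >= 2 frames")
    k = tc.shape[0]
    if networks is None:
        networks = [f"IC{i + 1}" for i in range(k)]
    sd = tc.std(axis=1)
    constant = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        mat = np.corrcoef(tc)
    undefined = []
    for i in range(k):
        mat[i, i] = 1.0
        for j in range(i + 1, k):
            if constant[i] or constant[j]:
                mat[i, j] = mat[j, i] = np.nan
                undefined.append((i, j))
    return BNCMatrix(networks=networks, matrix=mat, undefined_pairs=undefined)
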