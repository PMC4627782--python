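"""Group spatial ICA: two-stage PCA, MDL order selection, extended Infomax,
a stability screen over randomized restarts, and GICA3 backreconstruction.

The decomposition follows the standard group-ICA chain for multi-session
fMRI: each session's voxel-by-time matrix is reduced along time to
``session_k`` principal components, the reduced sessions are concatenated in
the (reduced) temporal direction and reduced again to ``n_components``, and
spatial ICA is run on the group-reduced data. Session-specific maps and time
courses are recovered by GICA3 backreconstruction, whose defining property —
the mean of the session maps equals the aggregate map — is exact by
construction and verified in the test suite.

Orientation conventions: data matrices are voxels x time; spatial maps are
components x voxels; voxels are flattened x-fastest over the mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import EstimationError, InvalidArgumentError, RSNMap

VOXEL_ORDER = "x-fastest"


@dataclass
class DataMatrix:
    """In-mask voxel x time data for one session."""

    values: np.ndarray  # n_voxels x n_frames
    mask: np.ndarray  # boolean volume
    voxel_order: str = VOXEL_ORDER

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InvalidArgumentError("values must be 2-D (voxels x time)")
        if int(np.count_nonzero(self.mask)) != self.values.shape[0]:
            raise InvalidArgumentError("row count must equal in-mask voxel count")
        if not np.all(np.isfinite(self.values)):
            raise InvalidArgumentError("data must be finite")

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


def volume_to_data_matrix(volume: np.ndarray, mask: np.ndarray) -> DataMatrix:
    """Flatten a 4D (x, y, z, t) volume to in-mask voxels x time, x-fastest."""
    if volume.ndim != 4:
        raise InvalidArgumentError("expected a 4D volume")
    nt = volume.shape[3]
    flat = volume.reshape(-1, nt, order="F")
    mflat = np.asarray(mask, dtype=bool).reshape(-1, order="F")
    return DataMatrix(values=flat[mflat], mask=np.asarray(mask, dtype=bool))


def map_to_volume(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Inverse of the x-fastest flattening for a single spatial map."""
    mflat = np.asarray(mask, dtype=bool).reshape(-1, order="F")
    out = np.zeros(mflat.size)
    out[mflat] = values
    return out.reshape(mask.shape, order="F")


@dataclass
class PCAReduction:
    """Temporal PCA reduction of one session: data ~ reduced @ diag(sing) @ basis^T."""

    reduced: np.ndarray  # n_voxels x k, orthonormal columns (whitened spatial PCs)
    basis: np.ndarray  # n_frames x k temporal basis
    sing: np.ndarray  # singular values, non-increasing
    eigenvalues: np.ndarray  # variance per component, non-increasing
    k: int
    voxel_means: np.ndarray | None = None


@dataclass
class GroupReduction:
    """Second-stage reduction of temporally concatenated session reductions."""

    reduced: np.ndarray  # n_voxels x k (group principal components, unwhitened)
    eigenvalues: np.ndarray
    k: int
    session_blocks: list[np.ndarray] = field(default_factory=list)  # G_i, k1 x k


@dataclass
class ICADecomposition:
    aggregate_maps: np.ndarray  # n_components x n_voxels, unit-variance rows
    unmixing: np.ndarray  # W: maps = W @ reduced^T
    mixing: np.ndarray  # A = inv(W)
    n_components: int
    converged: bool = True
    n_iter: int = 0
    stability_index: np.ndarray | None = None
    scaling_note: str = "maps standardized to mean 0 / SD 1 over in-mask voxels"


@dataclass
class BackreconResult:
    session_maps: list[np.ndarray]  # per session: n_components x n_voxels
    session_timecourses: list[np.ndarray]  # per session: n_frames x n_components


# ---------------------------------------------------------------------------
# order selection

def estimate_order_mdl(data: DataMatrix, n_eff: int | None = None) -> int:
    """Minimum-description-length estimate of the number of signal components.

    Uses the Wax–Kailath MDL cost on the eigenvalue spectrum of the
    time-dimension covariance (frames x frames, voxels as samples), with
    effective sample size equal to the number of frames (no i.i.d.
    correction for spatial smoothness). Returns the argmin over candidate
    orders 1..frames-1.
    """
    if data.n_frames < 2:
        raise InvalidArgumentError("need at least 2 frames")
    x = data.values - data.values.mean(axis=1, keepdims=True)
    cov = (x.T @ x) / data.n_voxels
    lam = np.linalg.eigvalsh(cov)[::-1]
    if lam[0] <= 0 or not np.all(np.isfinite(lam)):
        raise EstimationError("degenerate data: covariance has no positive eigenvalue")
    lam = np.clip(lam, 1e-12 * lam[0], None)
    p = lam.size
    n = n_eff if n_eff is not None else data.n_frames
    costs = np.full(p, np.inf)
    for k in range(1, p):
        tail = lam[k:]
        am = tail.mean()
        gm = np.exp(np.mean(np.log(tail)))
        ll = n * (p - k) * np.log(am / gm)
        penalty = 0.5 * k * (2 * p - k + 1) * np.log(n)
        costs[k] = ll + penalty
    return int(np.argmin(costs[1:]) + 1)


# ---------------------------------------------------------------------------
# PCA reduction

def reduce_pca(data: DataMatrix, k: int) -> PCAReduction:
    """Reduce the time dimension to the top-k principal subspace (whitened)."""
    if not 1 <= k <= min(data.n_voxels, data.n_frames):
        raise InvalidArgumentError(
            f"k must be in [1, {min(data.n_voxels, data.n_frames)}], got {k}"
        )
    means = data.values.mean(axis=1, keepdims=True)
    x = data.values - means
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    eig = (s**2) / max(data.n_voxels - 1, 1)
    return PCAReduction(
        reduced=u[:, :k],
        basis=vt[:k].T,
        sing=s[:k],
        eigenvalues=eig[:k],
        k=k,
        voxel_means=means.ravel(),
    )


def explained_variance_fraction(data: DataMatrix, red: PCAReduction) -> float:
    x = data.values - data.values.mean(axis=1, keepdims=True)
    recon = (red.reduced * red.sing) @ red.basis.T
    total = float(np.sum(x**2))
    if total == 0:
        return 1.0
    return 1.0 - float(np.sum((x - recon) ** 2)) / total


def concat_reduce(group: list[PCAReduction], k: int) -> GroupReduction:
    """Concatenate whitened session reductions along (reduced) time, reduce to k.

    Retains the per-session blocks G_i of the second-stage basis, which the
    GICA3 backreconstruction needs.
    """
    if not group:
        raise InvalidArgumentError("empty group")
    k1 = group[0].k
    if any(r.k != k1 for r in group):
        raise InvalidArgumentError("all sessions must share the same session_k")
    if k > k1 * len(group):
        raise InvalidArgumentError("k exceeds concatenated dimension")
    stacked = np.hstack([r.reduced for r in group])  # V x (k1*S)
    u, s, vt = np.linalg.svd(stacked, full_matrices=False)
    g = vt[:k].T  # (k1*S) x k
    reduced = u[:, :k] * s[:k]
    blocks = [g[i * k1 : (i + 1) * k1] for i in range(len(group))]
    eig = (s[:k] ** 2) / max(stacked.shape[0] - 1, 1)
    return GroupReduction(reduced=reduced, eigenvalues=eig, k=k, session_blocks=blocks)


# ---------------------------------------------------------------------------
# extended Infomax ICA

def _extended_infomax(
    z: np.ndarray,
    seed: int,
    max_iter: int = 512,
    tol: float = 1e-6,
    lr: float | None = None,
) -> tuple[np.ndarray, bool, int]:
    """Natural-gradient extended Infomax on whitened k x N data.

    Returns (unmixing W s.t. sources = W @ z, converged flag, iterations).
    Sub/super-Gaussian switching via a running kurtosis sign estimate.
    """
    k, n = z.shape
    rng = np.random.default_rng(seed)
    w = np.linalg.qr(rng.normal(size=(k, k)))[0]
    if lr is None:
        lr = 0.01 / np.log(k + 2.0)
    block = int(min(n, max(32, np.floor(np.sqrt(n / 3.0)))))
    signs = np.ones(k)  # +1 super-Gaussian, -1 sub-Gaussian
    eye = np.eye(k)
    last_delta = np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w_old = w.copy()
        perm = rng.permutation(n)
        for start in range(0, n - block + 1, block):
            zb = z[:, perm[start : start + block]]
            u = w @ zb
            y = np.tanh(u)
            grad = eye - (signs[:, None] * y) @ u.T / block - u @ u.T / block
            w = w + lr * grad @ w
            if not np.all(np.isfinite(w)) or np.max(np.abs(w)) > 1e8:
                # blow-up: restart colder
                lr *= 0.5
                w = np.linalg.qr(rng.normal(size=(k, k)))[0]
        # update source sign estimates from kurtosis of current sources
        s_all = w @ z
        m2 = np.mean(s_all**2, axis=1)
        m4 = np.mean(s_all**4, axis=1)
        kurt = m4 / np.maximum(m2**2, 1e-300) - 3.0
        signs = np.where(kurt >= 0, 1.0, -1.0)
        delta = np.linalg.norm(w - w_old) / max(np.linalg.norm(w_old), 1e-300)
        if delta < tol:
            converged = True
            break
        if delta > last_delta * 1.5:
            lr *= 0.9  # anneal when the trajectory oscillates
        last_delta = delta
    return w, converged, it


def infomax_ica(
    reduced: GroupReduction | PCAReduction,
    n_components: int,
    seed: int = 0,
    max_iter: int = 512,
    tol: float = 1e-6,
) -> ICADecomposition:
    """Spatial ICA of the group-reduced data by extended Infomax.

    Components (rows of ``aggregate_maps``) are scaled to unit variance over
    voxels, sign-flipped to positive skewness, and ordered by explained
    variance; these conventions resolve the ICA scale/sign/order
    indeterminacies deterministically.
    """
    x = reduced.reduced  # V x k
    if n_components != reduced.k:
        raise InvalidArgumentError("n_components must equal the reduction order k")
    xt = x.T  # k x V
    centered = xt - xt.mean(axis=1, keepdims=True)
    sd = centered.std(axis=1)
    if np.any(sd <= 0):
        raise EstimationError("degenerate reduction: zero-variance component")
    # whiten (principal components are uncorrelated; rescale to unit variance)
    sphere = np.diag(1.0 / sd)
    z = sphere @ centered
    w_ica, converged, n_iter = _extended_infomax(z, seed=seed, max_iter=max_iter, tol=tol)
    w = w_ica @ sphere
    # maps from the UNcentered reduction so the GICA3 aggregate identity
    # (mean of session maps = aggregate maps) holds exactly
    maps = w @ xt
    # unit-variance rows, positive skewness, variance-ordered
    scale = maps.std(axis=1)
    scale[scale == 0] = 1.0
    w = w / scale[:, None]
    maps = maps / scale[:, None]
    skew = np.mean((maps - maps.mean(axis=1, keepdims=True)) ** 3, axis=1)
    flip = np.where(skew < 0, -1.0, 1.0)
    w = w * flip[:, None]
    maps = maps * flip[:, None]
    a = np.linalg.inv(w)
    order = np.argsort(-np.sum(a**2, axis=0))
    w, maps, a = w[order], maps[order], a[:, order]
    return ICADecomposition(
        aggregate_maps=maps,
        unmixing=w,
        mixing=a,
        n_components=n_components,
        converged=converged,
        n_iter=n_iter,
    )


def _abs_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """|Pearson r| between rows of a and rows of b."""
    az = (a - a.mean(axis=1, keepdims=True)) / a.std(axis=1, keepdims=True)
    bz = (b - b.mean(axis=1, keepdims=True)) / b.std(axis=1, keepdims=True)
    return np.abs(az @ bz.T / a.shape[1])


def stability_screen(
    reduced: GroupReduction | PCAReduction,
    n_components: int,
    n_runs: int = 5,
    seed: int = 0,
    threshold: float = 0.8,
    seeds: list[int] | None = None,
) -> np.ndarray:
    """Per-component stability over randomized Infomax restarts.

    Components from every run are clustered against the first run's by
    greedy absolute-correlation assignment; the stability index of a cluster
    is (within-cluster mean |r|) - (between-cluster max |r|), clipped to
    [0, 1]. Components with index below ``threshold`` should be treated as
    unreliable (the analogue of rejecting low-reliability components after
    repeated-run clustering).
    """
    from scipy.optimize import linear_sum_assignment

    if n_runs < 2:
        raise InvalidArgumentError("n_runs must be >= 2")
    if seeds is None:
        seeds = [seed + i for i in range(n_runs)]
    runs = [
        infomax_ica(reduced, n_components, seed=s).aggregate_maps for s in seeds
    ]
    ref = runs[0]
    k = n_components
    # cluster id of component j of run r (matched to reference components)
    members: list[list[np.ndarray]] = [[ref[i]] for i in range(k)]
    for maps in runs[1:]:
        c = _abs_corr(ref, maps)
        ri, ci = linear_sum_assignment(-c)
        for i, j in zip(ri, ci):
            members[i].append(maps[j])
    index = np.zeros(k)
    stacked = [np.vstack(m) for m in members]
    for i in range(k):
        within = _abs_corr(stacked[i], stacked[i])
        iu = np.triu_indices(within.shape[0], 1)
        within_mean = float(within[iu].mean()) if iu[0].size else 1.0
        between_max = 0.0
        for j in range(k):
            if j != i:
                between_max = max(between_max, float(_abs_corr(stacked[i], stacked[j]).max()))
        index[i] = np.clip(within_mean - between_max, 0.0, 1.0)
    return index


# ---------------------------------------------------------------------------
# GICA3 backreconstruction

def backreconstruct_gica3(
    ica: ICADecomposition,
    group: GroupReduction,
    session_reductions: list[PCAReduction],
) -> BackreconResult:
    """Session-specific maps and time courses via the GICA3 procedure.

    With X = sum_i R_i G_i the group-reduced data, aggregate maps
    S = W X^T and mixing A = W^-1, the session map is
    ``S_i = n_sessions * W (R_i G_i)^T`` and the session time course is
    ``TC_i = B_i G_i A`` where B_i is session i's scaled temporal basis.
    The session maps average exactly to the aggregate maps.
    """
    if len(session_reductions) != len(group.session_blocks):
        raise InvalidArgumentError("session count mismatch with group reduction")
    n_s = len(session_reductions)
    maps, tcs = [], []
    for red, g in zip(session_reductions, group.session_blocks):
        if red.k != g.shape[0]:
            raise InvalidArgumentError("session reduction order mismatch")
        part = red.reduced @ g  # V x k2, session's contribution to X
        maps.append(n_s * (ica.unmixing @ part.T))
        tcs.append((red.basis * red.sing) @ g @ ica.mixing)  # T x k2
    return BackreconResult(session_maps=maps, session_timecourses=tcs)


# ---------------------------------------------------------------------------
# scaling

def zscore_map(values: np.ndarray, mask: np.ndarray | None = None, **kwargs) -> RSNMap:
    """Standardize a spatial map to mean 0 / SD 1 over in-mask voxels.

    This is the display-scale convention for backreconstructed weight maps;
    a correlation-style variance-stabilizing transform is not applicable to
    unbounded regression weights.
    """
    v = np.asarray(values, dtype=float).ravel()
    sd = v.std()
    if sd == 0:
        raise InvalidArgumentError("zero-variance map cannot be z-scored")
    return RSNMap(values=(v - v.mean()) / sd, mask=mask, **kwargs)


def scale_percent_signal(timecourse: np.ndarray, session_voxel_means: np.ndarray) -> np.ndarray:
    """Express a backreconstructed time course in % of the session mean signal."""
    baseline = float(np.mean(session_voxel_means))
    if baseline <= 0:
        raise InvalidArgumentError("session mean signal must be positive")
    return 100.0 * np.asarray(timecourse, dtype=float) / baseline


# ---------------------------------------------------------------------------
# convenience chain

@dataclass
class GICAResult:
    ica: ICADecomposition
    group: GroupReduction
    session_reductions: list[PCAReduction]
    backrecon: BackreconResult
    stability: np.ndarray | None
    session_k: int
    n_components: int


def run_gica(
    sessions: list[DataMatrix],
    n_components: int | str = "mdl",
    session_k: int | str = "auto",
    n_runs: int = 0,
    seed: int = 0,
) -> GICAResult:
    """Full chain: order selection -> two-stage PCA -> ICA -> GICA3.

    ``n_components='mdl'`` takes the median MDL order over sessions;
    ``session_k='auto'`` doubles the component number (robust
    backreconstruction heuristic). ``n_runs >= 2`` adds the stability screen.
    """
    if not sessions:
        raise InvalidArgumentError("no sessions")
    if n_components == "mdl":
        orders = [estimate_order_mdl(s) for s in sessions]
        n_components = int(np.median(orders))
    n_components = int(n_components)
    if session_k == "auto":
        session_k = 2 * n_components
    session_k = int(min(session_k, min(s.n_frames for s in sessions)))
    n_components = min(n_components, session_k)
    reds = [reduce_pca(s, session_k) for s in sessions]
    group = concat_reduce(reds, n_components)
    ica = infomax_ica(group, n_components, seed=seed)
    stability = None
    if n_runs >= 2:
        stability = stability_screen(group, n_components, n_runs=n_runs, seed=seed)
        ica.stability_index = stability
    back = backreconstruct_gica3(ica, group, reds)
    return GICAResult(
        ica=ica,
        group=group,
        session_reductions=reds,
        backrecon=back,
        stability=stability,
        session_k=session_k,
        n_components=n_components,
    )
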