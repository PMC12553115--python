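"""Per-object activation pattern estimation with motion scrubbing and QC.

The estimation path mirrors common single-subject practice: framewise
displacement (FD) and DVARS per volume, spike regressors for significantly
affected volumes, an ordinary-least-squares GLM with one HRF-convolved
regressor per object plus a fly regressor, the six rigid-body motion
parameters and a constant + linear drift, and univariate noise normalization
of the beta maps into t-value patterns. Participant-level QC excludes
participants with fewer than two usable presentations of any object in a
day, or more than three missed flies in any single run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import qr

from .schedule import PvtSchedule
from .timeseries import make_regressor

HEAD_RADIUS_MM = 50.0  # rotation-to-displacement conversion (standard convention)

__all__ = [
    "MotionTrace",
    "GlmResult",
    "QcDecision",
    "compute_fd_dvars",
    "detect_outlier_volumes",
    "fit_object_glm",
    "compute_tstat_patterns",
    "trials_hit_by_outliers",
    "usable_presentations",
    "qc_participant",
]


@dataclass(frozen=True)
class MotionTrace:
    """Rigid-body parameters with derived FD (mm) and DVARS per volume."""

    params: np.ndarray  # (n_volumes, 6)
    fd: np.ndarray  # (n_volumes,) first entry 0
    dvars: np.ndarray  # (n_volumes,) first entry 0


@dataclass(frozen=True)
class GlmResult:
    betas: np.ndarray  # (n_objects, n_voxels)
    residual_sd: np.ndarray  # (n_voxels,)
    dof: int
    outlier_volumes: tuple[int, ...]
    object_ids: tuple[int, ...]
    design: np.ndarray = field(repr=False)  # (n_volumes, n_regressors)
    column_names: tuple[str, ...] = ()


@dataclass(frozen=True)
class QcDecision:
    include: bool
    reasons: tuple[str, ...]


def compute_fd_dvars(data: np.ndarray, motion: np.ndarray,
                     mask: np.ndarray | None = None) -> MotionTrace:
    """Framewise displacement and DVARS for every volume.

    FD_t = sum |d translations| + 50 mm * sum |d rotations|; DVARS_t is the
    root-mean-square over in-mask voxels of the volume-to-volume signal
    difference. Both are defined as 0 at the first volume. ``data`` has time
    as its last axis (any spatial shape).
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion must be (n_volumes, 6)")
    n_vol = motion.shape[0]
    if n_vol < 2:
        raise ValueError("need at least two volumes to compute FD/DVARS")
    flat = np.asarray(data, dtype=float).reshape(-1, data.shape[-1])
    if flat.shape[1] != n_vol:
        raise ValueError("data and motion disagree on the number of volumes")
    if mask is not None:
        flat = flat[np.asarray(mask, bool).ravel()]

    d = np.diff(motion, axis=0)
    fd = np.zeros(n_vol)
    fd[1:] = np.abs(d[:, :3]).sum(axis=1) + HEAD_RADIUS_MM * np.abs(d[:, 3:]).sum(axis=1)
    dvars = np.zeros(n_vol)
    dvars[1:] = np.sqrt(np.mean(np.diff(flat, axis=1) ** 2, axis=0))
    return MotionTrace(params=motion, fd=fd, dvars=dvars)


def detect_outlier_volumes(trace: MotionTrace, fd_threshold: float = 0.5,
                           dvars_z: float = 3.0) -> tuple[int, ...]:
    """Volumes with FD above threshold or robust-z of DVARS above ``dvars_z``."""
    if fd_threshold <= 0 or dvars_z <= 0:
        raise ValueError("thresholds must be positive")
    flags = trace.fd > fd_threshold
    d = trace.dvars[1:]
    med = np.median(d)
    mad = 1.4826 * np.median(np.abs(d - med))
    if mad > 0:
        z = (trace.dvars - med) / mad
        z[0] = 0.0
        flags |= z > dvars_z
    return tuple(int(i) for i in np.flatnonzero(flags))


def _build_design(events: pd.DataFrame, motion: np.ndarray, outliers: tuple[int, ...],
                  n_volumes: int, tr: float) -> tuple[np.ndarray, list[str], list[int]]:
    object_ids = []
    cols, names = [], []
    for oid in sorted(int(o) for o in events["object_id"].unique()):
        grp = events[(events["object_id"] == oid) & (~events["fly"])]
        if grp.empty:
            continue  # all presentations fly-flagged: object not estimable
        object_ids.append(oid)
        cols.append(make_regressor(grp["onset"].to_numpy(), grp["duration"].to_numpy(),
                                   n_volumes, tr))
        names.append(f"object_{oid}")
    fly = events[events["fly"]]
    if len(fly):
        cols.append(make_regressor(fly["onset"].to_numpy(), fly["duration"].to_numpy(),
                                   n_volumes, tr))
        names.append("fly")
    for j in range(6):
        cols.append(motion[:, j])
        names.append(f"motion_{j}")
    for k in sorted(set(outliers)):
        spike = np.zeros(n_volumes)
        spike[k] = 1.0
        cols.append(spike)
        names.append(f"spike_{k}")
    cols.append(np.ones(n_volumes))
    names.append("intercept")
    t = np.arange(n_volumes, dtype=float)
    cols.append((t - t.mean()) / n_volumes)
    names.append("drift")
    return np.column_stack(cols), names, object_ids


def fit_object_glm(data: np.ndarray, events: pd.DataFrame, motion: np.ndarray,
                   outliers: tuple[int, ...] = (), tr: float = 1.0) -> GlmResult:
    """Voxelwise OLS of the object GLM.

    Raises a rank-deficiency error naming the collinear columns (identified
    with a pivoted QR) if the design matrix is singular.
    """
    flat = np.asarray(data, dtype=float).reshape(-1, data.shape[-1]).T  # (T, V)
    n_volumes = flat.shape[0]
    X, names, object_ids = _build_design(events, motion, outliers, n_volumes, tr)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, r, piv = qr(X, mode="economic", pivoting=True)
        bad = [names[piv[i]] for i in range(rank, X.shape[1])]
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient; collinear columns: {bad}")
    beta, _, _, _ = np.linalg.lstsq(X, flat, rcond=None)
    resid = flat - X @ beta
    dof = n_volumes - X.shape[1]
    if dof <= 0:
        raise ValueError("no residual degrees of freedom")
    residual_sd = np.sqrt((resid**2).sum(axis=0) / dof)
    obj_rows = [names.index(f"object_{oid}") for oid in object_ids]
    return GlmResult(
        betas=beta[obj_rows],
        residual_sd=residual_sd,
        dof=dof,
        outlier_volumes=tuple(sorted(set(outliers))),
        object_ids=tuple(object_ids),
        design=X,
        column_names=tuple(names),
    )


def compute_tstat_patterns(glm: GlmResult) -> tuple[np.ndarray, np.ndarray]:
    """Noise-normalize betas into t-value patterns.

    t(object, voxel) = beta / (residual_sd * sqrt([(X'X)^-1]_jj)). Voxels with
    zero residual variance are excluded from the returned validity mask
    rather than producing infinities. Returns ``(patterns, valid_mask)``.
    """
    valid = glm.residual_sd > 0
    if not valid.any():
        raise ValueError("no voxels with positive residual variance")
    xtx_inv = np.linalg.inv(glm.design.T @ glm.design)
    obj_rows = [glm.column_names.index(f"object_{oid}") for oid in glm.object_ids]
    scale = np.sqrt(np.diag(xtx_inv)[obj_rows])  # per-object design scale
    patterns = np.full_like(glm.betas, np.nan)
    patterns[:, valid] = glm.betas[:, valid] / (glm.residual_sd[valid][None, :]
                                                * scale[:, None])
    return patterns, valid


def trials_hit_by_outliers(events: pd.DataFrame, outliers: tuple[int, ...],
                           tr: float) -> pd.Index:
    """Indices of events whose presentation window covers an outlier volume."""
    if not outliers:
        return pd.Index([], dtype=int)
    times = np.asarray(sorted(set(outliers)), dtype=float) * tr
    hit = [
        idx
        for idx, row in events.iterrows()
        if np.any((times >= row["onset"]) & (times < row["onset"] + row["duration"]))
    ]
    return pd.Index(hit, dtype=int)


def usable_presentations(schedule: PvtSchedule,
                         scrubbed: set[tuple[int, int, int]] = frozenset()) -> dict[int, int]:
    """Per-object usable presentation count for one day.

    A presentation is usable when it is neither a fly trial nor scrubbed
    (``scrubbed`` holds (session, block, object) triples).
    """
    counts: dict[int, int] = {}
    for s, session in enumerate(schedule.blocks):
        for b, block in enumerate(session):
            for oid in block:
                ok = (s, b, oid) not in schedule.fly_trials and (s, b, oid) not in scrubbed
                counts[oid] = counts.get(oid, 0) + int(ok)
    return counts


def qc_participant(usable_per_day: dict[str, dict[int, int]],
                   fly_performance: pd.DataFrame,
                   max_fly_misses: int = 3,
                   min_presentations: int = 2) -> QcDecision:
    """Participant inclusion decision, listing every triggered rule.

    ``usable_per_day`` maps day label -> object id -> usable presentation
    count; ``fly_performance`` has one row per run with columns ``day``,
    ``session`` and ``misses`` (four runs over the two days).
    """
    reasons: list[str] = []
    for day, counts in usable_per_day.items():
        low = sorted(oid for oid, n in counts.items() if n < min_presentations)
        if low:
            reasons.append(f"objects with <{min_presentations} presentations on day "
                           f"{day}: {low}")
    for _, row in fly_performance.iterrows():
        if row["misses"] > max_fly_misses:
            reasons.append(f"fly-misses run {row['day']}-{int(row['session'])}: "
                           f"{int(row['misses'])}")
    return QcDecision(include=not reasons, reasons=tuple(reasons))
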