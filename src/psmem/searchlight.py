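"""Whole-volume searchlight RSA with TFCE permutation inference.

A sphere (default radius 6 voxels, Euclidean in voxel units,
boundary-inclusive) is centered at every in-mask voxel; spheres with fewer
than ``min_size`` in-mask members (default 20) are skipped. Each sphere is
treated as a small ROI: the requested pattern-similarity construct is
computed from its member voxels and condensed into one number per
participant and center — a t statistic across items for dichotomous
predictors, a Pearson correlation across items for continuous predictors.

Group inference uses sign-flip permutations with threshold-free cluster
enhancement (TFCE): the observed one-sample t map across participants is
TFCE-enhanced, each participant's map is randomly negated per permutation,
and the maximum enhanced statistic over voxels builds the null distribution
for family-wise-error-corrected p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy import stats as sps

from ._rng import child_rng
from .design import StudyDesign
from .rsa import reorganization, within_day_matrix

__all__ = [
    "SphereIndex",
    "TfceParams",
    "PermutationResult",
    "build_spheres",
    "sphere_stat_map",
    "tfce_enhance",
    "sign_flip_test",
    "paired_contrast_test",
]

CONNECTIVITY_6 = ndimage.generate_binary_structure(3, 1)


@dataclass(frozen=True)
class SphereIndex:
    center: tuple[int, int, int]
    members: np.ndarray  # (m, 3) voxel coordinates, includes the center


@dataclass(frozen=True)
class TfceParams:
    """TFCE parameters: height exponent H, extent exponent E, step dh.

    Defaults H=2, E=0.5, 6-connectivity are the standard recommendation;
    ``dh=None`` uses max/``n_steps``.
    """

    height_exponent: float = 2.0
    extent_exponent: float = 0.5
    dh: float | None = None
    n_steps: int = 100

    def __post_init__(self) -> None:
        if self.height_exponent < 0 or self.extent_exponent < 0:
            raise ValueError("TFCE exponents must be non-negative")
        if self.dh is not None and self.dh <= 0:
            raise ValueError("dh must be positive")


@dataclass(frozen=True)
class PermutationResult:
    p_corrected: np.ndarray  # voxelwise FWE-corrected p
    tfce_observed: np.ndarray
    null_max: np.ndarray  # (n_perm,) max-statistic null distribution
    n_perm: int
    seed: int


def sphere_offsets(radius: float) -> np.ndarray:
    """Integer offsets within Euclidean distance ``radius`` of the origin."""
    r = int(np.floor(radius))
    g = np.mgrid[-r:r + 1, -r:r + 1, -r:r + 1].reshape(3, -1).T
    return g[(g**2).sum(axis=1) <= radius**2]


def build_spheres(mask: np.ndarray, radius: float = 6.0,
                  min_size: int = 20) -> list[SphereIndex]:
    """One sphere per in-mask voxel with at least ``min_size`` in-mask members."""
    mask = np.asarray(mask, bool)
    if radius <= 0:
        raise ValueError("radius must be positive")
    if not mask.any():
        raise ValueError("mask is empty")
    offsets = sphere_offsets(radius)
    centers = np.argwhere(mask)
    spheres: list[SphereIndex] = []
    shape = np.asarray(mask.shape)
    for c in centers:
        pts = c + offsets
        ok = np.all((pts >= 0) & (pts < shape), axis=1)
        pts = pts[ok]
        pts = pts[mask[pts[:, 0], pts[:, 1], pts[:, 2]]]
        if len(pts) >= min_size:
            spheres.append(SphereIndex(center=tuple(int(v) for v in c), members=pts))
    if not spheres:
        raise ValueError("no sphere satisfies the minimum-size constraint")
    return spheres


def _category_pair_stat(pre_mat_values: np.ndarray, same_cat: np.ndarray) -> float:
    """t across pairs: same-category vs different-category pre-encoding z."""
    iu = np.triu_indices(pre_mat_values.shape[0], k=1)
    z = pre_mat_values[iu]
    same = same_cat[iu]
    a, b = z[same], z[~same]
    if len(a) < 2 or len(b) < 2:
        return np.nan
    t, _ = sps.ttest_ind(a, b)
    return float(t)


def _dichotomous_item_stat(values: np.ndarray, level: np.ndarray
                           ) -> tuple[float, float, float]:
    a, b = values[level], values[~level]
    if len(a) < 2 or len(b) < 2:
        return np.nan, np.nan, np.nan
    t, _ = sps.ttest_ind(a, b)
    return float(t), float(np.mean(a)), float(np.mean(b))


def sphere_stat_map(volumes: dict[str, np.ndarray], design: StudyDesign,
                    predictor: str, spheres: list[SphereIndex],
                    shape: tuple[int, int, int],
                    item_values: np.ndarray | None = None
                    ) -> dict[str, np.ndarray]:
    """Per-participant searchlight statistic map(s).

    ``volumes`` maps the four session names to (n_objects, *shape) arrays.
    Predictors:

    * ``"category"`` — same- vs different-category pre-encoding pair
      similarity, t across pairs;
    * ``"congruence"`` / ``"relevance"`` — object-level reorganization
      compared between condition levels, t across objects;
    * ``"room_correct"`` — reorganization by correct vs incorrect room
      recall; requires ``item_values`` as a boolean per-object vector;
    * ``"continuous"`` — Pearson correlation of reorganization with
      ``item_values`` across objects.

    Returns ``{"stat": map}`` plus ``"level_a"``/``"level_b"`` mean maps for
    dichotomous predictors. Spheres with undefined statistics stay NaN.
    """
    stat = np.full(shape, np.nan)
    level_a = np.full(shape, np.nan)
    level_b = np.full(shape, np.nan)
    dichotomous = predictor in ("congruence", "relevance", "room_correct")

    if predictor == "congruence":
        level = np.array([o.congruent for o in design.objects])
    elif predictor == "relevance":
        level = np.array([o.task_relevant for o in design.objects])
    elif predictor in ("room_correct", "continuous"):
        if item_values is None:
            raise ValueError(f"predictor {predictor!r} requires item_values")
        level = np.asarray(item_values)
    elif predictor == "category":
        cats = [o.category for o in design.objects]
        same_cat = np.equal.outer(cats, cats)
        level = None
    else:
        raise ValueError(f"unknown predictor {predictor!r}")

    def extract(session: str, pts: np.ndarray) -> np.ndarray:
        vol = volumes[session]
        return vol[:, pts[:, 0], pts[:, 1], pts[:, 2]]

    for sph in spheres:
        pts = sph.members
        if predictor == "category":
            mat = within_day_matrix(extract("pre1", pts), extract("pre2", pts),
                                    day="pre")
            val = _category_pair_stat(mat.values, same_cat)
            stat[sph.center] = val
            continue
        reorg = reorganization(
            (extract("pre1", pts), extract("pre2", pts)),
            (extract("post1", pts), extract("post2", pts)),
        )["reorg_z"].to_numpy()
        ok = np.isfinite(reorg)
        if ok.sum() < 4:
            continue
        if dichotomous:
            t, ma, mb = _dichotomous_item_stat(reorg[ok], np.asarray(level, bool)[ok])
            stat[sph.center] = t
            level_a[sph.center] = ma
            level_b[sph.center] = mb
        else:
            vals = np.asarray(level, float)[ok]
            if np.std(vals) == 0 or np.std(reorg[ok]) == 0:
                continue
            stat[sph.center] = float(np.corrcoef(reorg[ok], vals)[0, 1])

    out = {"stat": stat}
    if dichotomous:
        out["level_a"] = level_a
        out["level_b"] = level_b
    return out


def _tfce_one_sign(a: np.ndarray, params: TfceParams) -> np.ndarray:
    hmax = float(a.max(initial=0.0))
    if hmax <= 0:
        return np.zeros_like(a)
    dh = params.dh if params.dh is not None else hmax / params.n_steps
    out = np.zeros_like(a)
    n_steps = int(np.floor(hmax / dh + 1e-9))
    for k in range(1, n_steps + 1):
        h = np.float64(k * dh)
        labels, n = ndimage.label(a >= h, structure=CONNECTIVITY_6)
        if n == 0:
            break
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        out += (sizes[labels] ** params.extent_exponent) \
            * (h ** params.height_exponent) * dh
    return out


def tfce_enhance(stat_map: np.ndarray, params: TfceParams = TfceParams()) -> np.ndarray:
    """Threshold-free cluster enhancement.

    TFCE(v) = sum over thresholds h of extent(h, v)^E * h^H * dh, where
    extent is the size of the suprathreshold 6-connected component containing
    v. Negative values are enhanced on the negated map and re-negated;
    non-finite values are treated as 0.
    """
    a = np.nan_to_num(np.asarray(stat_map, dtype=float))
    pos = _tfce_one_sign(np.where(a > 0, a, 0.0), params)
    neg = _tfce_one_sign(np.where(a < 0, -a, 0.0), params)
    return pos - neg


T_CAP = 1e6  # zero-variance voxels get a large finite t instead of infinity


def _one_sample_t(maps: np.ndarray) -> np.ndarray:
    n = maps.shape[0]
    mean = maps.mean(axis=0)
    sd = maps.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / (sd / np.sqrt(n))
    return np.clip(np.nan_to_num(t), -T_CAP, T_CAP)


def sign_flip_test(participant_maps: np.ndarray, n_perm: int = 5000,
                   params: TfceParams = TfceParams(), seed: int = 0,
                   ) -> PermutationResult:
    """One-sample sign-flip permutation test with TFCE and max-statistic FWE.

    ``participant_maps`` is (n_participants, *grid); NaN entries count as 0.
    Corrected p(v) = (1 + #{perm max >= TFCE_obs(v)}) / (n_perm + 1).
    """
    maps = np.nan_to_num(np.asarray(participant_maps, dtype=float))
    if maps.ndim < 2 or maps.shape[0] < 2:
        raise ValueError("need at least two participant maps")
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    observed = tfce_enhance(_one_sample_t(maps), params)
    rng = child_rng(seed, "sign-flip")
    null_max = np.empty(n_perm)
    n_sub = maps.shape[0]
    for k in range(n_perm):
        signs = rng.choice([-1.0, 1.0], size=n_sub)
        flipped = maps * signs.reshape((n_sub,) + (1,) * (maps.ndim - 1))
        null_max[k] = np.abs(tfce_enhance(_one_sample_t(flipped), params)).max()
    exceed = (null_max[None, :] >= np.abs(observed).reshape(-1, 1)).sum(axis=1)
    p = ((1.0 + exceed) / (n_perm + 1.0)).reshape(observed.shape)
    return PermutationResult(p_corrected=p, tfce_observed=observed,
                             null_max=null_max, n_perm=n_perm, seed=seed)


def paired_contrast_test(maps_a: np.ndarray, maps_b: np.ndarray, n_perm: int = 5000,
                         params: TfceParams = TfceParams(), seed: int = 0
                         ) -> PermutationResult:
    """Paired contrast: sign-flip test on the per-participant difference maps."""
    a = np.asarray(maps_a, dtype=float)
    b = np.asarray(maps_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired maps must come from the same participants/grid")
    return sign_flip_test(a - b, n_perm=n_perm, params=params, seed=seed)
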