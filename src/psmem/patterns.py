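"""Synthetic voxel activation patterns.

Generative model (all components standard normal, unit variance by
construction, so pairwise correlations are available in closed form):

pre-encoding latent of object *i* in a voxel set of size V::

    L_i = sqrt(d_cat) * C[cat(i)] + sqrt(1 - d_cat) * U_i

where ``C[k]`` is a category component shared by the eight objects of
category *k* and ``U_i`` is object-specific. Same-category latents therefore
correlate at ``d_cat`` (``category_effect``), different-category latents at 0.

post-encoding latent::

    P_i = sqrt(1 - g_i) * L_i + sqrt(g_i) * F_i

with fresh ``F_i`` built the same way from post-encoding components; the
mixing weight ``g_i`` (the *reorganization gap*) depends on the object's
congruence and on the cortisol/placebo group, so pre-to-post self-correlation
is ``sqrt(1 - g_i)`` at the latent level. For incongruent task-relevant
objects the fresh component's category loading is raised by
``relevance_sim_boost``, planting the higher post-encoding similarity of
those objects to their congruent same-category counterparts.

observed session pattern (two sessions per day)::

    X_{i,s} = latent_i + noise_sd * eps_{i,s}

which attenuates every latent correlation by ``1 / (1 + noise_sd**2)``.
For bivariate Gaussian data the population Spearman correlation is
``(6/pi) * asin(rho/2)``; :func:`expected_same_category_spearman` exposes the
resulting closed form used by the calibration tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._rng import child_rng
from .design import N_OBJECTS, ROOMS, StudyDesign

SESSIONS = ("pre1", "pre2", "post1", "post2")

__all__ = ["GeneratorParams", "PatternSet", "generate_patterns", "generate_pattern_volumes",
           "expected_same_category_spearman", "expected_self_spearman", "SESSIONS"]


@dataclass(frozen=True)
class GeneratorParams:
    """Knobs of the synthetic-data generator.

    Defaults encode the study conditions the analyses assume: a small
    same-category similarity effect pre-encoding, a larger reorganization gap
    for incongruent than congruent objects (lower pre-to-post self-similarity
    for incongruent objects), higher pattern retention under cortisol, an
    episodic/semantic/unrelated room-choice bias that is more semantic for
    task-irrelevant objects, roughly three quarters of objects recognized,
    and 5% fly trials.
    """

    n_voxels: int = 60
    category_effect: float = 0.1
    reorg_gap_congruent: float = 0.2
    reorg_gap_incongruent: float = 0.4
    group_reorg_shift: float = 0.1
    relevance_sim_boost: float = 0.15
    noise_sd: float = 1.0
    bias_probs_relevant: tuple[float, float, float] = (0.70, 0.15, 0.15)
    bias_probs_irrelevant: tuple[float, float, float] = (0.40, 0.40, 0.20)
    drop_noise_sd: float = 2.0
    recognition_miss_rate: float = 0.23
    confidence_midpoint: float = 5.0
    confidence_scale: float = 3.0
    confidence_noise_sd: float = 5.0
    fly_rate: float = 0.05
    fly_miss_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("bias_probs_relevant", "bias_probs_irrelevant"):
            p = getattr(self, name)
            if len(p) != 3 or any(x < 0 for x in p) or abs(sum(p) - 1.0) > 1e-9:
                raise ValueError(f"{name} must be a probability triple summing to 1")
        for name in ("recognition_miss_rate", "fly_rate", "fly_miss_rate",
                     "category_effect", "reorg_gap_congruent", "reorg_gap_incongruent"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    def bias_probs(self, task_relevant: bool) -> tuple[float, float, float]:
        return self.bias_probs_relevant if task_relevant else self.bias_probs_irrelevant

    def with_(self, **kwargs) -> "GeneratorParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class PatternSet:
    """Per-session, per-object voxel activation vectors within one ROI."""

    sessions: dict[str, np.ndarray]  # session name -> (n_objects, n_voxels)
    participant_id: str = ""
    roi: str = "roi"

    def __post_init__(self) -> None:
        shapes = {v.shape for v in self.sessions.values()}
        if len(shapes) > 1:
            raise ValueError("all sessions must share the same (objects, voxels) shape")

    @property
    def n_objects(self) -> int:
        return next(iter(self.sessions.values())).shape[0]


def _reorg_mixing(design: StudyDesign, params: GeneratorParams) -> np.ndarray:
    """Per-object mixing weight g_i in [0, 1]."""
    g = np.empty(N_OBJECTS)
    shift = params.group_reorg_shift if design.group == "cortisol" else 0.0
    for obj in design.objects:
        base = params.reorg_gap_congruent if obj.congruent else params.reorg_gap_incongruent
        g[obj.object_id] = np.clip(base - shift, 0.0, 1.0)
    return g


def _draw_latents(design: StudyDesign, params: GeneratorParams, rng: np.random.Generator,
                  n_voxels: int, cat_loading: np.ndarray | None = None
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Draw pre- and post-encoding latent vectors, (n_objects, n_voxels) each.

    ``cat_loading`` is a per-voxel category-effect profile (defaults to the
    uniform ``category_effect``); setting it to zero in a voxel removes the
    category structure there, which is how planted-region volumes are built.
    """
    if n_voxels < 2:
        raise ValueError("n_voxels must be >= 2 (correlation undefined otherwise)")
    d = np.full(n_voxels, params.category_effect) if cat_loading is None else cat_loading
    cat_idx = np.array([ROOMS.index(o.category) for o in design.objects])

    def draw_layer(boost: np.ndarray) -> np.ndarray:
        # boost: per-object additive category loading (n_objects,)
        comp = rng.standard_normal((len(ROOMS), n_voxels))
        uniq = rng.standard_normal((N_OBJECTS, n_voxels))
        load = np.clip(d[None, :] + boost[:, None], 0.0, 1.0)
        return np.sqrt(load) * comp[cat_idx] + np.sqrt(1.0 - load) * uniq

    no_boost = np.zeros(N_OBJECTS)
    pre = draw_layer(no_boost)
    boost = np.array(
        [params.relevance_sim_boost if (not o.congruent and o.task_relevant) else 0.0
         for o in design.objects]
    )
    fresh = draw_layer(boost)
    g = _reorg_mixing(design, params)[:, None]
    post = np.sqrt(1.0 - g) * pre + np.sqrt(g) * fresh
    return pre, post


def generate_patterns(design: StudyDesign, params: GeneratorParams,
                      roi: str = "roi") -> PatternSet:
    """Generate observed patterns for the four PVT sessions of one ROI."""
    rng = child_rng(params.seed, "patterns", design.participant_id, roi)
    pre, post = _draw_latents(design, params, rng, params.n_voxels)
    sessions: dict[str, np.ndarray] = {}
    for name in SESSIONS:
        latent = pre if name.startswith("pre") else post
        sessions[name] = latent + params.noise_sd * rng.standard_normal(latent.shape)
    return PatternSet(sessions=sessions, participant_id=design.participant_id, roi=roi)


def generate_pattern_volumes(design: StudyDesign, params: GeneratorParams,
                             shape: tuple[int, int, int],
                             signal_mask: np.ndarray | None = None,
                             roi: str = "volume") -> dict[str, np.ndarray]:
    """Volumetric variant: session -> (n_objects, *shape) arrays.

    The category structure is confined to ``signal_mask`` (everywhere by
    default); outside it objects still have stable object-specific patterns
    but no category similarity, which is the planted-signal fixture for the
    searchlight path.
    """
    n_vox = int(np.prod(shape))
    loading = np.full(n_vox, params.category_effect)
    if signal_mask is not None:
        if signal_mask.shape != shape:
            raise ValueError("signal_mask shape must match volume shape")
        loading = np.where(signal_mask.ravel(), params.category_effect, 0.0)
    rng = child_rng(params.seed, "pattern-volumes", design.participant_id, roi)
    pre, post = _draw_latents(design, params, rng, n_vox, cat_loading=loading)
    out: dict[str, np.ndarray] = {}
    for name in SESSIONS:
        latent = pre if name.startswith("pre") else post
        obs = latent + params.noise_sd * rng.standard_normal(latent.shape)
        out[name] = obs.reshape((N_OBJECTS, *shape))
    return out


def _gauss_spearman(rho: float) -> float:
    """Population Spearman correlation of a bivariate Gaussian with Pearson rho."""
    return (6.0 / np.pi) * np.arcsin(rho / 2.0)


def expected_same_category_spearman(params: GeneratorParams) -> float:
    """Closed-form pre-encoding Spearman correlation between same-category objects."""
    rho = params.category_effect / (1.0 + params.noise_sd**2)
    return _gauss_spearman(rho)


def expected_self_spearman(params: GeneratorParams, congruent: bool,
                           group: str = "placebo") -> float:
    """Closed-form pre-to-post self Spearman correlation for one condition."""
    base = params.reorg_gap_congruent if congruent else params.reorg_gap_incongruent
    g = np.clip(base - (params.group_reorg_shift if group == "cortisol" else 0.0), 0.0, 1.0)
    rho = np.sqrt(1.0 - g) / (1.0 + params.noise_sd**2)
    return _gauss_spearman(rho)
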