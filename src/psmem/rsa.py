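"""Pattern-similarity constructs.

Pattern similarity (PS) between two voxel activation patterns is the
Fisher-z-transformed Spearman correlation. Four constructs are built from
the four PVT sessions:

* **PS pre-encoding** — object-by-object matrix correlating session 1 with
  session 2 of day 1 (symmetrized over the two run orderings);
* **PS post-encoding** — the same for day 2;
* **PS change** — post minus pre, entrywise;
* **pattern reorganization** — an object's similarity to itself across days,
  the average of the four Fisher-z pre-session x post-session
  self-correlations (lower values = greater representational change).

Correlations are clipped to +/-(1 - 1e-7) before atanh so degenerate
fixtures stay finite; clip events are counted on the matrix object.
Constant patterns yield missing (NaN) similarities, never zeros.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .design import StudyDesign

CLIP = 1.0 - 1e-7

__all__ = [
    "SimilarityMatrix",
    "average_within_session",
    "spearman_z",
    "within_day_matrix",
    "ps_change",
    "reorganization",
    "build_pair_table",
    "incongruent_category_mean",
    "mds_embed",
]


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric object x object Fisher-z similarity matrix."""

    values: np.ndarray
    day: str  # {pre, post, change, cross}
    participant_id: str = ""
    roi: str = "roi"
    object_ids: tuple[int, ...] = field(default_factory=tuple)
    clip_count: int = 0

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("similarity matrix must be square")
        if not self.object_ids:
            object.__setattr__(self, "object_ids", tuple(range(v.shape[0])))

    @property
    def n_objects(self) -> int:
        return self.values.shape[0]

    def pair_values(self) -> pd.DataFrame:
        """Long format: one row per unordered off-diagonal pair (i < j)."""
        i, j = np.triu_indices(self.n_objects, k=1)
        return pd.DataFrame({
            "object_i": np.asarray(self.object_ids)[i],
            "object_j": np.asarray(self.object_ids)[j],
            "z": self.values[i, j],
        })


def average_within_session(presentations: np.ndarray,
                           usable: np.ndarray | None = None) -> np.ndarray:
    """Voxelwise mean over a (n_presentations, n_voxels) stack.

    ``usable`` masks out fly-flagged / scrubbed presentations; zero usable
    presentations is an error (propagated to QC by the caller).
    """
    p = np.asarray(presentations, dtype=float)
    if p.ndim == 1:
        p = p[None, :]
    if usable is not None:
        p = p[np.asarray(usable, bool)]
    if p.shape[0] == 0:
        raise ValueError("no usable presentations to average")
    return p.mean(axis=0)


def _rank_rows(a: np.ndarray) -> np.ndarray:
    return rankdata(np.asarray(a, dtype=float), axis=1)


def _pearson_rows(ra: np.ndarray, rb: np.ndarray) -> np.ndarray:
    """Row-by-row Pearson correlation matrix between two (n, v) arrays.

    Rows with zero variance produce NaN (undefined correlation).
    """
    a = ra - ra.mean(axis=1, keepdims=True)
    b = rb - rb.mean(axis=1, keepdims=True)
    sa = np.sqrt((a**2).sum(axis=1))
    sb = np.sqrt((b**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (a @ b.T) / np.outer(sa, sb)
    r[sa == 0, :] = np.nan
    r[:, sb == 0] = np.nan
    return r


def _fisher_z(r: np.ndarray) -> tuple[np.ndarray, int]:
    clipped = np.clip(r, -CLIP, CLIP)
    n_clip = int(np.sum(np.abs(r) > CLIP))
    return np.arctanh(clipped), n_clip


def spearman_z(pattern_a: np.ndarray, pattern_b: np.ndarray) -> float:
    """Fisher-z Spearman similarity between two patterns.

    Average ranks for ties; correlations clipped to +/-(1 - 1e-7) before
    atanh. Constant input (zero rank variance) returns NaN.
    """
    a = np.asarray(pattern_a, dtype=float)
    b = np.asarray(pattern_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("patterns must be equal-length 1-d arrays of size >= 2")
    r = _pearson_rows(rankdata(a)[None, :], rankdata(b)[None, :])[0, 0]
    z, _ = _fisher_z(np.asarray(r))
    return float(z)


def _spearman_z_matrix(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, int]:
    return _fisher_z(_pearson_rows(_rank_rows(a), _rank_rows(b)))


def within_day_matrix(session1: np.ndarray, session2: np.ndarray, day: str,
                      participant_id: str = "", roi: str = "roi",
                      object_ids: tuple[int, ...] = ()) -> SimilarityMatrix:
    """Object x object matrix for one day, symmetrized over run orderings.

    Entry (i, j) is the mean of z(sim(s1_i, s2_j)) and z(sim(s1_j, s2_i)).
    The diagonal (cross-run self-similarity within a day) is not part of the
    construct and is set to NaN.
    """
    s1 = np.asarray(session1, dtype=float)
    s2 = np.asarray(session2, dtype=float)
    if s1.shape != s2.shape:
        raise ValueError("both sessions must cover the same object set")
    z, n_clip = _spearman_z_matrix(s1, s2)
    m = (z + z.T) / 2.0
    np.fill_diagonal(m, np.nan)
    return SimilarityMatrix(values=m, day=day, participant_id=participant_id,
                            roi=roi, object_ids=tuple(object_ids), clip_count=n_clip)


def ps_change(pre: SimilarityMatrix, post: SimilarityMatrix) -> SimilarityMatrix:
    """Entrywise post - pre; missing entries propagate."""
    if pre.object_ids != post.object_ids:
        raise ValueError("pre and post matrices cover different object sets")
    return SimilarityMatrix(
        values=post.values - pre.values,
        day="change",
        participant_id=pre.participant_id,
        roi=pre.roi,
        object_ids=pre.object_ids,
        clip_count=pre.clip_count + post.clip_count,
    )


def reorganization(pre_sessions: tuple[np.ndarray, np.ndarray],
                   post_sessions: tuple[np.ndarray, np.ndarray],
                   design: StudyDesign | None = None,
                   participant_id: str = "", roi: str = "roi") -> pd.DataFrame:
    """Cross-day self-similarity per object.

    Each pre-session is correlated with each post-session; the four Fisher-z
    self-correlations are averaged per object. Higher values mean stronger
    reinstatement of the pre-encoding pattern. Returns one row per object
    with design columns joined when a design is given.
    """
    shapes = {np.asarray(s).shape for s in (*pre_sessions, *post_sessions)}
    if len(shapes) != 1:
        raise ValueError("all four sessions must cover the same object set")
    crossings = [
        np.diag(_spearman_z_matrix(np.asarray(p), np.asarray(q))[0])
        for p, q in itertools.product(pre_sessions, post_sessions)
    ]
    z = np.mean(np.stack(crossings, axis=0), axis=0)
    out = pd.DataFrame({"object_id": np.arange(len(z)), "reorg_z": z,
                        "participant_id": participant_id, "roi": roi})
    if design is not None:
        out = out.merge(
            design.to_frame()[["object_id", "congruent", "task_relevant",
                               "category", "group"]],
            on="object_id",
        )
    return out


def build_pair_table(pre: SimilarityMatrix, post: SimilarityMatrix,
                     design: StudyDesign,
                     behavior: pd.DataFrame | None = None) -> pd.DataFrame:
    """One row per unordered object pair joining similarities and predictors.

    Predictors: same_category, same_retrieved_room, retrieved_distance (the
    Euclidean distance between the two retrieved SRT positions),
    mean_confidence. Pairs with at least one unrecognized object are flagged
    (``excluded``) rather than dropped, so callers can match each analysis's
    filtering rule. ``behavior`` must be a scored table (see
    :func:`psmem.scoring.score_behavior`).
    """
    change = ps_change(pre, post)
    pairs = pre.pair_values().rename(columns={"z": "z_pre"})
    pairs["z_post"] = post.pair_values()["z"]
    pairs["z_change"] = change.pair_values()["z"]
    dmap = {o.object_id: o for o in design.objects}
    cat_i = pairs["object_i"].map(lambda i: dmap[i].category)
    cat_j = pairs["object_j"].map(lambda j: dmap[j].category)
    pairs["same_category"] = (cat_i == cat_j).to_numpy()
    pairs["participant_id"] = design.participant_id
    pairs["group"] = design.group
    if behavior is not None:
        b = behavior.set_index("object_id")
        for col, merged in (("retrieved_room", "same_retrieved_room"),):
            pairs[merged] = (
                b.loc[pairs["object_i"], col].to_numpy()
                == b.loc[pairs["object_j"], col].to_numpy()
            )
        xi = b.loc[pairs["object_i"], ["retrieved_x", "retrieved_y"]].to_numpy()
        xj = b.loc[pairs["object_j"], ["retrieved_x", "retrieved_y"]].to_numpy()
        pairs["retrieved_distance"] = np.hypot(*(xi - xj).T)
        pairs["mean_confidence"] = (
            b.loc[pairs["object_i"], "confidence"].to_numpy()
            + b.loc[pairs["object_j"], "confidence"].to_numpy()
        ) / 2.0
        rec = b["recognized"]
        pairs["excluded"] = ~(
            rec.loc[pairs["object_i"]].to_numpy() & rec.loc[pairs["object_j"]].to_numpy()
        )
    return pairs


def incongruent_category_mean(post: SimilarityMatrix, design: StudyDesign,
                              split: str, behavior: pd.DataFrame | None = None
                              ) -> pd.DataFrame:
    """Mean similarity of incongruent objects to their congruent same-category
    counterparts, averaged into per-participant condition cells.

    Each incongruent object contributes the mean of exactly four pairwise
    similarities (to the four congruently encountered objects of its
    category). ``split='relevance'`` averages over task-relevant vs.
    task-irrelevant objects (always 6 vs 6); ``split='room_choice'`` averages
    over objects sorted to the episodically correct room vs. the semantic
    room (needs a scored behavior table; unrecognized objects are retained
    by design in this analysis). A condition cell with no objects yields a
    missing mean rather than an error.
    """
    if split not in ("relevance", "room_choice"):
        raise ValueError("split must be 'relevance' or 'room_choice'")
    idx = {oid: k for k, oid in enumerate(post.object_ids)}
    per_object = {}
    for obj in design.objects:
        if obj.congruent:
            continue
        partners = [o.object_id for o in design.objects
                    if o.congruent and o.category == obj.category]
        per_object[obj.object_id] = float(
            np.mean([post.values[idx[obj.object_id], idx[p]] for p in partners])
        )

    rows = []
    if split == "relevance":
        cells = {"task_relevant": [oid for oid in per_object
                                   if design.by_id(oid).task_relevant],
                 "task_irrelevant": [oid for oid in per_object
                                     if not design.by_id(oid).task_relevant]}
    else:
        if behavior is None or "room_choice" not in behavior.columns:
            raise ValueError("room_choice split requires a scored behavior table")
        choice = behavior.set_index("object_id")["room_choice"]
        cells = {"correct": [oid for oid in per_object if choice.loc[oid] == "episodic"],
                 "semantic": [oid for oid in per_object if choice.loc[oid] == "semantic"]}
    for cond, oids in cells.items():
        rows.append({
            "participant_id": design.participant_id,
            "group": design.group,
            "split": split,
            "condition": cond,
            "mean_z": float(np.mean([per_object[o] for o in oids])) if oids else np.nan,
            "n_objects": len(oids),
        })
    return pd.DataFrame(rows)


def mds_embed(matrix: SimilarityMatrix) -> np.ndarray:
    """Classical (Torgerson) MDS of the similarity matrix into 2 dimensions.

    Dissimilarity d = 1 - tanh(z) (one minus the back-transformed
    correlation); output is centered at the origin with each axis flipped so
    the first object's coordinate is non-negative.
    """
    z = matrix.values.copy()
    np.fill_diagonal(z, np.arctanh(CLIP))  # self-dissimilarity 0
    d = 1.0 - np.tanh(z)
    np.fill_diagonal(d, 0.0)
    if not np.all(np.isfinite(d)):
        raise ValueError("non-finite dissimilarities; complete matrix required")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:2]
    coords = vecs[:, order] * np.sqrt(np.maximum(vals[order], 0.0))
    for dim in range(coords.shape[1]):
        if coords[0, dim] < 0:
            coords[:, dim] = -coords[:, dim]
    return coords
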