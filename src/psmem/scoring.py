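"""Spatial-recall scoring.

Scores the drag-and-drop spatial recall task: drop error (Euclidean distance
between the retrieved and true positions), geometric room lookup of the drop
coordinate, classification of each incongruent object's room choice as
episodic (encoded room), semantic (category room) or unrelated, and
participant-level semantic-bias proportions over recognized incongruent
objects. Drops landing in the corridor are classified as unrelated and
flagged (the board geometry makes them possible in principle only).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import CORRIDOR, ApartmentLayout, ObjectSpec, ROOMS, StudyDesign

__all__ = ["drop_error", "locate_room", "classify_room_choice", "score_behavior",
           "bias_summary"]


def drop_error(retrieved: tuple[float, float], true: tuple[float, float]) -> float:
    """Euclidean distance between the dropped and the correct location."""
    r = np.asarray(retrieved, dtype=float)
    t = np.asarray(true, dtype=float)
    if not (np.all(np.isfinite(r)) and np.all(np.isfinite(t))):
        raise ValueError("coordinates must be finite")
    return float(np.hypot(*(r - t)))


def locate_room(position: tuple[float, float], layout: ApartmentLayout) -> str:
    """Room whose rectangle contains the point; corridor if none.

    Membership is boundary-inclusive; a point on a shared boundary belongs
    to the room with the lower room index (documented tie-break). Positions
    outside the apartment bounding box are an error.
    """
    x, y = position
    bx0, by0, bx1, by1 = layout.bounding_box
    if not (bx0 <= x <= bx1 and by0 <= y <= by1):
        raise ValueError(f"position {position} outside the apartment bounding box")
    for room in ROOMS:
        x0, y0, x1, y1 = layout.rooms[room]
        if x0 <= x <= x1 and y0 <= y <= y1:
            return room
    return CORRIDOR


def classify_room_choice(obj: ObjectSpec, retrieved_room: str) -> str:
    """Episodic / semantic / unrelated classification of a room choice.

    For congruent objects the episodic and semantic rooms coincide and the
    classifier returns ``episodic``. Corridor drops count as unrelated.
    """
    if retrieved_room not in ROOMS and retrieved_room != CORRIDOR:
        raise ValueError(f"unknown room label {retrieved_room!r}")
    if retrieved_room == obj.encoded_room:
        return "episodic"
    if retrieved_room == obj.category:
        return "semantic"
    return "unrelated"


def score_behavior(behavior: pd.DataFrame, layout: ApartmentLayout | None = None,
                   design: StudyDesign | None = None) -> pd.DataFrame:
    """Add derived columns to a raw behavior table.

    Adds ``retrieved_room`` (geometric lookup of the drop coordinate),
    ``room_choice`` (episodic/semantic/unrelated) and ``drop_error``. The
    input needs columns retrieved_x/y, true_x/y, encoded_room, category,
    congruent, task_relevant.
    """
    layout = layout or (design.layout if design is not None else ApartmentLayout())
    out = behavior.copy()
    out["retrieved_room"] = [
        locate_room((row.retrieved_x, row.retrieved_y), layout)
        for row in out.itertuples()
    ]
    def _choice(row):
        if row.retrieved_room == row.encoded_room:
            return "episodic"
        if row.retrieved_room == row.category:
            return "semantic"
        return "unrelated"
    out["room_choice"] = [_choice(r) for r in out.itertuples()]
    out["drop_error"] = np.hypot(out["retrieved_x"] - out["true_x"],
                                 out["retrieved_y"] - out["true_y"])
    return out


def bias_summary(scored: pd.DataFrame) -> pd.DataFrame:
    """Semantic-bias proportions per participant x task-relevance level.

    Proportions of episodic / semantic / unrelated room choices over
    *recognized incongruent* objects. Cells with zero such objects get
    missing proportions (count 0) rather than raising.
    """
    base = scored[(~scored["congruent"]) & (scored["recognized"])]
    rows = []
    for (pid, relevant), grp in base.groupby(["participant_id", "task_relevant"],
                                             sort=True):
        n = len(grp)
        counts = grp["room_choice"].value_counts()
        row = {"participant_id": pid, "task_relevant": bool(relevant), "n": n}
        for label in ("episodic", "semantic", "unrelated"):
            row[f"p_{label}"] = counts.get(label, 0) / n if n else np.nan
        rows.append(row)
    # participants contribute both levels even when one cell is empty
    all_pids = scored["participant_id"].unique()
    have = {(r["participant_id"], r["task_relevant"]) for r in rows}
    for pid in all_pids:
        for relevant in (True, False):
            if (pid, relevant) not in have:
                rows.append({"participant_id": pid, "task_relevant": relevant, "n": 0,
                             "p_episodic": np.nan, "p_semantic": np.nan,
                             "p_unrelated": np.nan})
    return pd.DataFrame(rows).sort_values(
        ["participant_id", "task_relevant"]).reset_index(drop=True)
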