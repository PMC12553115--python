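"""Synthetic spatial-recall and recognition behavior.

Emulates the recognition task and the spatial recall task (SRT): every
object gets an old/new recognition outcome, a retrieved drop position on the
bird's-eye apartment board, and a 1-100 placement confidence. The SRT covers
all 24 objects whether or not they were recognized; the recognition filter
is applied downstream by the analyses that require it.

Room choice for incongruent objects follows the episodic/semantic/unrelated
bias triple of the object's task-relevance level. For congruent objects the
episodic and semantic rooms coincide, so the encoded room is chosen with the
combined episodic + semantic probability. Within the chosen room the drop
position is anchored at the true position (episodic choice) or the room
centroid (semantic/unrelated choice) plus isotropic Gaussian noise, then
clipped to the room rectangle. Confidence falls logistically with drop
error.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._rng import child_rng
from .design import ROOMS, StudyDesign
from .patterns import GeneratorParams
from .schedule import PvtSchedule

__all__ = ["generate_behavior", "generate_fly_performance"]


def _clip_to_rect(pos: np.ndarray, rect: tuple[float, float, float, float],
                  margin: float = 0.1) -> np.ndarray:
    x0, y0, x1, y1 = rect
    return np.array([np.clip(pos[0], x0 + margin, x1 - margin),
                     np.clip(pos[1], y0 + margin, y1 - margin)])


def generate_behavior(design: StudyDesign, params: GeneratorParams) -> pd.DataFrame:
    """Simulate recognition + SRT outcomes; one row per object.

    Columns: object_id, recognized, retrieved_x/y, chosen_room (the room the
    drop was aimed at), confidence, plus the design columns needed by the
    scoring module.
    """
    rng = child_rng(params.seed, "behavior", design.participant_id)
    rows = []
    for obj in design.objects:
        recognized = bool(rng.random() >= params.recognition_miss_rate)
        p_epi, p_sem, p_unr = params.bias_probs(obj.task_relevant)
        others = [r for r in ROOMS if r not in (obj.encoded_room, obj.category)]
        if obj.congruent:
            # episodic and semantic rooms coincide; two unrelated rooms
            choices = [obj.encoded_room] + others
            probs = [p_epi + p_sem] + [p_unr / len(others)] * len(others)
        else:
            choices = [obj.encoded_room, obj.category] + others
            probs = [p_epi, p_sem] + [p_unr / len(others)] * len(others)
        room = choices[rng.choice(len(choices), p=np.asarray(probs) / np.sum(probs))]
        anchor = np.asarray(obj.true_position) if room == obj.encoded_room \
            else np.asarray(design.layout.centroid(room))
        pos = anchor + params.drop_noise_sd * rng.standard_normal(2)
        pos = _clip_to_rect(pos, design.layout.rooms[room])
        err = float(np.hypot(*(pos - np.asarray(obj.true_position))))
        conf = 1.0 + 99.0 / (1.0 + np.exp((err - params.confidence_midpoint)
                                          / params.confidence_scale))
        conf = float(np.clip(conf + params.confidence_noise_sd * rng.standard_normal(), 1, 100))
        rows.append(
            {
                "object_id": obj.object_id,
                "recognized": recognized,
                "retrieved_x": float(pos[0]),
                "retrieved_y": float(pos[1]),
                "chosen_room": room,
                "confidence": conf,
                "category": obj.category,
                "encoded_room": obj.encoded_room,
                "congruent": obj.congruent,
                "task_relevant": obj.task_relevant,
                "true_x": obj.true_position[0],
                "true_y": obj.true_position[1],
                "participant_id": design.participant_id,
                "group": design.group,
            }
        )
    return pd.DataFrame(rows)


def generate_fly_performance(schedule: PvtSchedule, params: GeneratorParams,
                             participant_id: str = "", day: str = "pre") -> pd.DataFrame:
    """Fly hits/misses per session (run) of one day's schedule."""
    rng = child_rng(params.seed, "flies", participant_id, day)
    rows = []
    for s, _session in enumerate(schedule.blocks):
        n_fly = sum(1 for (ss, _b, _o) in schedule.fly_trials if ss == s)
        misses = int(rng.binomial(n_fly, params.fly_miss_rate)) if n_fly else 0
        rows.append({"day": day, "session": s, "n_fly": n_fly,
                     "misses": misses, "participant_id": participant_id})
    return pd.DataFrame(rows)
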