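"""Picture-viewing-task (PVT) presentation schedule.

One scanning day comprises two PVT sessions of six blocks each; every block
shows all 24 objects once in random order, so each object is presented 12
times per day. A small fraction of trials (default 5%) additionally shows a
fly; fly trials keep participants attentive and are excluded from pattern
estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import child_rng
from .design import N_OBJECTS, StudyDesign

N_SESSIONS_PER_DAY = 2
N_BLOCKS_PER_SESSION = 6

__all__ = ["PvtSchedule", "generate_pvt_schedule", "N_SESSIONS_PER_DAY", "N_BLOCKS_PER_SESSION"]


@dataclass(frozen=True)
class PvtSchedule:
    """Ordered object presentations for one scanning day.

    ``blocks[session][block]`` is the ordered list of the 24 object ids shown
    in that block; ``fly_trials`` flags individual (session, block, object)
    presentations.
    """

    blocks: tuple[tuple[tuple[int, ...], ...], ...]
    fly_trials: frozenset[tuple[int, int, int]] = field(default_factory=frozenset)

    @property
    def n_trials(self) -> int:
        return sum(len(b) for session in self.blocks for b in session)

    def presentations_per_object(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for session in self.blocks:
            for block in session:
                for oid in block:
                    counts[oid] = counts.get(oid, 0) + 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s, session in enumerate(self.blocks):
            for b, block in enumerate(session):
                for pos, oid in enumerate(block):
                    rows.append(
                        {
                            "session": s,
                            "block": b,
                            "trial_in_block": pos,
                            "object_id": oid,
                            "fly": (s, b, oid) in self.fly_trials,
                        }
                    )
        return pd.DataFrame(rows)


def generate_pvt_schedule(design: StudyDesign, fly_rate: float = 0.05,
                          seed: int | None = None, day: str = "pre") -> PvtSchedule:
    """Build one day's schedule: 2 sessions x 6 blocks x 24 presentations.

    ``round(fly_rate * 288)`` trials are flagged as fly trials, spread
    uniformly at random over all presentations of the day.
    """
    if not 0 <= fly_rate < 1:
        raise ValueError("fly_rate must be in [0, 1)")
    rng = child_rng(design.seed if seed is None else seed, "schedule", day)
    blocks = tuple(
        tuple(tuple(int(i) for i in rng.permutation(N_OBJECTS)) for _ in range(N_BLOCKS_PER_SESSION))
        for _ in range(N_SESSIONS_PER_DAY)
    )
    all_trials = [
        (s, b, oid)
        for s, session in enumerate(blocks)
        for b, block in enumerate(session)
        for oid in block
    ]
    n_fly = int(round(fly_rate * len(all_trials)))
    fly_idx = rng.choice(len(all_trials), size=n_fly, replace=False) if n_fly else []
    fly = frozenset(all_trials[i] for i in fly_idx)
    return PvtSchedule(blocks=blocks, fly_trials=fly)
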