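"""Study design: object layout in the three-room apartment.

Twenty-four everyday objects, eight per semantic room category (kitchen,
bathroom, bedroom), are placed in a virtual three-room apartment. An object
is *congruent* when it is encoded in the room matching its semantic category
(a toaster in the kitchen) and *incongruent* otherwise (a toaster in the
bathroom). Half of the objects are *task-relevant* (interacted with during
encoding), half task-irrelevant. Placement is counterbalanced so that every
room receives four congruent and four incongruent objects and four
task-relevant and four task-irrelevant objects, equally divided among
congruent and incongruent placements and balanced for category of origin,
which yields six incongruent task-relevant and six incongruent
task-irrelevant objects per participant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import child_rng

ROOMS = ("kitchen", "bathroom", "bedroom")
CORRIDOR = "corridor"
N_OBJECTS = 24
N_PER_CATEGORY = 8

__all__ = [
    "ROOMS",
    "CORRIDOR",
    "N_OBJECTS",
    "ObjectSpec",
    "ApartmentLayout",
    "StudyDesign",
    "generate_design",
]


@dataclass(frozen=True)
class ObjectSpec:
    """One object's role in the study design."""

    object_id: int
    category: str
    encoded_room: str
    congruent: bool
    task_relevant: bool
    true_position: tuple[float, float]

    def __post_init__(self) -> None:
        if self.category not in ROOMS or self.encoded_room not in ROOMS:
            raise ValueError(f"unknown room label for object {self.object_id}")
        if self.congruent != (self.encoded_room == self.category):
            raise ValueError("congruent flag inconsistent with encoded_room/category")


@dataclass(frozen=True)
class ApartmentLayout:
    """Axis-aligned rectangles for the three rooms plus the corridor.

    Geometry is unit-free: three 10x10 rooms side by side with a corridor
    strip along the top. Only relative distances matter downstream, so the
    absolute scale is arbitrary by design. Rectangles are (xmin, ymin, xmax,
    ymax); room membership is boundary-inclusive with ties broken by the
    lower room index (see :func:`psmem.scoring.locate_room`).
    """

    rooms: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: {
            "kitchen": (0.0, 0.0, 10.0, 10.0),
            "bathroom": (10.0, 0.0, 20.0, 10.0),
            "bedroom": (20.0, 0.0, 30.0, 10.0),
        }
    )
    corridor: tuple[float, float, float, float] = (0.0, 10.0, 30.0, 13.0)

    @property
    def bounding_box(self) -> tuple[float, float, float, float]:
        rects = list(self.rooms.values()) + [self.corridor]
        xs0, ys0, xs1, ys1 = zip(*rects)
        return (min(xs0), min(ys0), max(xs1), max(ys1))

    def centroid(self, room: str) -> tuple[float, float]:
        x0, y0, x1, y1 = self.corridor if room == CORRIDOR else self.rooms[room]
        return ((x0 + x1) / 2.0, (y0 + y1) / 2.0)


@dataclass(frozen=True)
class StudyDesign:
    """Complete object layout for one simulated participant."""

    objects: tuple[ObjectSpec, ...]
    layout: ApartmentLayout
    participant_id: str
    group: str  # "cortisol" | "placebo"
    seed: int

    def __post_init__(self) -> None:
        if self.group not in ("cortisol", "placebo"):
            raise ValueError(f"unknown group {self.group!r}")
        ids = [o.object_id for o in self.objects]
        if len(ids) != N_OBJECTS or len(set(ids)) != N_OBJECTS:
            raise ValueError("design must contain 24 uniquely identified objects")

    def to_frame(self) -> pd.DataFrame:
        """One row per object (the TSV serialization layout)."""
        return pd.DataFrame(
            {
                "object_id": [o.object_id for o in self.objects],
                "category": [o.category for o in self.objects],
                "encoded_room": [o.encoded_room for o in self.objects],
                "congruent": [o.congruent for o in self.objects],
                "task_relevant": [o.task_relevant for o in self.objects],
                "true_x": [o.true_position[0] for o in self.objects],
                "true_y": [o.true_position[1] for o in self.objects],
                "participant_id": self.participant_id,
                "group": self.group,
            }
        )

    def by_id(self, object_id: int) -> ObjectSpec:
        return self.objects[object_id]


def _uniform_in_room(rng: np.random.Generator, rect: tuple[float, float, float, float],
                     margin: float = 0.5) -> tuple[float, float]:
    x0, y0, x1, y1 = rect
    return (
        float(rng.uniform(x0 + margin, x1 - margin)),
        float(rng.uniform(y0 + margin, y1 - margin)),
    )


def generate_design(seed: int, group: str = "placebo",
                    participant_id: str | None = None) -> StudyDesign:
    """Generate one counterbalanced pseudo-random object layout.

    Within each semantic category the eight objects are shuffled and dealt
    into fixed counterbalancing slots: four congruent (two task-relevant),
    and four incongruent split as one task-relevant plus one task-irrelevant
    object into each of the two non-category rooms. This satisfies every
    room-level count by construction for any seed.
    """
    if seed < 0:
        raise ValueError("seed must be a non-negative integer")
    rng = child_rng(seed, "design")
    layout = ApartmentLayout()

    objects: list[ObjectSpec] = []
    for ci, category in enumerate(ROOMS):
        ids = np.arange(ci * N_PER_CATEGORY, (ci + 1) * N_PER_CATEGORY)
        ids = rng.permutation(ids)
        other = [r for r in ROOMS if r != category]
        # slot -> (encoded_room, task_relevant)
        slots = [
            (category, True), (category, True), (category, False), (category, False),
            (other[0], True), (other[0], False), (other[1], True), (other[1], False),
        ]
        for oid, (room, relevant) in zip(ids, slots):
            pos = _uniform_in_room(rng, layout.rooms[room])
            objects.append(
                ObjectSpec(
                    object_id=int(oid),
                    category=category,
                    encoded_room=room,
                    congruent=room == category,
                    task_relevant=relevant,
                    true_position=pos,
                )
            )
    objects.sort(key=lambda o: o.object_id)
    return StudyDesign(
        objects=tuple(objects),
        layout=layout,
        participant_id=participant_id or f"sub-{seed:04d}",
        group=group,
        seed=int(seed),
    )
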