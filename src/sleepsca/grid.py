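"""Declarative enumeration of the analytical specification grid.

A specification is one full analytical path: day type x sleep measure x
technology measure x control set.  The default options yield 2*3*4*5 = 120
specifications; a "no controls" option is deliberately absent.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Callable, Sequence

import pandas as pd

DAY_OPTIONS = ("weekday", "weekend")
SLEEP_OPTIONS = ("bedtime_retro", "bedtime_diary", "total_sleep_retro")
TECH_OPTIONS = ("participation", "bedtime_use", "time_spent_diary", "time_spent_retro")
CONTROL_OPTIONS = (
    "demographics",
    "demographics_child",
    "demographics_mother",
    "demographics_family",
    "all",
)

FIELDS = ("day_type", "sleep_measure", "tech_measure", "control_set")


class GridError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class Specification:
    day_type: str
    sleep_measure: str
    tech_measure: str
    control_set: str

    @property
    def spec_id(self) -> str:
        return "|".join(
            (self.day_type, self.sleep_measure, self.tech_measure, self.control_set)
        )

    @classmethod
    def from_id(cls, spec_id: str) -> "Specification":
        parts = spec_id.split("|")
        if len(parts) != 4:
            raise GridError(f"malformed spec_id: {spec_id!r}")
        return cls(*parts)


def build_grid(
    day_options: Sequence[str] = DAY_OPTIONS,
    sleep_options: Sequence[str] = SLEEP_OPTIONS,
    tech_options: Sequence[str] = TECH_OPTIONS,
    control_options: Sequence[str] = CONTROL_OPTIONS,
) -> tuple[Specification, ...]:
    """Full Cartesian product of the analytical options, in stable order."""
    return tuple(
        Specification(day, sleep, tech, controls)
        for day, sleep, tech, controls in itertools.product(
            day_options, sleep_options, tech_options, control_options
        )
    )


def subset(
    grid: Sequence[Specification],
    predicate: Callable[[Specification], bool] | None = None,
    **field_values: str,
) -> tuple[Specification, ...]:
    """Order-preserving filter by predicate and/or field equality."""
    for field in field_values:
        if field not in FIELDS:
            raise GridError(f"unknown specification field {field!r}")
    out = []
    for spec in grid:
        if predicate is not None and not predicate(spec):
            continue
        if all(getattr(spec, f) == v for f, v in field_values.items()):
            out.append(spec)
    return tuple(out)


def grid_to_frame(grid: Sequence[Specification]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"spec_id": s.spec_id, **{f: getattr(s, f) for f in FIELDS}}
            for s in grid
        ]
    )


def frame_to_grid(frame: pd.DataFrame) -> tuple[Specification, ...]:
    return tuple(Specification.from_id(sid) for sid in frame["spec_id"])
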