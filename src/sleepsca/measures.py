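"""Derived sleep, technology, and covariate measures.

All scalar recoding rules follow the published midpoint conventions:

* retrospective bedtime category ``s`` (1-5) maps to clock time ``s + 7.5``
  (PM-decimal), so hours slept before midnight are ``12 - (s + 7.5)``;
* wake categories map to ``s + 4.5`` (weekday) or ``s + 6.5`` (weekend);
* total retrospective sleep is before-midnight plus after-midnight sleep;
* the diary sleep-onset score is ``145 - i`` for the slot ``i`` of the last
  transition from a non-sleep code into sleep (higher = earlier), with score
  1 (the 4 AM fallback) for diaries that never record a sleep onset.

Every function propagates missing inputs as ``nan`` and raises
:class:`ValidationError` for out-of-range values.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import DAY_TYPES
from .synthetic import DIGITAL_CODES, N_SLOTS, DiaryMatrix

__all__ = [
    "ValidationError",
    "reverse_bedtime_score",
    "bedtime_to_clock",
    "sleep_before_midnight",
    "wake_to_clock",
    "total_sleep_retro",
    "composite_screen",
    "diary_sleep_onset",
    "diary_onset_slot",
    "score_to_clock",
    "diary_participation",
    "diary_time_spent",
    "diary_bedtime_use",
    "closeness_score",
    "educational_motivation",
    "build_covariate_sets",
    "derive_measures",
]

WAKE_RANGE = {"weekday": (1, 5), "weekend": (1, 6)}
WAKE_OFFSET = {"weekday": 4.5, "weekend": 6.5}

COVARIATE_BLOCKS: dict[str, tuple[str, ...]] = {
    "demographics": ("sex", "age", "mother_white"),
    "child": ("closeness", "longterm_illness", "motivation"),
    "mother": ("word_activity", "nvq", "time_with_child", "kessler"),
    "family": ("income", "father_home", "n_siblings"),
}

#: covariates entering models as unordered factors (dummy-coded)
FACTOR_COVARIATES = ("nvq",)


class ValidationError(ValueError):
    """Raised when a raw score lies outside its documented range."""


def _is_missing(value) -> bool:
    try:
        return value is None or math.isnan(float(value))
    except (TypeError, ValueError):
        return True


def _check_range(value, lo: int, hi: int, name: str) -> float:
    v = float(value)
    if not (lo <= v <= hi) or v != int(v):
        raise ValidationError(f"{name} must be an integer in [{lo}, {hi}], got {value}")
    return v


def reverse_bedtime_score(score):
    """6 - score, so higher values mean earlier bedtimes.  An involution."""
    if _is_missing(score):
        return float("nan")
    return 6.0 - _check_range(score, 1, 5, "bedtime score")


def bedtime_to_clock(score) -> float:
    """Raw bedtime category to PM-decimal clock hours (bin midpoint)."""
    if _is_missing(score):
        return float("nan")
    return _check_range(score, 1, 5, "bedtime score") + 7.5


def sleep_before_midnight(score) -> float:
    """Hours asleep before midnight; negative when bedtime is past midnight."""
    if _is_missing(score):
        return float("nan")
    return 12.0 - bedtime_to_clock(score)


def wake_to_clock(score, day_type: str) -> float:
    """Wake category to AM-decimal clock hours for the given day type."""
    if day_type not in WAKE_RANGE:
        raise ValidationError(f"unknown day_type {day_type!r}")
    if _is_missing(score):
        return float("nan")
    lo, hi = WAKE_RANGE[day_type]
    return _check_range(score, lo, hi, f"{day_type} wake score") + WAKE_OFFSET[day_type]


def total_sleep_retro(bed_score, wake_score, day_type: str) -> float:
    """Total hours slept: before-midnight plus after-midnight components."""
    before = sleep_before_midnight(bed_score)
    after = wake_to_clock(wake_score, day_type)
    return before + after


def composite_screen(items: Sequence) -> float:
    """Mean of the four screen items; missing if any item is missing."""
    items = list(items)
    if len(items) != 4:
        raise ValidationError("composite_screen expects exactly four items")
    values = []
    for item in items:
        if _is_missing(item):
            return float("nan")
        values.append(_check_range(item, 1, 8, "screen item"))
    return float(np.mean(values))


def _slots(diary) -> np.ndarray:
    if isinstance(diary, DiaryMatrix):
        return diary.slots
    arr = np.asarray(diary, dtype=object)
    if arr.shape != (N_SLOTS,):
        raise ValidationError(f"diary must have exactly {N_SLOTS} slots")
    return arr


def diary_onset_slot(diary, fallback_score: float = 1.0) -> float:
    """1-based slot of the last non-sleep-to-sleep transition.

    Returns ``145 - fallback_score`` when no onset exists (sleep after 4 AM)
    and ``nan`` for an all-sleep diary, where onset is undefined.
    """
    slots = _slots(diary)
    asleep = slots == "SLEEP"
    if asleep.all():
        return float("nan")
    onsets = np.flatnonzero(asleep[1:] & ~asleep[:-1]) + 1  # 0-based slot index
    if onsets.size == 0:
        return 145.0 - fallback_score
    return float(onsets[-1] + 1)


def diary_sleep_onset(diary, fallback_score: float = 1.0) -> float:
    """Onset score on the 1-144 scale (higher = earlier in the day)."""
    slot = diary_onset_slot(diary, fallback_score=fallback_score)
    if math.isnan(slot):
        return float("nan")
    return 145.0 - slot


def score_to_clock(score) -> tuple[int, float]:
    """Invert an onset score to (hour, minutes) on the 24 h clock.

    Slot ``i = 145 - score`` starts ``(i - 1) * 10`` minutes after 4 AM.
    """
    s = float(score)
    if not (1.0 <= s <= 144.0):
        raise ValidationError(f"onset score must lie in [1, 144], got {score}")
    minutes_after_midnight = (240.0 + (144.0 - s) * 10.0) % 1440.0
    return int(minutes_after_midnight // 60), minutes_after_midnight % 60


def diary_participation(diary) -> int:
    """1 iff any slot carries a digital code."""
    slots = _slots(diary)
    return int(np.isin(slots, DIGITAL_CODES).any())


def diary_time_spent(diary) -> float:
    """Digital hours (10 min per slot); missing for non-participants."""
    slots = _slots(diary)
    count = int(np.isin(slots, DIGITAL_CODES).sum())
    if count == 0:
        return float("nan")
    return count * 10.0 / 60.0


def diary_bedtime_use(diary, onset_slot) -> int:
    """1 iff a digital code occupies any of the 3 slots before sleep onset."""
    slots = _slots(diary)
    if _is_missing(onset_slot):
        return 0
    i = int(onset_slot)
    window = [j for j in (i - 3, i - 2, i - 1) if 1 <= j <= N_SLOTS]
    if not window:
        return 0
    return int(np.isin(slots[[j - 1 for j in window]], DIGITAL_CODES).any())


def closeness_score(close_mother, close_father, argue_mother, argue_father) -> float:
    """Mean of the four closeness items with the two argue items reversed."""
    items = (close_mother, close_father, argue_mother, argue_father)
    if any(_is_missing(i) for i in items):
        return float("nan")
    cm = _check_range(close_mother, 1, 4, "closeness item")
    cf = _check_range(close_father, 1, 4, "closeness item")
    am = 5.0 - _check_range(argue_mother, 1, 4, "argue item")
    af = 5.0 - _check_range(argue_father, 1, 4, "argue item")
    return float(np.mean([cm, cf, am, af]))


def educational_motivation(items: Sequence) -> float:
    """Mean of six 4-level items with the first two reverse-coded."""
    items = list(items)
    if len(items) != 6:
        raise ValidationError("educational_motivation expects exactly six items")
    values = []
    for j, item in enumerate(items):
        if _is_missing(item):
            return float("nan")
        v = _check_range(item, 1, 4, "motivation item")
        values.append(5.0 - v if j < 2 else v)
    return float(np.mean(values))


def build_covariate_sets(table: pd.DataFrame | None = None) -> dict[str, tuple[str, ...]]:
    """The five nested control sets (demographics nested in every other set)."""
    demo = COVARIATE_BLOCKS["demographics"]
    sets = {
        "demographics": demo,
        "demographics_child": demo + COVARIATE_BLOCKS["child"],
        "demographics_mother": demo + COVARIATE_BLOCKS["mother"],
        "demographics_family": demo + COVARIATE_BLOCKS["family"],
        "all": demo
        + COVARIATE_BLOCKS["child"]
        + COVARIATE_BLOCKS["mother"]
        + COVARIATE_BLOCKS["family"],
    }
    if table is not None:
        missing = set(sets["all"]) - set(table.columns)
        if missing:
            raise ValidationError(f"table lacks covariate columns: {sorted(missing)}")
    return sets


def covariate_set(name: str) -> tuple[str, ...]:
    sets = build_covariate_sets()
    if name not in sets:
        raise ValidationError(f"unknown covariate set {name!r}")
    return sets[name]


def derive_measures(
    cohort: pd.DataFrame,
    diaries: Iterable[DiaryMatrix] | Mapping | None = None,
    fallback_score: float = 1.0,
) -> pd.DataFrame:
    """Build the long person-by-day-type analysis table.

    One row per person per day type, holding the derived sleep and technology
    measures alongside the (day-invariant) covariates.  Diary-derived columns
    are missing for adolescents without a diary.
    """
    diary_map: dict[tuple[int, str], DiaryMatrix] = {}
    for diary in diaries or ():
        diary_map[(int(diary.person_id), diary.day_type)] = diary

    comp = cohort.apply(
        lambda r: composite_screen(
            (r["screen_tv"], r["screen_games"], r["screen_internet"], r["screen_social"])
        ),
        axis=1,
    )
    closeness = cohort.apply(
        lambda r: closeness_score(
            r["close_mother"], r["close_father"], r["argue_mother"], r["argue_father"]
        ),
        axis=1,
    )
    motivation = cohort.apply(
        lambda r: educational_motivation([r[f"motiv_{j}"] for j in range(1, 7)]),
        axis=1,
    )

    frames = []
    for day in DAY_TYPES:
        bed = cohort[f"bedtime_{day}"]
        wake = cohort[f"wake_{day}"]
        rows = pd.DataFrame(
            {
                "person_id": cohort["person_id"].astype(int),
                "day_type": day,
                "bedtime_retro": bed.map(reverse_bedtime_score),
                "total_sleep_retro": [
                    total_sleep_retro(b, w, day) for b, w in zip(bed, wake)
                ],
                "composite_screen": comp,
                "fall_asleep_time": cohort["fall_asleep_time"],
                "night_waking": cohort["night_waking"],
                "closeness": closeness,
                "motivation": motivation,
                "has_diary": cohort["has_diary"].astype(bool),
            }
        )
        onset_scores, participations, times, uses = [], [], [], []
        for pid in rows["person_id"]:
            diary = diary_map.get((pid, day))
            if diary is None:
                onset_scores.append(float("nan"))
                participations.append(float("nan"))
                times.append(float("nan"))
                uses.append(float("nan"))
                continue
            onset_scores.append(diary_sleep_onset(diary, fallback_score=fallback_score))
            participations.append(float(diary_participation(diary)))
            times.append(diary_time_spent(diary))
            uses.append(
                float(
                    diary_bedtime_use(
                        diary, diary_onset_slot(diary, fallback_score=fallback_score)
                    )
                )
            )
        rows["onset_score"] = onset_scores
        rows["participation"] = participations
        rows["time_spent"] = times
        rows["bedtime_use"] = uses
        for cov in build_covariate_sets()["all"]:
            if cov in cohort.columns:
                rows[cov] = cohort[cov].to_numpy()
        frames.append(rows)
    return pd.concat(frames, ignore_index=True)
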