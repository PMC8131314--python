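"""EMA study-design: items, question-set personalization, and prompt schedules.

The protocol encoded here is signal-contingent sampling: prompts every
``interval_hours`` during the participant's waking window, for ``n_days``
days.  The question set is partly fixed (a 13-item battery) and partly
personalized (up to 3 extra physical complaints and up to 5 personal
factors), with a hard cap of 26 items so a survey stays under a minute.

Clock times are integer minutes since midnight; there are no time zones.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .errors import CapViolationError, InvalidDesignError

__all__ = [
    "ItemSpec",
    "StudyDesign",
    "PromptSchedule",
    "parse_clock",
    "format_clock",
    "default_fixed_items",
    "build_prompt_schedule",
    "personalize_question_set",
    "validate_design",
    "design_to_dict",
    "design_from_dict",
    "save_design",
    "load_design",
]

VALID_SCALES = ("vas", "categorical")
VALID_BLOCKS = ("fixed", "complaint", "personal")
VALID_BRANCHES = ("always", "morning_only", "later_only")

N_FIXED = 13
MAX_COMPLAINTS = 3
MAX_PERSONAL = 5
MAX_ITEMS = 26

#: Default waking window 08:00-22:59: with a 3-hour interval and an
#: inclusive end this yields the protocol's nominal five prompts per day.
DEFAULT_WAKING_START = 8 * 60
DEFAULT_WAKING_END = 22 * 60 + 59


def parse_clock(value: int | str) -> int:
    """Accept minutes-since-midnight or an ``HH:MM`` string."""
    if isinstance(value, str):
        hh, mm = value.split(":")
        value = int(hh) * 60 + int(mm)
    value = int(value)
    if not 0 <= value < 24 * 60:
        raise InvalidDesignError(f"clock time {value} outside 00:00-23:59")
    return value


def format_clock(minutes: int) -> str:
    return f"{minutes // 60:02d}:{minutes % 60:02d}"


@dataclass(frozen=True)
class ItemSpec:
    """One EMA question.

    ``scale`` is either ``vas`` (visual analogue scale, 0-100) or
    ``categorical`` (2-4 answer options).  ``block`` records whether the item
    belongs to the fixed battery, the personalized complaint slots, or the
    personalized personal-factor slots.  ``branch`` tags morning-only /
    later-only items (branching is a static tag: morning = first prompt of
    the day).
    """

    item_id: str
    label: str = ""
    scale: str = "vas"
    n_categories: int | None = None
    block: str = "fixed"
    branch: str = "always"

    def __post_init__(self):
        if self.scale not in VALID_SCALES:
            raise InvalidDesignError(f"item {self.item_id!r}: unknown scale {self.scale!r}")
        if self.block not in VALID_BLOCKS:
            raise InvalidDesignError(f"item {self.item_id!r}: unknown block {self.block!r}")
        if self.branch not in VALID_BRANCHES:
            raise InvalidDesignError(f"item {self.item_id!r}: unknown branch {self.branch!r}")
        if self.scale == "vas" and self.n_categories is not None:
            raise InvalidDesignError(f"item {self.item_id!r}: VAS items take no n_categories")
        if self.scale == "categorical" and (
            self.n_categories is None or not 2 <= self.n_categories <= 4
        ):
            raise InvalidDesignError(
                f"item {self.item_id!r}: categorical items need n_categories in [2, 4]"
            )


def default_fixed_items() -> list[ItemSpec]:
    """The 13-item fixed battery (placeholder labels).

    Covers fatigue, restrictions, school participation, night/day sleep,
    physical and mental activity, social support and mood-type VAS items
    plus two categorical context items (company, location).
    """
    vas = [
        ("fatigue", "How fatigued are you right now?", "always"),
        ("restrictions", "How restricted do you feel by your symptoms?", "always"),
        ("school_participation", "Share of scheduled school hours attended", "always"),
        ("nighttime_sleep", "How well did you sleep last night?", "morning_only"),
        ("daytime_sleep", "How much did you sleep since the last prompt?", "later_only"),
        ("physical_activity", "How physically active have you been?", "always"),
        ("mental_activity", "How mentally active have you been?", "always"),
        ("social_support", "How supported do you feel?", "always"),
        ("mood", "How is your mood right now?", "always"),
        ("worry", "How much have you been worrying?", "always"),
        ("relaxation", "How relaxed do you feel?", "always"),
    ]
    items = [
        ItemSpec(item_id=i, label=lbl, scale="vas", block="fixed", branch=br)
        for i, lbl, br in vas
    ]
    items.append(
        ItemSpec("company", "Are you alone or with others?", "categorical", 2, "fixed")
    )
    items.append(
        ItemSpec("location", "Where are you?", "categorical", 3, "fixed")
    )
    return items


@dataclass(frozen=True)
class StudyDesign:
    subject_id: str
    waking_start: int = DEFAULT_WAKING_START
    waking_end: int = DEFAULT_WAKING_END
    interval_hours: float = 3.0
    n_days: int = 42
    start_weekday: int = 0  # 0 = Monday; day_index 0 falls on this weekday
    items: tuple[ItemSpec, ...] = field(default_factory=lambda: tuple(default_fixed_items()))

    def __post_init__(self):
        object.__setattr__(self, "waking_start", parse_clock(self.waking_start))
        object.__setattr__(self, "waking_end", parse_clock(self.waking_end))
        object.__setattr__(self, "items", tuple(self.items))

    def item(self, item_id: str) -> ItemSpec:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(item_id)

    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    def with_items(self, items) -> "StudyDesign":
        return replace(self, items=tuple(items))


@dataclass(frozen=True)
class PromptSchedule:
    """All prompts sent to one subject, on a fixed daily grid.

    Derived per-occasion arrays (``day_index``, ``clock_minutes``,
    ``slot_of_day``, ``weekday``, ``is_weekend``, ``first_of_day``) are what
    the analysis modules consume.
    """

    prompts: tuple[tuple[int, int], ...]  # (day_index, minutes since midnight)
    per_day_count: int
    n_days: int
    interval_hours: float
    start_weekday: int = 0

    def __len__(self) -> int:
        return len(self.prompts)

    @property
    def day_index(self) -> np.ndarray:
        return np.array([d for d, _ in self.prompts], dtype=int)

    @property
    def clock_minutes(self) -> np.ndarray:
        return np.array([m for _, m in self.prompts], dtype=int)

    @property
    def slot_of_day(self) -> np.ndarray:
        return np.arange(len(self.prompts), dtype=int) % self.per_day_count

    @property
    def weekday(self) -> np.ndarray:
        return (self.day_index + self.start_weekday) % 7

    @property
    def is_weekend(self) -> np.ndarray:
        return self.weekday >= 5

    @property
    def first_of_day(self) -> np.ndarray:
        return self.slot_of_day == 0

    def slot_index(self) -> dict[tuple[int, int], int]:
        """Map (day_index, clock_minutes) -> occasion index."""
        return {p: i for i, p in enumerate(self.prompts)}

    def to_frame(self, subject_id: str | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "day_index": self.day_index,
                "clock_time": [format_clock(m) for m in self.clock_minutes],
            }
        )
        if subject_id is not None:
            df.insert(0, "subject_id", subject_id)
        return df


def _daily_times(design: StudyDesign) -> list[int]:
    step = int(round(design.interval_hours * 60))
    if step <= 0:
        raise InvalidDesignError(f"interval_hours must be positive, got {design.interval_hours}")
    if design.waking_end - design.waking_start < step:
        raise InvalidDesignError(
            f"waking window {format_clock(design.waking_start)}-"
            f"{format_clock(design.waking_end)} is shorter than one "
            f"{design.interval_hours}-hour interval"
        )
    # inclusive end: a prompt lands exactly on waking_end if the grid reaches it
    return list(range(design.waking_start, design.waking_end + 1, step))


def build_prompt_schedule(design: StudyDesign) -> PromptSchedule:
    """Daily grid: first prompt at waking_start, then every interval while
    the time stays <= waking_end (inclusive), repeated for n_days."""
    if design.n_days < 1:
        raise InvalidDesignError(f"n_days must be >= 1, got {design.n_days}")
    times = _daily_times(design)
    prompts = tuple(
        (day, t) for day, t in itertools.product(range(design.n_days), times)
    )
    return PromptSchedule(
        prompts=prompts,
        per_day_count=len(times),
        n_days=design.n_days,
        interval_hours=design.interval_hours,
        start_weekday=design.start_weekday,
    )


def personalize_question_set(
    fixed: list[ItemSpec],
    complaints: list[ItemSpec] = (),
    personal: list[ItemSpec] = (),
) -> tuple[ItemSpec, ...]:
    """Merge the fixed battery with personalized complaint/personal items.

    Raises on any cap violation; ordering is fixed, then complaints, then
    personal factors.
    """
    if len(fixed) != N_FIXED:
        raise InvalidDesignError(f"fixed battery must have exactly {N_FIXED} items, got {len(fixed)}")
    if len(complaints) > MAX_COMPLAINTS:
        raise CapViolationError(
            f"at most {MAX_COMPLAINTS} complaint items allowed, got {len(complaints)}"
        )
    if len(personal) > MAX_PERSONAL:
        raise CapViolationError(
            f"at most {MAX_PERSONAL} personal factors allowed, got {len(personal)}"
        )
    merged = (
        [replace(i, block="fixed") for i in fixed]
        + [replace(i, block="complaint") for i in complaints]
        + [replace(i, block="personal") for i in personal]
    )
    if len(merged) > MAX_ITEMS:
        raise CapViolationError(f"question set exceeds the {MAX_ITEMS}-item cap: {len(merged)}")
    seen: set[str] = set()
    for it in merged:
        if it.item_id in seen:
            raise InvalidDesignError(f"duplicate item_id {it.item_id!r}")
        seen.add(it.item_id)
    return tuple(merged)


def validate_design(design: StudyDesign) -> list[str]:
    """Return human-readable rule violations; empty list iff valid."""
    v: list[str] = []
    if design.waking_start >= design.waking_end:
        v.append(
            f"waking window: waking_start {format_clock(design.waking_start)} must be "
            f"before waking_end {format_clock(design.waking_end)}"
        )
    elif design.waking_end - design.waking_start < design.interval_hours * 60:
        v.append("waking window: shorter than one prompt interval")
    if design.interval_hours <= 0:
        v.append(f"interval_hours: must be positive, got {design.interval_hours}")
    if design.n_days < 1:
        v.append(f"n_days: must be >= 1, got {design.n_days}")
    if not 0 <= design.start_weekday <= 6:
        v.append(f"start_weekday: must be in [0, 6], got {design.start_weekday}")

    n_fixed = sum(1 for i in design.items if i.block == "fixed")
    n_complaint = sum(1 for i in design.items if i.block == "complaint")
    n_personal = sum(1 for i in design.items if i.block == "personal")
    if n_fixed != N_FIXED:
        v.append(f"items: exactly {N_FIXED} fixed items required, got {n_fixed}")
    if n_complaint > MAX_COMPLAINTS:
        v.append(f"items: at most {MAX_COMPLAINTS} complaint items allowed, got {n_complaint}")
    if n_personal > MAX_PERSONAL:
        v.append(f"items: at most {MAX_PERSONAL} personal factors allowed, got {n_personal}")
    if len(design.items) > MAX_ITEMS:
        v.append(f"items: total exceeds the {MAX_ITEMS}-item cap ({len(design.items)})")
    ids = [i.item_id for i in design.items]
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        v.append(f"items: duplicate item_id(s) {dupes}")
    return v


# --- config (YAML/JSON-dict) round trip -------------------------------------

def design_to_dict(design: StudyDesign) -> dict:
    return {
        "subject_id": design.subject_id,
        "waking_start": format_clock(design.waking_start),
        "waking_end": format_clock(design.waking_end),
        "interval_hours": design.interval_hours,
        "n_days": design.n_days,
        "start_weekday": design.start_weekday,
        "items": [
            {
                k: v
                for k, v in {
                    "item_id": i.item_id,
                    "label": i.label,
                    "scale": i.scale,
                    "n_categories": i.n_categories,
                    "block": i.block,
                    "branch": i.branch,
                }.items()
                if v is not None
            }
            for i in design.items
        ],
    }


def design_from_dict(d: dict) -> StudyDesign:
    items = tuple(ItemSpec(**i) for i in d.get("items", []))
    kwargs = {k: v for k, v in d.items() if k != "items"}
    if items:
        kwargs["items"] = items
    return StudyDesign(**kwargs)


def save_design(design: StudyDesign, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(design_to_dict(design), fh, sort_keys=False)


def load_design(path) -> StudyDesign:
    with open(path) as fh:
        return design_from_dict(yaml.safe_load(fh))
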