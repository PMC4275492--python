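"""Segmented-day questionnaire structure and raw section scoring.

The bundled instrument is a 15-item, 3-section segmented-day recall for
youth (grades 4-12): five items cover in-school periods (commute to
school, recess, physical education, lunch, commute from school), five
cover out-of-school periods (before school, after school, evening,
Saturday, Sunday), and five cover sedentary habits.  Each activity item
is linked to one window type of the weekly accelerometer-processing
schedule so that self-reported scores can be regressed on objectively
measured percent time in MVPA for the matching window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .segment import WindowType

SECTION_SCHOOL = "activity_at_school"
SECTION_OUT = "activity_out_of_school"
SECTION_SEDENTARY = "sedentary"

DEFAULT_SECTIONS = (SECTION_SCHOOL, SECTION_OUT, SECTION_SEDENTARY)

SCHOOL_WINDOW_TYPES = frozenset(
    {
        WindowType.TRANSPORT_TO_SCHOOL,
        WindowType.RECESS,
        WindowType.PHYSICAL_EDUCATION,
        WindowType.LUNCH,
        WindowType.TRANSPORT_FROM_SCHOOL,
    }
)
OUT_OF_SCHOOL_WINDOW_TYPES = frozenset(
    {
        WindowType.BEFORE_SCHOOL,
        WindowType.AFTER_SCHOOL,
        WindowType.EVENING,
        WindowType.SATURDAY,
        WindowType.SUNDAY,
    }
)


class InstrumentError(ValueError):
    """Raised when an instrument definition violates its invariants."""


@dataclass(frozen=True)
class ItemDef:
    """One questionnaire item, optionally linked to a schedule window."""

    item_id: str
    section: str
    window_type: WindowType | None = None
    prompt: str = ""

    def __post_init__(self) -> None:
        if self.window_type is not None and not isinstance(self.window_type, WindowType):
            object.__setattr__(self, "window_type", WindowType(self.window_type))


@dataclass(frozen=True)
class InstrumentDefinition:
    """A validated segmented-day instrument.

    Invariants (enforced at construction): 15 items in the 3 declared
    sections, unique item ids, exactly 5 items linked to school windows
    and 5 to out-of-school windows; sedentary items carry no window link.
    """

    items: tuple[ItemDef, ...]
    sections: tuple[str, ...] = DEFAULT_SECTIONS
    scale_min: int = 1
    scale_max: int = 5

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple(self.items))
        object.__setattr__(self, "sections", tuple(self.sections))
        self._validate()

    def _validate(self) -> None:
        if self.scale_min >= self.scale_max:
            raise InstrumentError("scale_min must be < scale_max")
        if len(self.sections) != 3:
            raise InstrumentError(f"expected 3 sections, got {len(self.sections)}")
        if len(self.items) != 15:
            raise InstrumentError(f"expected 15 items, got {len(self.items)}")
        ids = [it.item_id for it in self.items]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise InstrumentError(f"duplicate item ids: {sorted(dupes)}")
        for it in self.items:
            if it.section not in self.sections:
                raise InstrumentError(
                    f"item {it.item_id!r}: unknown section {it.section!r}"
                )
        n_school = sum(
            1 for it in self.items if it.window_type in SCHOOL_WINDOW_TYPES
        )
        n_out = sum(
            1 for it in self.items if it.window_type in OUT_OF_SCHOOL_WINDOW_TYPES
        )
        if n_school != 5:
            raise InstrumentError(
                f"expected 5 items linked to school windows, got {n_school}"
            )
        if n_out != 5:
            raise InstrumentError(
                f"expected 5 items linked to out-of-school windows, got {n_out}"
            )

    # -- lookups ---------------------------------------------------------
    def item(self, item_id: str) -> ItemDef:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(item_id)

    @property
    def activity_items(self) -> tuple[ItemDef, ...]:
        """Items with a window link (the ones that get calibrated)."""
        return tuple(it for it in self.items if it.window_type is not None)

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(it.item_id for it in self.items)

    def items_in_section(self, section: str) -> tuple[ItemDef, ...]:
        return tuple(it for it in self.items if it.section == section)

    def window_for_item(self, item_id: str) -> WindowType | None:
        return self.item(item_id).window_type


@dataclass
class ResponseSet:
    """One participant's responses; missing answers are explicit ``None``."""

    participant_id: str
    responses: dict[str, int | None]
    administration_date: str | None = None

    def validate(self, instrument: InstrumentDefinition) -> None:
        for item_id, score in self.responses.items():
            if item_id not in instrument.item_ids:
                raise InstrumentError(
                    f"{self.participant_id}: response for unknown item {item_id!r}"
                )
            if score is None:
                continue
            if not instrument.scale_min <= score <= instrument.scale_max:
                raise InstrumentError(
                    f"{self.participant_id}: item {item_id!r} score {score} outside "
                    f"[{instrument.scale_min}, {instrument.scale_max}]"
                )


@dataclass
class SectionScores:
    """Raw composite scores: mean of a section's non-missing items.

    ``scores[section]`` is ``None`` when every item of the section is
    missing; ``low_coverage`` lists sections where fewer than half of the
    items were answered (scored anyway, flagged for the analyst).
    """

    participant_id: str
    scores: dict[str, float | None] = field(default_factory=dict)
    low_coverage: set[str] = field(default_factory=set)


def default_instrument() -> InstrumentDefinition:
    """The bundled 15-item segmented-day instrument (placeholder prompts)."""
    w = WindowType
    items = [
        ItemDef("act_transport_to_school", SECTION_SCHOOL, w.TRANSPORT_TO_SCHOOL,
                "Activity while travelling to school last week"),
        ItemDef("act_recess", SECTION_SCHOOL, w.RECESS,
                "Activity during recess last week"),
        ItemDef("act_pe", SECTION_SCHOOL, w.PHYSICAL_EDUCATION,
                "Activity during physical education class last week"),
        ItemDef("act_lunch", SECTION_SCHOOL, w.LUNCH,
                "Activity during lunch break last week"),
        ItemDef("act_transport_from_school", SECTION_SCHOOL, w.TRANSPORT_FROM_SCHOOL,
                "Activity while travelling home from school last week"),
        ItemDef("act_before_school", SECTION_OUT, w.BEFORE_SCHOOL,
                "Activity before school last week"),
        ItemDef("act_after_school", SECTION_OUT, w.AFTER_SCHOOL,
                "Activity after school last week"),
        ItemDef("act_evening", SECTION_OUT, w.EVENING,
                "Activity during the evening last week"),
        ItemDef("act_saturday", SECTION_OUT, w.SATURDAY,
                "Activity last Saturday"),
        ItemDef("act_sunday", SECTION_OUT, w.SUNDAY,
                "Activity last Sunday"),
        ItemDef("sed_tv", SECTION_SEDENTARY, None,
                "Time spent watching TV last week"),
        ItemDef("sed_video_games", SECTION_SEDENTARY, None,
                "Time spent playing video games last week"),
        ItemDef("sed_computer", SECTION_SEDENTARY, None,
                "Time spent using a computer or phone last week"),
        ItemDef("sed_sitting_friends", SECTION_SEDENTARY, None,
                "Time spent sitting around with friends last week"),
        ItemDef("sed_overall", SECTION_SEDENTARY, None,
                "Overall sedentary time last week"),
    ]
    return InstrumentDefinition(items=tuple(items))


def load_instrument(path) -> InstrumentDefinition:
    """Load an instrument definition from a YAML config file.

    Expected layout::

        scale_min: 1
        scale_max: 5
        sections: [activity_at_school, activity_out_of_school, sedentary]
        items:
          - item_id: act_recess
            section: activity_at_school
            window_type: recess      # omit for sedentary items
            prompt: "..."
    """
    with open(path, "r", encoding="utf-8") as fh:
        try:
            raw = yaml.safe_load(fh)
        except yaml.YAMLError as exc:  # pragma: no cover - yaml details vary
            mark = getattr(exc, "problem_mark", None)
            line = f" at line {mark.line + 1}" if mark is not None else ""
            raise InstrumentError(f"malformed instrument file {path}{line}: {exc}")
    if not isinstance(raw, dict) or "items" not in raw:
        raise InstrumentError(f"instrument file {path} lacks an 'items' list")
    items = []
    for i, entry in enumerate(raw["items"]):
        try:
            wt = entry.get("window_type")
            items.append(
                ItemDef(
                    item_id=str(entry["item_id"]),
                    section=str(entry["section"]),
                    window_type=WindowType(wt) if wt else None,
                    prompt=str(entry.get("prompt", "")),
                )
            )
        except (KeyError, ValueError) as exc:
            raise InstrumentError(f"instrument item #{i + 1} invalid: {exc}") from exc
    return InstrumentDefinition(
        items=tuple(items),
        sections=tuple(raw.get("sections", DEFAULT_SECTIONS)),
        scale_min=int(raw.get("scale_min", 1)),
        scale_max=int(raw.get("scale_max", 5)),
    )


def save_instrument(instrument: InstrumentDefinition, path) -> None:
    doc = {
        "scale_min": instrument.scale_min,
        "scale_max": instrument.scale_max,
        "sections": list(instrument.sections),
        "items": [
            {
                "item_id": it.item_id,
                "section": it.section,
                **({"window_type": it.window_type.value} if it.window_type else {}),
                "prompt": it.prompt,
            }
            for it in instrument.items
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def score_sections(
    instrument: InstrumentDefinition, responses: ResponseSet
) -> SectionScores:
    """Raw composite score per section: mean of non-missing item scores.

    A section with every item missing scores ``None`` (never zero).
    Sections with fewer than half their items answered are scored from
    the available items but flagged in ``low_coverage``.
    """
    responses.validate(instrument)
    out = SectionScores(participant_id=responses.participant_id)
    for section in instrument.sections:
        items = instrument.items_in_section(section)
        values = [
            responses.responses.get(it.item_id)
            for it in items
            if responses.responses.get(it.item_id) is not None
        ]
        if not values:
            out.scores[section] = None
            out.low_coverage.add(section)
            continue
        out.scores[section] = float(sum(values)) / len(values)
        if len(values) < 0.5 * len(items):
            out.low_coverage.add(section)
    return out
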