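"""Pattern search, event comparison and element-frequency banding.

Queries mirror how an analyst interrogates the screening matrix: metadata
drop-down filters (crop, stack type, authorization status), AND/OR searches
over required element states, side-by-side comparison of two events (or an
event and a hypothetical element combination), and per-element occurrence
frequencies with the four-colour banding used to flag common screening
targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

from .model import (
    EU_STATUSES,
    EVENT_TYPES,
    GmoEvent,
    ScreeningMatrix,
    TriState,
)


class QueryError(Exception):
    """A query refers to an unknown element or metadata value."""


UNKNOWN_POLICIES = ("strict", "permissive", "flagged")


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero (116/126 -> 92%)."""
    return int(x + 0.5) if x >= 0 else -int(-x + 0.5)


class FrequencyBand(Enum):
    """Colour band for an element's occurrence frequency (integer percent)."""

    RED = "red"            # >= 30%
    ORANGE = "orange"      # 10-29%
    YELLOW = "yellow"      # 5-9%
    PALE_YELLOW = "pale_yellow"  # 2-4%
    NONE = "none"          # 0-1%


def frequency_band(percent: int) -> FrequencyBand:
    """Band an integer percentage; bands partition 0..100.

    The published colour code overlaps at exactly 2% (pale yellow spans
    "4% to 2%", uncoloured is "<= 2%"); the partition here gives 2% to pale
    yellow, the more informative colour.
    """
    if not 0 <= percent <= 100:
        raise QueryError(f"percent {percent} outside 0..100")
    if percent >= 30:
        return FrequencyBand.RED
    if percent >= 10:
        return FrequencyBand.ORANGE
    if percent >= 5:
        return FrequencyBand.YELLOW
    if percent >= 2:
        return FrequencyBand.PALE_YELLOW
    return FrequencyBand.NONE


@dataclass(frozen=True)
class MetadataFilters:
    """Conjunctive constraints on the five metadata columns."""

    crop_species: str | None = None
    event_type: str | None = None
    eu_status: str | None = None
    trade_name: str | None = None
    unique_id: str | None = None

    def is_empty(self) -> bool:
        return all(
            v is None
            for v in (self.crop_species, self.event_type, self.eu_status,
                      self.trade_name, self.unique_id)
        )


@dataclass(frozen=True)
class PatternQuery:
    """Element-state requirements: AND within a line, OR across lines.

    Each line maps canonical element names to a required state
    (:attr:`TriState.PRESENT` or :attr:`TriState.ABSENT`).  An event matches
    the query when it satisfies at least one line and all metadata filters.
    """

    lines: tuple[Mapping[str, TriState], ...] = ()
    metadata: MetadataFilters = field(default_factory=MetadataFilters)

    def __post_init__(self) -> None:
        for line in self.lines:
            for el, state in line.items():
                if state not in (TriState.PRESENT, TriState.ABSENT):
                    raise QueryError(
                        f"line requirement for {el!r} must be present or absent"
                    )


def filter_events(matrix: ScreeningMatrix,
                  filters: MetadataFilters | None = None,
                  **criteria: str) -> list[GmoEvent]:
    """Events satisfying every metadata criterion, in matrix order.

    Criteria may be passed as a :class:`MetadataFilters` or as keyword
    arguments (``crop_species=``, ``event_type=``, ``eu_status=``,
    ``trade_name=``, ``unique_id=``).
    """
    if filters is None:
        filters = MetadataFilters(**criteria)
    elif criteria:
        raise TypeError("pass either a MetadataFilters or keyword criteria, not both")
    if filters.event_type is not None and filters.event_type not in EVENT_TYPES:
        raise QueryError(
            f"unknown event_type {filters.event_type!r}; admissible: {', '.join(EVENT_TYPES)}"
        )
    if filters.eu_status is not None and filters.eu_status not in EU_STATUSES:
        raise QueryError(
            f"unknown eu_status {filters.eu_status!r}; admissible: {', '.join(EU_STATUSES)}"
        )
    if filters.crop_species is not None:
        crops = matrix.crops()
        if filters.crop_species not in crops:
            raise QueryError(
                f"unknown crop {filters.crop_species!r}; admissible: {', '.join(sorted(crops))}"
            )
    out = []
    for ev in matrix.events:
        if filters.crop_species is not None and ev.crop_species != filters.crop_species:
            continue
        if filters.event_type is not None and ev.event_type != filters.event_type:
            continue
        if filters.eu_status is not None and ev.eu_status != filters.eu_status:
            continue
        if filters.trade_name is not None and ev.trade_name != filters.trade_name:
            continue
        if filters.unique_id is not None and ev.unique_id != filters.unique_id:
            continue
        out.append(ev)
    return out


def _requirement_met(cell: TriState, required: TriState, policy: str) -> tuple[bool, bool]:
    """(satisfied, via_unknown) for one element requirement under a policy."""
    if cell is required:
        return True, False
    if cell is TriState.UNKNOWN:
        if policy == "strict":
            return False, False
        return True, True  # permissive and flagged both let unknowns satisfy
    return False, False


@dataclass
class MatchResult:
    """Events matching a pattern query, with unknown-cell annotations."""

    events: list[GmoEvent]
    #: event label -> elements whose unknown cells were needed for the match
    unknown_flags: dict[str, tuple[str, ...]]


def match_pattern(matrix: ScreeningMatrix, query: PatternQuery,
                  unknown_policy: str = "strict") -> MatchResult:
    """AND/OR pattern search over the matrix.

    A line is satisfied when every required-present element is present and
    every required-absent element is absent in the event's profile.  Unknown
    cells fail requirements under ``strict``, satisfy them under
    ``permissive``, and satisfy them with a per-event annotation under
    ``flagged``.
    """
    if unknown_policy not in UNKNOWN_POLICIES:
        raise QueryError(f"unknown policy {unknown_policy!r}; admissible: {UNKNOWN_POLICIES}")
    vocab = set(matrix.element_names())
    for line in query.lines:
        missing = sorted(set(line) - vocab)
        if missing:
            raise QueryError(f"element(s) not in matrix vocabulary: {', '.join(missing)}")

    candidates = filter_events(matrix, query.metadata)
    if not query.lines:
        return MatchResult(events=candidates, unknown_flags={})

    matched: list[GmoEvent] = []
    flags: dict[str, tuple[str, ...]] = {}
    for ev in candidates:
        best_unknowns: tuple[str, ...] | None = None
        for line in query.lines:
            unknowns: list[str] = []
            ok = True
            for el, required in line.items():
                satisfied, via_unknown = _requirement_met(ev.state(el), required, unknown_policy)
                if not satisfied:
                    ok = False
                    break
                if via_unknown:
                    unknowns.append(el)
            if ok:
                u = tuple(sorted(unknowns))
                # prefer a line that needs no unknown cells
                if best_unknowns is None or len(u) < len(best_unknowns):
                    best_unknowns = u
                if not u:
                    break
        if best_unknowns is not None:
            matched.append(ev)
            if unknown_policy == "flagged" and best_unknowns:
                flags[ev.label()] = best_unknowns
    return MatchResult(events=matched, unknown_flags=flags)


@dataclass(frozen=True)
class ComparisonRecord:
    """Element-wise comparison of two profiles (events or query lines)."""

    shared_present: frozenset[str]
    only_a: frozenset[str]
    only_b: frozenset[str]
    unknown_involved: frozenset[str]


ProfileLike = "GmoEvent | str | Mapping[str, TriState]"


def _resolve_profile(matrix: ScreeningMatrix, side) -> Mapping[str, TriState]:
    if isinstance(side, GmoEvent):
        return side.profile
    if isinstance(side, str):
        try:
            return matrix.find_event(side).profile
        except KeyError as exc:
            raise QueryError(str(exc)) from None
    if isinstance(side, Mapping):
        # a query line: required-present reads as present, required-absent as absent
        return side
    raise QueryError(f"cannot resolve {side!r} to an event or element combination")


def compare_events(matrix: ScreeningMatrix, a, b) -> ComparisonRecord:
    """Compare two events, or an event against an element combination.

    Over every element where at least one side is present or unknown:
    ``shared_present`` (both present), ``only_a`` / ``only_b`` (present on
    one side, absent on the other), ``unknown_involved`` (at least one side
    unknown).
    """
    pa = _resolve_profile(matrix, a)
    pb = _resolve_profile(matrix, b)
    shared, only_a, only_b, unknown = set(), set(), set(), set()
    for name in matrix.element_names():
        sa = pa.get(name, TriState.UNKNOWN)
        sb = pb.get(name, TriState.UNKNOWN)
        if sa is TriState.ABSENT and sb is TriState.ABSENT:
            continue
        if sa is TriState.UNKNOWN and sb is TriState.UNKNOWN:
            continue
        if TriState.UNKNOWN in (sa, sb):
            unknown.add(name)
        elif sa is TriState.PRESENT and sb is TriState.PRESENT:
            shared.add(name)
        elif sa is TriState.PRESENT:
            only_a.add(name)
        else:
            only_b.add(name)
    return ComparisonRecord(
        shared_present=frozenset(shared),
        only_a=frozenset(only_a),
        only_b=frozenset(only_b),
        unknown_involved=frozenset(unknown),
    )


@dataclass(frozen=True)
class FrequencyRecord:
    """Occurrence frequency of one element over an event subset."""

    element: str
    n_present: int
    n_unknown: int
    n_total: int
    percent: int
    band: FrequencyBand


def element_frequencies(matrix: ScreeningMatrix,
                        subset: Sequence[GmoEvent] | None = None,
                        hide_zero: bool = False) -> dict[str, FrequencyRecord]:
    """Per-element occurrence frequency over ``subset`` (default: all events).

    The denominator is the whole subset — unknown cells count in ``n_total``
    but not in ``n_present`` — and ``percent`` is rounded half away from
    zero before banding.  An empty subset yields an empty report (no
    division by zero).  ``hide_zero`` drops 0% rows, mirroring the
    presentation toggle of the original spreadsheet tool.
    """
    events = list(matrix.events) if subset is None else list(subset)
    if not events:
        return {}
    out: dict[str, FrequencyRecord] = {}
    for name in matrix.element_names():
        n_present = sum(1 for ev in events if ev.state(name) is TriState.PRESENT)
        n_unknown = sum(1 for ev in events if ev.state(name) is TriState.UNKNOWN)
        percent = round_half_away(100.0 * n_present / len(events))
        if hide_zero and percent == 0:
            continue
        out[name] = FrequencyRecord(
            element=name,
            n_present=n_present,
            n_unknown=n_unknown,
            n_total=len(events),
            percent=percent,
            band=frequency_band(percent),
        )
    return out
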