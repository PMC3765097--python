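"""Screening-panel design: coverage, greedy selection, discrimination, gaps.

A screening panel is an ordered list of target groups; elements within a
group are interchangeable alternatives (an event detected by any member is
detected by the group).  Coverage is detection semantics: an event counts as
covered when at least one panel element is present in its profile.
Identification of *which* event produced a screening pattern is the job of
the interpretation module.

Panel construction is greedy marginal-coverage maximization with a
deterministic tie-break; an exhaustive optimizer over all k-subsets is
provided for small instances (it is the testing oracle for the greedy
heuristic, and usable directly on desk-scale problems).  Second-round target
choice ranks elements by discriminating power: how many unordered pairs of
shortlisted candidate events an element separates.

Endogenous (species) targets are excluded from panel candidates by default:
they detect the plant, not the modification.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

from .model import GM_SECTIONS, GmoEvent, ScreeningMatrix, TriState
from .query import QueryError, element_frequencies, round_half_away


class DesignError(Exception):
    """Panel or candidate-set error in screening design."""


@dataclass(frozen=True)
class Panel:
    """Ordered groups of alternative screening targets (OR within a group)."""

    groups: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        for g in self.groups:
            if not g:
                raise DesignError("panel group must be non-empty")

    @classmethod
    def from_elements(cls, elements: Iterable[str]) -> "Panel":
        """One singleton group per element."""
        return cls(tuple(frozenset([e]) for e in elements))

    @classmethod
    def parse(cls, text: str) -> "Panel":
        """Parse ``"p35S,tNOS,pTa29|pSsuAra"`` (comma: groups, pipe: alternatives)."""
        groups = []
        for chunk in text.split(","):
            members = frozenset(m.strip() for m in chunk.split("|") if m.strip())
            if members:
                groups.append(members)
        return cls(tuple(groups))

    def all_elements(self) -> frozenset[str]:
        out: set[str] = set()
        for g in self.groups:
            out |= g
        return frozenset(out)


@dataclass(frozen=True)
class CoverageResult:
    """Events detected by a panel over a subset, with the printed-style percent."""

    covered: tuple[GmoEvent, ...]
    uncovered: tuple[GmoEvent, ...]
    n_covered: int
    n_total: int
    percent: int

    def fraction_label(self) -> str:
        return f"{self.n_covered}/{self.n_total} - {self.percent}%"


def _check_vocabulary(matrix: ScreeningMatrix, elements: Iterable[str]) -> None:
    vocab = set(matrix.element_names())
    missing = sorted(set(elements) - vocab)
    if missing:
        raise QueryError(f"element(s) not in matrix vocabulary: {', '.join(missing)}")


def _detects(event: GmoEvent, elements: Iterable[str], unknown_policy: str) -> bool:
    for el in elements:
        state = event.state(el)
        if state is TriState.PRESENT:
            return True
        if state is TriState.UNKNOWN and unknown_policy == "permissive":
            return True
    return False


def coverage(matrix: ScreeningMatrix, panel: Panel,
             subset: Sequence[GmoEvent] | None = None,
             unknown_policy: str = "strict") -> CoverageResult:
    """Fraction of ``subset`` detectable by at least one panel element.

    Unknown cells never count as detection under the default ``strict``
    policy (conservative: no over-claiming); ``permissive`` counts them.
    Percent is rounded half away from zero, matching the convention of the
    printed coverage figures (116/126 -> 92%).
    """
    events = list(matrix.events) if subset is None else list(subset)
    _check_vocabulary(matrix, panel.all_elements())
    elements = panel.all_elements()
    covered = tuple(ev for ev in events if _detects(ev, elements, unknown_policy))
    uncovered = tuple(ev for ev in events if not _detects(ev, elements, unknown_policy))
    n_total = len(events)
    percent = round_half_away(100.0 * len(covered) / n_total) if n_total else 0
    return CoverageResult(
        covered=covered, uncovered=uncovered,
        n_covered=len(covered), n_total=n_total, percent=percent,
    )


def default_candidates(matrix: ScreeningMatrix, include_endogenous: bool = False) -> list[str]:
    """GM-section elements (optionally plus endogenous) in matrix order."""
    sections = set(GM_SECTIONS) | ({"endogenous"} if include_endogenous else set())
    return [e.canonical_name for e in matrix.elements if e.section in sections]


@dataclass
class GreedyTrace:
    """Per-step record of greedy panel growth."""

    element: str
    n_covered: int
    percent: int


def greedy_panel(matrix: ScreeningMatrix,
                 subset: Sequence[GmoEvent] | None = None,
                 candidates: Sequence[str] | None = None,
                 max_groups: int = 5,
                 mandatory: Sequence[str] = (),
                 unknown_policy: str = "strict") -> tuple[Panel, list[GreedyTrace]]:
    """Greedy maximum-coverage panel of at most ``max_groups`` targets.

    Starts from the ``mandatory`` elements, then repeatedly adds the
    candidate with the largest marginal coverage until the budget is spent
    or every reachable event is covered.  Ties break by higher global
    frequency in the subset, then lexicographically — the output is fully
    deterministic.  The trace records cumulative coverage after each pick
    and is non-decreasing.
    """
    events = list(matrix.events) if subset is None else list(subset)
    if candidates is None:
        candidates = default_candidates(matrix)
    _check_vocabulary(matrix, candidates)
    _check_vocabulary(matrix, mandatory)
    if max_groups < len(mandatory):
        raise DesignError(f"max_groups={max_groups} smaller than |mandatory|={len(mandatory)}")

    freqs = element_frequencies(matrix, events) if events else {}

    def freq_of(el: str) -> int:
        rec = freqs.get(el)
        return rec.n_present if rec else 0

    chosen: list[str] = []
    covered: set[int] = set()
    trace: list[GreedyTrace] = []
    n_total = len(events)

    def record(el: str) -> None:
        for i, ev in enumerate(events):
            if i not in covered and _detects(ev, [el], unknown_policy):
                covered.add(i)
        percent = round_half_away(100.0 * len(covered) / n_total) if n_total else 0
        trace.append(GreedyTrace(element=el, n_covered=len(covered), percent=percent))

    for el in mandatory:
        chosen.append(el)
        record(el)

    pool = [c for c in candidates if c not in chosen]
    while len(chosen) < max_groups and len(covered) < n_total:
        best: tuple[int, int, str] | None = None
        best_el: str | None = None
        for el in pool:
            gain = sum(
                1 for i, ev in enumerate(events)
                if i not in covered and _detects(ev, [el], unknown_policy)
            )
            key = (gain, freq_of(el), _NegStr(el))
            if best is None or key > best:
                best = key
                best_el = el
        if best is None or best[0] == 0:
            break  # saturation: nothing left to gain
        assert best_el is not None
        chosen.append(best_el)
        pool.remove(best_el)
        record(best_el)

    return Panel.from_elements(chosen), trace


class _NegStr(str):
    """String ordered in reverse, so max() prefers the lexicographically first."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


BRUTE_FORCE_GUARD = 200_000


def brute_force_optimal_panel(matrix: ScreeningMatrix,
                              subset: Sequence[GmoEvent] | None = None,
                              candidates: Sequence[str] | None = None,
                              k: int = 3,
                              unknown_policy: str = "strict") -> tuple[list[Panel], int]:
    """Exact maximum-coverage k-subset(s) of candidates, by enumeration.

    Returns every optimal panel in lexicographic order plus the optimal
    covered-event count.  Guarded to instances with at most
    ``BRUTE_FORCE_GUARD`` combinations.
    """
    events = list(matrix.events) if subset is None else list(subset)
    if candidates is None:
        candidates = default_candidates(matrix)
    _check_vocabulary(matrix, candidates)
    cands = sorted(set(candidates))
    k = min(k, len(cands))
    from math import comb
    if comb(len(cands), k) > BRUTE_FORCE_GUARD:
        raise DesignError(
            f"instance too large: C({len(cands)}, {k}) exceeds {BRUTE_FORCE_GUARD}"
        )
    # bitmask per candidate of the events it detects
    masks = {}
    for el in cands:
        m = 0
        for i, ev in enumerate(events):
            if _detects(ev, [el], unknown_policy):
                m |= 1 << i
        masks[el] = m
    best_count = -1
    best_sets: list[tuple[str, ...]] = []
    for combo in combinations(cands, k):
        m = 0
        for el in combo:
            m |= masks[el]
        n = m.bit_count()
        if n > best_count:
            best_count = n
            best_sets = [combo]
        elif n == best_count:
            best_sets.append(combo)
    if best_count < 0:
        best_count = 0
        best_sets = [()]
    return [Panel.from_elements(c) for c in best_sets], best_count


def discriminating_power(matrix: ScreeningMatrix, element: str,
                         candidate_events: Sequence[GmoEvent]) -> int:
    """Unordered candidate pairs separated by ``element``.

    A pair is distinguished when the element is present in exactly one of
    the two events; unknown cells distinguish nothing.  With fewer than two
    candidates the power is zero by definition.
    """
    _check_vocabulary(matrix, [element])
    if len(candidate_events) < 2:
        return 0
    n_present = sum(1 for ev in candidate_events if ev.state(element) is TriState.PRESENT)
    n_absent = sum(1 for ev in candidate_events if ev.state(element) is TriState.ABSENT)
    return n_present * n_absent


def second_round_select(matrix: ScreeningMatrix,
                        candidate_events: Sequence[GmoEvent],
                        candidates: Sequence[str] | None = None,
                        max_targets: int = 3) -> list[tuple[str, int]]:
    """Greedy second-round target choice by newly distinguished pairs.

    After a first screening shortlists candidate events, each further assay
    is chosen to split as many still-confounded pairs as possible.  Returns
    (element, newly distinguished pairs) per pick; stops when every pair
    separable by some candidate element is separated.
    """
    if candidates is None:
        candidates = default_candidates(matrix)
    _check_vocabulary(matrix, candidates)
    events = list(candidate_events)
    pairs = list(combinations(range(len(events)), 2))
    undistinguished = set(pairs)
    picks: list[tuple[str, int]] = []
    pool = sorted(set(candidates))
    while pool and undistinguished and len(picks) < max_targets:
        best_el, best_gain, best_split = None, 0, None
        for el in pool:
            split = {
                (i, j) for (i, j) in undistinguished
                if (events[i].state(el), events[j].state(el))
                in ((TriState.PRESENT, TriState.ABSENT), (TriState.ABSENT, TriState.PRESENT))
            }
            if len(split) > best_gain:
                best_el, best_gain, best_split = el, len(split), split
        if best_el is None:
            break
        picks.append((best_el, best_gain))
        pool.remove(best_el)
        assert best_split is not None
        undistinguished -= best_split
    return picks


@dataclass
class GapReport:
    """Detection gaps: events no available assay reaches, and unassayed elements."""

    undetectable_events: list[GmoEvent]
    #: (element, n_present in subset) for elements lacking an assay,
    #: most frequent first
    elements_without_assay: list[tuple[str, int]]


def gap_analysis(matrix: ScreeningMatrix,
                 subset: Sequence[GmoEvent] | None = None,
                 include_endogenous: bool = False) -> GapReport:
    """Find events not detectable by any assay-available GM element.

    Elements whose descriptor carries ``assay_available=False`` are treated
    as unusable for detection; ``None`` counts as available.  Also ranks the
    unassayed elements by how many subset events carry them, flagging the
    high-value targets for new assay development.
    """
    events = list(matrix.events) if subset is None else list(subset)
    names = default_candidates(matrix, include_endogenous=include_endogenous)
    available = [n for n in names if matrix.element(n).assay_available is not False]
    unavailable = [n for n in names if matrix.element(n).assay_available is False]
    undetectable = [ev for ev in events if not _detects(ev, available, "strict")]
    missing_ranked = sorted(
        (
            (el, sum(1 for ev in events if ev.state(el) is TriState.PRESENT))
            for el in unavailable
        ),
        key=lambda t: (-t[1], t[0]),
    )
    return GapReport(undetectable_events=undetectable, elements_without_assay=missing_ranked)
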