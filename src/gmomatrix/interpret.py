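"""Interpretation of observed screening patterns against the matrix.

After a first qPCR screening round, the analyst has a pattern of
positive/negative results over the tested elements.  Three questions follow:

* which single events are consistent with the pattern (``explain_single``);
* failing that, which *minimal mixtures* of events jointly produce the
  positives while none carries a tested-negative element
  (``explain_mixture`` — the pattern is split into complementary
  sub-patterns, one per mixture member);
* if nothing fits, why: a mixture beyond the search depth, a trace-level
  event whose weaker targets stayed below the detection limit, or a GMO not
  listed in the matrix at all (``diagnose_no_match``).

Negatives constrain every member of a candidate mixture: an element that is
truly present should have fired its screening assay, so an event carrying a
tested-negative element is excluded from candidacy.  Limit-of-detection
caveats are surfaced by the diagnosis instead of by relaxing the logic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from itertools import combinations
from math import comb
from typing import Iterable, Mapping, Sequence

from .model import GmoEvent, ScreeningMatrix, TriState
from .query import QueryError, element_frequencies


class InterpretationError(Exception):
    """Contradictory pattern or invalid interpretation request."""


class ObsState(Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    UNTESTED = "untested"


@dataclass(frozen=True)
class ObservedPattern:
    """Screening outcome per tested element; untested elements unconstrained."""

    results: Mapping[str, ObsState]

    @classmethod
    def from_calls(cls, positives: Iterable[str] = (), negatives: Iterable[str] = (),
                   untested: Iterable[str] = ()) -> "ObservedPattern":
        pos, neg = set(positives), set(negatives)
        both = pos & neg
        if both:
            raise InterpretationError(
                f"element(s) both positive and negative: {', '.join(sorted(both))}"
            )
        results: dict[str, ObsState] = {}
        for el in sorted(pos):
            results[el] = ObsState.POSITIVE
        for el in sorted(neg):
            results[el] = ObsState.NEGATIVE
        for el in sorted(set(untested) - pos - neg):
            results[el] = ObsState.UNTESTED
        return cls(results)

    @property
    def positives(self) -> frozenset[str]:
        return frozenset(e for e, s in self.results.items() if s is ObsState.POSITIVE)

    @property
    def negatives(self) -> frozenset[str]:
        return frozenset(e for e, s in self.results.items() if s is ObsState.NEGATIVE)


UNKNOWN_POLICIES = ("default", "strict", "permissive")


def _check_pattern(matrix: ScreeningMatrix, pattern: ObservedPattern) -> None:
    vocab = set(matrix.element_names())
    missing = sorted(set(pattern.results) - vocab)
    if missing:
        raise QueryError(f"element(s) not in matrix vocabulary: {', '.join(missing)}")


def _covers_positive(event: GmoEvent, element: str, policy: str) -> bool:
    state = event.state(element)
    if state is TriState.PRESENT:
        return True
    # an unknown cell is no evidence the event carries the element
    return state is TriState.UNKNOWN and policy == "permissive"


def _violates_negative(event: GmoEvent, element: str, policy: str) -> tuple[bool, bool]:
    """(violates, annotate): does a tested-negative element exclude the event?"""
    state = event.state(element)
    if state is TriState.PRESENT:
        return True, False
    if state is TriState.UNKNOWN:
        if policy == "strict":
            return True, False
        return False, policy == "default"  # keep the event, note the caveat
    return False, False


def explain_single(matrix: ScreeningMatrix, pattern: ObservedPattern,
                   unknown_policy: str = "default") -> list[GmoEvent]:
    """Events individually consistent with the whole observed pattern.

    Consistent: every observed positive is present and every observed
    negative is absent in the event's profile.  Under the ``default``
    policy an unknown cell neither claims a positive nor excludes on a
    negative; ``strict`` lets unknowns fail both; ``permissive`` lets them
    satisfy both.
    """
    if unknown_policy not in UNKNOWN_POLICIES:
        raise InterpretationError(f"unknown policy {unknown_policy!r}")
    _check_pattern(matrix, pattern)
    out = []
    for ev in matrix.events:
        if all(_covers_positive(ev, el, unknown_policy) for el in pattern.positives) and not any(
            _violates_negative(ev, el, unknown_policy)[0] for el in pattern.negatives
        ):
            out.append(ev)
    return out


@dataclass(frozen=True)
class Explanation:
    """A minimal event set whose union of present elements covers the positives."""

    events: tuple[GmoEvent, ...]
    annotations: tuple[str, ...] = ()

    @property
    def cardinality(self) -> int:
        return len(self.events)

    def labels(self) -> tuple[str, ...]:
        return tuple(sorted(ev.label() for ev in self.events))


@dataclass
class Diagnosis:
    """Why a pattern has no single-event match, by the three classic reasons."""

    #: reason 1 — every positive is carried by some candidate, but no single
    #: event carries them all: a mixture of products is plausible
    mixture_plausible: bool
    #: positives -> candidate events able to contribute them
    positive_candidates: dict[str, tuple[str, ...]]
    #: reason 2 — events consistent after dropping one tested negative
    #: (negative element -> near-miss event labels); a trace-level event whose
    #: weaker assay stayed under its detection limit could look like this
    near_misses: dict[str, tuple[str, ...]]
    #: reason 3 — positives present in no event profile: an unlisted/unknown GMO
    unexplainable_positives: tuple[str, ...]
    recommendation: str = ""


@dataclass
class MixtureResult:
    """Outcome of mixture search: minimal explanations, or a diagnosis."""

    explanations: list[Explanation]
    exhaustive: bool
    diagnosis: Diagnosis | None = None


def _mixture_candidates(matrix: ScreeningMatrix, pattern: ObservedPattern,
                        unknown_policy: str) -> tuple[list[GmoEvent], list[str]]:
    """Events eligible for mixture membership, with unknown-cell annotations."""
    candidates: list[GmoEvent] = []
    notes: list[str] = []
    for ev in matrix.events:
        violated = False
        for el in pattern.negatives:
            v, annotate = _violates_negative(ev, el, unknown_policy)
            if v:
                violated = True
                break
            if annotate:
                notes.append(f"{ev.label()}: cell for tested-negative {el} is unknown")
        if violated:
            continue
        if any(_covers_positive(ev, el, unknown_policy) for el in pattern.positives):
            candidates.append(ev)
    return candidates, notes


def explain_mixture(matrix: ScreeningMatrix, pattern: ObservedPattern,
                    max_events: int = 3, unknown_policy: str = "default",
                    enumeration_limit: int = 10 ** 6) -> MixtureResult:
    """Minimal event sets of size <= ``max_events`` explaining the pattern.

    Exhaustive by increasing cardinality while the subset count stays within
    ``enumeration_limit``; beyond that a greedy cover is returned with
    ``exhaustive=False``.  With ``max_events=1`` the result coincides with
    :func:`explain_single`.  An empty result carries the no-match diagnosis.
    """
    if max_events < 1:
        raise InterpretationError("max_events must be >= 1")
    if unknown_policy not in UNKNOWN_POLICIES:
        raise InterpretationError(f"unknown policy {unknown_policy!r}")
    _check_pattern(matrix, pattern)
    positives = pattern.positives
    if not positives:
        # nothing to cover: single consistent events are the explanations
        singles = explain_single(matrix, pattern, unknown_policy)
        return MixtureResult(
            explanations=[Explanation(events=(ev,)) for ev in singles], exhaustive=True
        )

    candidates, notes = _mixture_candidates(matrix, pattern, unknown_policy)
    covers = {
        id(ev): frozenset(el for el in positives if _covers_positive(ev, el, unknown_policy))
        for ev in candidates
    }

    n = len(candidates)
    k = min(max_events, n)
    total_subsets = sum(comb(n, i) for i in range(1, k + 1))
    if total_subsets > enumeration_limit:
        return _greedy_mixture(candidates, covers, positives, notes, max_events, matrix, pattern)

    found: list[Explanation] = []
    found_sets: list[frozenset[int]] = []
    order = {id(ev): i for i, ev in enumerate(candidates)}
    for size in range(1, k + 1):
        for combo in combinations(candidates, size):
            idx = frozenset(order[id(ev)] for ev in combo)
            if any(prev < idx for prev in found_sets):
                continue  # a smaller explanation is a proper subset: not minimal
            union: set[str] = set()
            for ev in combo:
                union |= covers[id(ev)]
            if positives <= union:
                # minimality within the same size: every member must be needed
                if size > 1 and any(
                    positives <= frozenset().union(
                        *(covers[id(e)] for e in combo if e is not ev)
                    )
                    for ev in combo
                ):
                    continue
                found_sets.append(idx)
                found.append(Explanation(events=combo, annotations=tuple(notes)))
    if found:
        return MixtureResult(explanations=found, exhaustive=True)
    return MixtureResult(
        explanations=[], exhaustive=True, diagnosis=diagnose_no_match(matrix, pattern)
    )


def _greedy_mixture(candidates, covers, positives, notes, max_events, matrix, pattern):
    chosen: list[GmoEvent] = []
    remaining = set(positives)
    pool = list(candidates)
    while remaining and pool and len(chosen) < max_events:
        best = max(
            pool,
            key=lambda ev: (len(covers[id(ev)] & remaining), _rev(ev.label())),
        )
        if not covers[id(best)] & remaining:
            break
        chosen.append(best)
        pool.remove(best)
        remaining -= covers[id(best)]
    if remaining:
        return MixtureResult(
            explanations=[], exhaustive=False,
            diagnosis=diagnose_no_match(matrix, pattern),
        )
    # prune to a minimal set (drop members made redundant by later picks)
    pruned = list(chosen)
    for ev in list(pruned):
        rest = [e for e in pruned if e is not ev]
        if rest and positives <= frozenset().union(*(covers[id(e)] for e in rest)):
            pruned = rest
    return MixtureResult(
        explanations=[
            Explanation(events=tuple(pruned), annotations=tuple(notes) + ("non-exhaustive",))
        ],
        exhaustive=False,
    )


class _rev(str):
    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)


def rank_explanations(explanations: Sequence[Explanation],
                      matrix: ScreeningMatrix,
                      preferred_status: str | None = None) -> list[Explanation]:
    """Stable sort: fewer events, then preferred-status members, then frequency.

    Rank keys, in order: cardinality ascending; number of events carrying
    the preferred authorization status, descending; aggregate occurrence
    frequency of the explanation's present elements (matrix-wide percent
    sum), descending — common-element explanations are the likelier finds;
    finally lexicographic event labels for full determinism.
    """
    freqs = element_frequencies(matrix)

    def agg_freq(exp: Explanation) -> int:
        union: set[str] = set()
        for ev in exp.events:
            union |= ev.present_elements
        return sum(freqs[el].percent for el in union if el in freqs)

    def n_preferred(exp: Explanation) -> int:
        if preferred_status is None:
            return 0
        return sum(1 for ev in exp.events if ev.eu_status == preferred_status)

    return sorted(
        explanations,
        key=lambda e: (e.cardinality, -n_preferred(e), -agg_freq(e), e.labels()),
    )


def diagnose_no_match(matrix: ScreeningMatrix, pattern: ObservedPattern,
                      unknown_policy: str = "default") -> Diagnosis:
    """Structured reasons why no single event matches the pattern.

    Reason 1 (mixture): each positive is explainable by some candidate but
    no single event explains them jointly.  Reason 2 (low-level presence):
    some event fits once a single tested negative is ignored — a weaker
    target of a trace-level GMO may simply have missed its detection limit.
    Reason 3 (unknown GMO): a positive element occurs in no event profile;
    further investigation of the sample is recommended.
    """
    _check_pattern(matrix, pattern)
    positives = pattern.positives
    candidates, _ = _mixture_candidates(matrix, pattern, unknown_policy)

    positive_candidates: dict[str, tuple[str, ...]] = {}
    unexplainable: list[str] = []
    for el in sorted(positives):
        anywhere = any(ev.state(el) is TriState.PRESENT for ev in matrix.events)
        if not anywhere:
            unexplainable.append(el)
            continue
        carriers = tuple(
            ev.label() for ev in candidates if _covers_positive(ev, el, unknown_policy)
        )
        positive_candidates[el] = carriers
    mixture_plausible = (
        not unexplainable
        and bool(positives)
        and all(positive_candidates.get(el) for el in positive_candidates)
        and not explain_single(matrix, pattern, unknown_policy)
    )

    near_misses: dict[str, tuple[str, ...]] = {}
    for el in sorted(pattern.negatives):
        relaxed = ObservedPattern.from_calls(
            positives=positives, negatives=pattern.negatives - {el}
        )
        hits = explain_single(matrix, relaxed, unknown_policy)
        if hits:
            near_misses[el] = tuple(ev.label() for ev in hits)

    recommendation = ""
    if unexplainable:
        recommendation = (
            "positives not attributable to any listed event; suspect an unlisted or "
            "unknown GMO — further investigation (e.g. DNA walking and sequencing of "
            "the unexplained targets) is recommended"
        )
    elif mixture_plausible:
        recommendation = "split the pattern into sub-patterns and search for event mixtures"
    elif near_misses:
        recommendation = (
            "pattern fits listed events up to single negatives; consider low-level "
            "presence and per-assay detection limits"
        )
    return Diagnosis(
        mixture_plausible=mixture_plausible,
        positive_candidates=positive_candidates,
        near_misses=near_misses,
        unexplainable_positives=tuple(unexplainable),
        recommendation=recommendation,
    )


def check_explanation(matrix: ScreeningMatrix, pattern: ObservedPattern,
                      explanation: Explanation, unknown_policy: str = "default") -> bool:
    """Independent validity check of one explanation against its pattern.

    True iff the union of the members' contributions covers every observed
    positive, no member carries a tested-negative element, and no proper
    subset of the members already suffices (minimality).
    """
    evs = explanation.events
    for ev in evs:
        if any(_violates_negative(ev, el, unknown_policy)[0] for el in pattern.negatives):
            return False

    def union_covers(members: Sequence[GmoEvent]) -> bool:
        return all(
            any(_covers_positive(ev, el, unknown_policy) for ev in members)
            for el in pattern.positives
        )

    if not union_covers(evs):
        return False
    if len(evs) > 1:
        for drop in evs:
            if union_covers([e for e in evs if e is not drop]):
                return False
    return True
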