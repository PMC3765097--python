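"""Seeded synthetic matrices and screening samples with known ground truth.

The generator emulates the statistical shape of a real screening matrix:

* an element inventory mirroring the published section proportions
  (55 promoters : 31 terminators : 103 ORFs : 47 miscellaneous :
  11 junctions, plus 28 endogenous targets), scaled by a factor;
* frequency-skewed elements — a few near-ubiquitous screening targets and a
  long tail of rare ones;
* stacked events built as exact unions of 2–3 single events of the same
  crop (no segregation loss);
* endogenous targets present in every event of their crop and absent
  elsewhere;
* sparse unknown cells obtained by masking.

Observed samples are derived from a matrix by taking the union of the true
events' present elements over the tested targets, with optional dropout
(false negatives, emulating detection-limit misses) and contamination
(false positives).  Every draw is fixed by an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .design import Panel, coverage, greedy_panel
from .interpret import ObservedPattern
from .model import (
    REFERENCE_SECTION_SIZES,
    ElementDescriptor,
    GmoEvent,
    ScreeningMatrix,
    TriState,
)
from .query import FrequencyRecord, element_frequencies, filter_events
from .query import MetadataFilters


class SynthesisError(Exception):
    """Out-of-range generator parameter."""


_SECTION_PREFIX = {
    "promoter": "pSyn",
    "terminator": "tSyn",
    "orf": "orfSyn",
    "miscellaneous": "mSyn",
    "junction": "jSyn",
    "endogenous": "endoSyn",
}


def default_element_inventory(scale: float = 0.1) -> list[ElementDescriptor]:
    """Element schema mirroring the reference section proportions.

    ``scale=1.0`` reproduces the full published sizes (55/31/103/47/11 GM
    elements plus 28 endogenous targets); smaller scales keep at least one
    element per section.
    """
    if scale <= 0:
        raise SynthesisError("scale must be positive")
    out: list[ElementDescriptor] = []
    for section, size in REFERENCE_SECTION_SIZES.items():
        n = max(1, round(size * scale))
        prefix = _SECTION_PREFIX[section]
        out.extend(
            ElementDescriptor(f"{prefix}{i:03d}", section) for i in range(1, n + 1)
        )
    return out


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic screening matrix draw."""

    n_events_per_crop: Mapping[str, int] = field(
        default_factory=lambda: {"maize": 12, "soybean": 8, "rapeseed": 6}
    )
    #: element -> target occurrence frequency among single events; elements
    #: absent from the mapping get a skewed frequency drawn from Beta(0.8, 3)
    element_frequencies: Mapping[str, float] = field(default_factory=dict)
    stacking_rate: float = 0.25
    unknown_rate: float = 0.02
    seed: int = 0
    elements: Sequence[ElementDescriptor] | None = None
    inventory_scale: float = 0.1

    def __post_init__(self) -> None:
        for el, f in self.element_frequencies.items():
            if not 0.0 <= f <= 1.0:
                raise SynthesisError(f"frequency for {el!r} outside [0, 1]: {f}")
        for name, rate in (("stacking_rate", self.stacking_rate),
                           ("unknown_rate", self.unknown_rate)):
            if not 0.0 <= rate <= 1.0:
                raise SynthesisError(f"{name} outside [0, 1]: {rate}")
        for crop, n in self.n_events_per_crop.items():
            if n < 0:
                raise SynthesisError(f"negative event count for crop {crop!r}")


def generate_matrix(spec: SyntheticSpec) -> ScreeningMatrix:
    """Draw a screening matrix; identical specs give identical matrices.

    Single events draw each GM element independently at its target
    frequency; a ``stacking_rate`` fraction of each crop's rows are stacked
    events formed as unions of 2–3 of its singles; finally GM cells are
    masked to unknown at ``unknown_rate``.
    """
    rng = np.random.default_rng(spec.seed)
    elements = list(spec.elements) if spec.elements is not None else (
        default_element_inventory(spec.inventory_scale)
    )
    gm_names = [e.canonical_name for e in elements if e.section != "endogenous"]
    endo_names = [e.canonical_name for e in elements if e.section == "endogenous"]

    freqs: dict[str, float] = {}
    for name in gm_names:
        if name in spec.element_frequencies:
            freqs[name] = float(spec.element_frequencies[name])
        else:
            freqs[name] = float(rng.beta(0.8, 3.0))

    crops = list(spec.n_events_per_crop)
    # endogenous targets assigned round-robin to crops (species markers)
    endo_of_crop: dict[str, list[str]] = {c: [] for c in crops}
    for i, name in enumerate(endo_names):
        if crops:
            endo_of_crop[crops[i % len(crops)]].append(name)

    events: list[GmoEvent] = []
    serial = 0
    for crop in crops:
        n_total = spec.n_events_per_crop[crop]
        n_stacked = int(round(spec.stacking_rate * n_total))
        n_single = n_total - n_stacked
        if n_single < 2 and n_stacked > 0:  # stacks need >= 2 parents
            n_single, n_stacked = n_total, 0
        singles: list[GmoEvent] = []
        for _ in range(n_single):
            serial += 1
            profile: dict[str, TriState] = {}
            for name in gm_names:
                profile[name] = (
                    TriState.PRESENT if rng.random() < freqs[name] else TriState.ABSENT
                )
            for name in endo_names:
                profile[name] = (
                    TriState.PRESENT if name in endo_of_crop[crop] else TriState.ABSENT
                )
            singles.append(
                GmoEvent(
                    trade_name=f"{crop}-ev{serial:03d}",
                    unique_id=f"SYN-{crop[:2].upper()}{serial:03d}-{(serial * 7) % 10}",
                    crop_species=crop,
                    event_type="single",
                    eu_status=str(rng.choice(
                        ["authorized", "not_authorized", "llp_619_2011"],
                        p=[0.45, 0.45, 0.10],
                    )),
                    profile=profile,
                )
            )
        stacks: list[GmoEvent] = []
        for _ in range(n_stacked):
            serial += 1
            n_parents = int(rng.integers(2, min(3, len(singles)) + 1))
            parents = [singles[i] for i in rng.choice(len(singles), n_parents, replace=False)]
            profile = {}
            for name in gm_names + endo_names:
                profile[name] = (
                    TriState.PRESENT
                    if any(p.state(name) is TriState.PRESENT for p in parents)
                    else TriState.ABSENT
                )
            stacks.append(
                GmoEvent(
                    trade_name=f"{crop}-stk{serial:03d}",
                    unique_id=f"SYN-{crop[:2].upper()}{serial:03d}-{(serial * 7) % 10}",
                    crop_species=crop,
                    event_type="stacked",
                    eu_status="not_authorized",
                    profile=profile,
                )
            )
        events.extend(singles + stacks)

    if spec.unknown_rate > 0:
        masked: list[GmoEvent] = []
        for ev in events:
            profile = dict(ev.profile)
            for name in gm_names:
                if rng.random() < spec.unknown_rate:
                    profile.pop(name, None)  # unknown == missing cell
            masked.append(
                GmoEvent(
                    trade_name=ev.trade_name, unique_id=ev.unique_id,
                    crop_species=ev.crop_species, event_type=ev.event_type,
                    eu_status=ev.eu_status, profile=profile,
                )
            )
        events = masked

    return ScreeningMatrix(
        elements=elements, events=events, version_tag=f"synthetic-seed{spec.seed}"
    )


@dataclass
class SyntheticSample:
    """An observed screening pattern with its generating ground truth."""

    true_events: tuple[GmoEvent, ...]
    pattern: ObservedPattern
    tested_targets: tuple[str, ...]
    dropout_prob: float
    contamination_prob: float
    seed: int


def generate_sample(matrix: ScreeningMatrix, true_events: Sequence[GmoEvent],
                    tested_targets: Sequence[str], dropout_prob: float = 0.0,
                    contamination_prob: float = 0.0, seed: int = 0) -> SyntheticSample:
    """Simulate a screening round on a product containing ``true_events``.

    Positives are the union of the true events' present elements restricted
    to the tested targets, each then lost with ``dropout_prob`` (a target
    below its detection limit); every other tested target turns positive
    with ``contamination_prob``.  Remaining tested targets are negative.
    """
    if not tested_targets:
        raise SynthesisError("tested_targets must be non-empty")
    for p, name in ((dropout_prob, "dropout_prob"), (contamination_prob, "contamination_prob")):
        if not 0.0 <= p <= 1.0:
            raise SynthesisError(f"{name} outside [0, 1]: {p}")
    labels = {ev.label() for ev in matrix.events}
    for ev in true_events:
        if ev.label() not in labels:
            raise SynthesisError(f"true event {ev.label()!r} not in matrix")
    rng = np.random.default_rng(seed)
    truth_union: set[str] = set()
    for ev in true_events:
        truth_union |= ev.present_elements
    positives: set[str] = set()
    negatives: set[str] = set()
    for el in tested_targets:
        if el in truth_union:
            if rng.random() < dropout_prob:
                negatives.add(el)
            else:
                positives.add(el)
        else:
            if rng.random() < contamination_prob:
                positives.add(el)
            else:
                negatives.add(el)
    pattern = ObservedPattern.from_calls(positives=positives, negatives=negatives)
    return SyntheticSample(
        true_events=tuple(true_events), pattern=pattern,
        tested_targets=tuple(tested_targets),
        dropout_prob=dropout_prob, contamination_prob=contamination_prob, seed=seed,
    )


@dataclass
class CropScreeningReport:
    """Per-crop view: most frequent elements plus a proposed greedy panel."""

    crop: str
    n_events: int
    top_elements: list[FrequencyRecord]
    panel: Panel
    coverage_n: int
    coverage_total: int
    coverage_percent: int

    def coverage_label(self) -> str:
        return f"{self.coverage_n}/{self.coverage_total} - {self.coverage_percent}%"


def table2_style_report(matrix: ScreeningMatrix, crop: str,
                        status_filter: str | None = None,
                        panel_size: int = 5, n_top: int = 6) -> CropScreeningReport:
    """Most frequent GM elements of a crop and a proposed screening panel.

    Combines the frequency ranking of the query engine with greedy panel
    construction, the way per-crop screening recommendations are tabulated:
    top elements by occurrence, then a panel of ``panel_size`` targets with
    its coverage of the (optionally status-filtered) crop subset.
    """
    filters = MetadataFilters(crop_species=crop, eu_status=status_filter)
    subset = filter_events(matrix, filters)
    if not subset:
        return CropScreeningReport(
            crop=crop, n_events=0, top_elements=[],
            panel=Panel(()), coverage_n=0, coverage_total=0, coverage_percent=0,
        )
    freqs = element_frequencies(matrix, subset)
    gm = {
        name: rec for name, rec in freqs.items()
        if matrix.element(name).section != "endogenous"
    }
    top = sorted(gm.values(), key=lambda r: (-r.percent, r.element))[:n_top]
    panel, _trace = greedy_panel(matrix, subset, max_groups=panel_size)
    cov = coverage(matrix, panel, subset)
    return CropScreeningReport(
        crop=crop, n_events=len(subset), top_elements=top, panel=panel,
        coverage_n=cov.n_covered, coverage_total=cov.n_total,
        coverage_percent=cov.percent,
    )
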