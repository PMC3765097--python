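"""Concordance audit of qPCR verification results against the matrix.

Screening assays run on certified reference materials (CRMs) produce coded
outcomes per (material, target) cell:

========  ==========================================================
code      meaning
========  ==========================================================
``+``     positive signal, matrix expects the element present
``-``     negative, matrix expects it absent
``N``     not tested
``R+``    positive explained by a GMO impurity in the CRM
``R-``    negative concordant with the matrix, impurity annotation
``U+``    unexpected positive, unexplained
``U(+)``  unexpected very late positive (trace-level signal)
``(+)``   late positive (trace-level signal)
``U-``    unexpected negative (assay missed a present element)
``BS``    bad amplification signal
========  ==========================================================

Each coded result is classified as concordant with the matrix or into one
of four discordance categories (impurity-explained false positive,
unexplained false positive, ambiguous, false negative), and a
:class:`ConcordanceReport` tallies them.  Late-positive and bad-signal
codes on the t35S terminator are classified as ambiguous rather than false
positive: the t35S consensus target is short and A/T-rich, forcing a less
specific assay whose stray late signals are a known artefact.  The bundled
fixture transcribes a 31-material verification study spanning 26 assay
targets (530 informative tests).
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Sequence

from .model import ElementDescriptor, GmoEvent, ScreeningMatrix, TriState
from .query import round_half_away


class VerificationError(Exception):
    """Unknown result code or corrupted fixture."""


RESULT_CODES = ("+", "-", "N", "R+", "R-", "U+", "U(+)", "U-", "(+)", "BS")

#: Codes whose observed signal is positive-like (some signal was seen —
#: including the bad/atypical amplification curves coded ``BS``).
POSITIVE_LIKE = frozenset({"+", "R+", "U+", "U(+)", "(+)", "BS"})


class Category(Enum):
    CONCORDANT = "concordant"
    FP_IMPURITY = "fp_impurity"
    FP_UNEXPLAINED = "fp_unexplained"
    AMBIGUOUS = "ambiguous"
    FALSE_NEGATIVE = "false_negative"
    EXCLUDED = "excluded"


@dataclass(frozen=True)
class VerificationRecord:
    """One (reference material, assay target) verification outcome."""

    material_id: str
    event: str
    crop: str
    target_element: str
    assay_ref: str
    code: str
    impurity_source: str = ""

    def __post_init__(self) -> None:
        if self.code not in RESULT_CODES:
            raise VerificationError(
                f"unknown result code {self.code!r}; admissible: {', '.join(RESULT_CODES)}"
            )


def classify_record(code: str, target_element: str) -> Category:
    """Map a result code (and its target) to a concordance category.

    Late-positive (``U(+)``, ``(+)``) and bad-signal codes count as
    ambiguous on t35S (known assay artefact) and as unexplained false
    positives elsewhere.
    """
    if code not in RESULT_CODES:
        raise VerificationError(
            f"unknown result code {code!r}; admissible: {', '.join(RESULT_CODES)}"
        )
    if code == "N":
        return Category.EXCLUDED
    if code in ("+", "-", "R-"):
        return Category.CONCORDANT
    if code == "R+":
        return Category.FP_IMPURITY
    if code == "U+":
        return Category.FP_UNEXPLAINED
    if code == "U-":
        return Category.FALSE_NEGATIVE
    if code == "BS":
        return Category.AMBIGUOUS
    # U(+) and (+): trace-level late positives
    return Category.AMBIGUOUS if target_element == "t35S" else Category.FP_UNEXPLAINED


def expected_state(code: str) -> TriState:
    """Matrix expectation implied by a coded result.

    Concordant positives imply *present*; every discordant positive-like
    code implies the matrix says *absent* (the signal came from an impurity
    or artefact, not the certified event), and a false negative (``U-``)
    implies *present* (the element is there, the assay missed it).
    """
    if code not in RESULT_CODES:
        raise VerificationError(f"unknown result code {code!r}")
    if code == "N":
        raise VerificationError("code 'N' (not tested) has no matrix expectation")
    if code in ("+", "U-"):
        return TriState.PRESENT
    return TriState.ABSENT


@dataclass(frozen=True)
class ConcordanceReport:
    """Category tallies over informative (non-``N``) verification results."""

    n_total: int
    n_concordant: int
    n_discordant: int
    n_fp_impurity: int
    n_fp_unexplained: int
    n_ambiguous: int
    n_false_negative: int
    pct_concordant: int
    pct_discordant: int
    pct_fp_impurity: int

    @property
    def n_false_positive(self) -> int:
        """All false positives: impurity-explained plus unexplained."""
        return self.n_fp_impurity + self.n_fp_unexplained


def summarize(records: Sequence[VerificationRecord]) -> ConcordanceReport:
    """Tally classified records; ``N`` (not tested) cells are excluded.

    Percentages are integers, rounded half away from zero on the
    informative total.
    """
    tallies = {c: 0 for c in Category}
    for rec in records:
        tallies[classify_record(rec.code, rec.target_element)] += 1
    n_total = sum(v for c, v in tallies.items() if c is not Category.EXCLUDED)
    n_concordant = tallies[Category.CONCORDANT]
    n_discordant = n_total - n_concordant

    def pct(n: int) -> int:
        return round_half_away(100.0 * n / n_total) if n_total else 0

    return ConcordanceReport(
        n_total=n_total,
        n_concordant=n_concordant,
        n_discordant=n_discordant,
        n_fp_impurity=tallies[Category.FP_IMPURITY],
        n_fp_unexplained=tallies[Category.FP_UNEXPLAINED],
        n_ambiguous=tallies[Category.AMBIGUOUS],
        n_false_negative=tallies[Category.FALSE_NEGATIVE],
        pct_concordant=pct(n_concordant),
        pct_discordant=pct(n_discordant),
        pct_fp_impurity=pct(tallies[Category.FP_IMPURITY]),
    )


# ---------------------------------------------------------------------------
# Bundled fixture

FIXTURE_COLUMNS = (
    "material_id", "event", "crop", "target_element", "assay_ref", "code", "impurity_source"
)

#: Expected accounting of the bundled fixture; load_table1_fixture refuses to
#: return silently corrupted data.
_FIXTURE_CHECKS = {
    "n_materials": 31,
    "n_records": 806,
    "n_total": 530,
    "n_concordant": 492,
    "n_fp_impurity": 28,
    "n_fp_unexplained": 3,
    "n_ambiguous": 4,
    "n_false_negative": 3,
}

_SECTION_BY_ELEMENT = {
    "p35S": "promoter", "pFMV": "promoter", "pNOS": "promoter", "pUbi": "promoter",
    "pSsuAra": "promoter", "pTa29": "promoter", "pActin1": "promoter",
    "tE9": "terminator", "tNOS": "terminator", "t35S": "terminator",
    "tOCS": "terminator", "tg7": "terminator",
    "epsps1": "orf", "epsps2": "orf", "gox": "orf", "bar": "orf", "pat": "orf",
    "cry1Ab": "orf",
    "p35S-bar": "junction", "p35S-hsp70": "junction", "p35S-pat": "junction",
    "CTP2-cp4epsps": "junction",
}


def read_records(path: str | Path) -> list[VerificationRecord]:
    """Read verification records from a TSV file with the fixture columns."""
    return _parse_records(Path(path).read_text("utf-8"))


def _parse_records(text: str) -> list[VerificationRecord]:
    reader = csv.DictReader(io.StringIO(text), delimiter="\t")
    if reader.fieldnames is None or tuple(reader.fieldnames) != FIXTURE_COLUMNS:
        raise VerificationError(
            f"record file must have columns: {', '.join(FIXTURE_COLUMNS)}"
        )
    return [VerificationRecord(**row) for row in reader]


def derive_mini_matrix(records: Sequence[VerificationRecord]) -> ScreeningMatrix:
    """Build the events x targets matrix implied by the records.

    Cells come from :func:`expected_state`; observations of the same element
    by different assays must agree on the expectation (they do in the
    bundled fixture — e.g. the event whose two enhancer-targeting p35S
    assays failed still expects p35S *present*, confirmed by the third
    assay).  Untested cells stay unknown.
    """
    element_order: list[str] = []
    per_event: dict[str, dict[str, TriState]] = {}
    meta: dict[str, tuple[str, str]] = {}
    for rec in records:
        if rec.target_element not in element_order:
            element_order.append(rec.target_element)
        meta.setdefault(rec.event, (rec.crop, rec.material_id))
        if rec.code == "N":
            continue
        exp = expected_state(rec.code)
        cell = per_event.setdefault(rec.event, {})
        prev = cell.get(rec.target_element)
        if prev is not None and prev is not exp:
            raise VerificationError(
                f"conflicting expectations for {rec.event}/{rec.target_element}"
            )
        cell[rec.target_element] = exp
    elements = [
        ElementDescriptor(name, _SECTION_BY_ELEMENT.get(name, "miscellaneous"))
        for name in element_order
    ]
    events = [
        GmoEvent(
            trade_name=event, unique_id="", crop_species=meta[event][0],
            profile=per_event.get(event, {}),
        )
        for event in meta
    ]
    return ScreeningMatrix(elements=elements, events=events, version_tag="verification-mini")


def load_table1_fixture() -> tuple[list[VerificationRecord], ScreeningMatrix]:
    """Load the bundled verification study records and the derived mini-matrix.

    Integrity-checked against the study's accounting: 31 reference
    materials, 530 informative tests, 492 concordant, 28 impurity-explained
    false positives, 3 unexplained late positives, 4 ambiguous results and
    3 false negatives.  A mismatch raises :class:`VerificationError`.
    """
    text = resources.files("gmomatrix.data").joinpath("table1_records.tsv").read_text("utf-8")
    records = _parse_records(text)
    report = summarize(records)
    observed = {
        "n_materials": len({r.material_id for r in records}),
        "n_records": len(records),
        "n_total": report.n_total,
        "n_concordant": report.n_concordant,
        "n_fp_impurity": report.n_fp_impurity,
        "n_fp_unexplained": report.n_fp_unexplained,
        "n_ambiguous": report.n_ambiguous,
        "n_false_negative": report.n_false_negative,
    }
    if observed != _FIXTURE_CHECKS:
        raise VerificationError(
            f"fixture integrity check failed: expected {_FIXTURE_CHECKS}, got {observed}"
        )
    return records, derive_mini_matrix(records)
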