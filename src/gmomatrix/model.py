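"""Tri-state screening matrix: data model, TSV/Excel I/O, validation.

The central object is :class:`ScreeningMatrix`, a table of GMO events (rows)
against genetic elements (columns) where each cell is one of three states:
*present* (the event's transgene construct carries the element), *absent*
(documented not to carry it), or *unknown* (no reliable information — the
cell is left empty in the tabulated file).

Elements are grouped into six sections: promoters, terminators, open-reading
frames, miscellaneous vector elements, construct junctions, and endogenous
(species-identification) targets.  Element naming follows a single canonical
vocabulary; common synonyms (e.g. ``pE35S`` for ``p35S``) are resolved
through an editable synonym table.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple


class TriState(Enum):
    """Cell state of the screening matrix: present / absent / unknown."""

    PRESENT = "present"
    ABSENT = "absent"
    UNKNOWN = "unknown"

    @classmethod
    def from_token(cls, token: str) -> "TriState":
        """Parse a file cell token: ``"1"`` / ``"0"`` / empty string."""
        token = token.strip()
        if token == "1":
            return cls.PRESENT
        if token == "0":
            return cls.ABSENT
        if token == "":
            return cls.UNKNOWN
        raise MatrixParseError(f"illegal cell token {token!r} (expected 1, 0 or empty)")

    def to_token(self) -> str:
        return {TriState.PRESENT: "1", TriState.ABSENT: "0", TriState.UNKNOWN: ""}[self]


SECTIONS = ("promoter", "terminator", "orf", "miscellaneous", "junction", "endogenous")
#: Sections whose elements are transgene components (endogenous targets detect
#: the plant species, not the modification).
GM_SECTIONS = ("promoter", "terminator", "orf", "miscellaneous", "junction")

#: Section sizes of the published reference schema (release 18/07/2013):
#: 55 promoters, 31 terminators, 103 ORF segments, 47 miscellaneous elements,
#: 11 construct junctions, plus 28 endogenous plant targets.
REFERENCE_SECTION_SIZES: dict[str, int] = {
    "promoter": 55,
    "terminator": 31,
    "orf": 103,
    "miscellaneous": 47,
    "junction": 11,
    "endogenous": 28,
}

EU_STATUSES = ("authorized", "not_authorized", "llp_619_2011")
EVENT_TYPES = ("single", "stacked")

METADATA_COLUMNS = ("trade_name", "unique_id", "crop_species", "event_type", "eu_status")


class MatrixError(Exception):
    """Base class for screening-matrix errors."""


class MatrixParseError(MatrixError):
    """A cell or header token could not be interpreted."""


class MatrixSchemaError(MatrixError):
    """The file header or metadata violates the matrix schema."""


@dataclass(frozen=True)
class ElementDescriptor:
    """One genetic element (screening target) of the matrix.

    ``assay_available`` records whether a detection assay (PCR/qPCR) exists
    for the element; ``None`` means unrecorded (treated as available).
    """

    canonical_name: str
    section: str
    synonyms: tuple[str, ...] = ()
    assay_available: bool | None = None

    def __post_init__(self) -> None:
        if self.section not in SECTIONS:
            raise MatrixSchemaError(
                f"illegal section {self.section!r} for element {self.canonical_name!r}; "
                f"admissible: {', '.join(SECTIONS)}"
            )


@dataclass(frozen=True)
class GmoEvent:
    """One GMO transformation event (matrix row) with its element profile."""

    trade_name: str
    unique_id: str
    crop_species: str
    event_type: str = "single"
    eu_status: str = "not_authorized"
    # excluded from the generated hash (dict cells); equality still uses it
    profile: Mapping[str, TriState] = field(default_factory=dict, hash=False)

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise MatrixSchemaError(
                f"illegal event_type {self.event_type!r}; admissible: {', '.join(EVENT_TYPES)}"
            )
        if self.eu_status not in EU_STATUSES:
            raise MatrixSchemaError(
                f"illegal eu_status {self.eu_status!r}; admissible: {', '.join(EU_STATUSES)}"
            )

    def state(self, element: str) -> TriState:
        """Cell state for ``element``; missing cells read as unknown."""
        return self.profile.get(element, TriState.UNKNOWN)

    @property
    def present_elements(self) -> frozenset[str]:
        return frozenset(e for e, s in self.profile.items() if s is TriState.PRESENT)

    @property
    def absent_elements(self) -> frozenset[str]:
        return frozenset(e for e, s in self.profile.items() if s is TriState.ABSENT)

    def label(self) -> str:
        return self.unique_id or self.trade_name


@dataclass
class ScreeningMatrix:
    """Ordered events x ordered elements tri-state table with metadata."""

    elements: list[ElementDescriptor]
    events: list[GmoEvent]
    version_tag: str = ""

    def element_names(self) -> list[str]:
        return [e.canonical_name for e in self.elements]

    def element(self, name: str) -> ElementDescriptor:
        for e in self.elements:
            if e.canonical_name == name:
                return e
        raise KeyError(name)

    def has_element(self, name: str) -> bool:
        return any(e.canonical_name == name for e in self.elements)

    def find_event(self, identifier: str) -> GmoEvent:
        """Look up an event by unique id or trade name."""
        for ev in self.events:
            if identifier in (ev.unique_id, ev.trade_name):
                return ev
        raise KeyError(f"no event with identifier {identifier!r}")

    def state(self, event: GmoEvent, element: str) -> TriState:
        return event.state(element)

    def crops(self) -> list[str]:
        seen: dict[str, None] = {}
        for ev in self.events:
            seen.setdefault(ev.crop_species)
        return list(seen)

    def synonym_table(self) -> dict[str, str]:
        table: dict[str, str] = {}
        for e in self.elements:
            for syn in e.synonyms:
                table[syn] = e.canonical_name
        return table

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ScreeningMatrix):
            return NotImplemented
        if self.version_tag != other.version_tag or self.elements != other.elements:
            return False
        if len(self.events) != len(other.events):
            return False
        names = self.element_names()
        for a, b in zip(self.events, other.events):
            if (a.trade_name, a.unique_id, a.crop_species, a.event_type, a.eu_status) != (
                b.trade_name, b.unique_id, b.crop_species, b.event_type, b.eu_status
            ):
                return False
            # profiles compare on materialized cells (missing == unknown)
            if any(a.state(n) is not b.state(n) for n in names):
                return False
        return True


class CanonicalName(NamedTuple):
    """Result of synonym resolution: the name plus a vocabulary flag."""

    name: str
    in_vocabulary: bool


def canonicalize_element(name: str, synonym_table: Mapping[str, str],
                         vocabulary: Iterable[str] | None = None) -> CanonicalName:
    """Resolve ``name`` to its canonical form.

    A canonical name is a fixed point.  Unrecognized names are returned
    unchanged with ``in_vocabulary=False`` rather than raising, so callers
    can decide whether an unknown element is an error.
    """
    if name in synonym_table:
        return CanonicalName(synonym_table[name], True)
    if vocabulary is None:
        vocab = set(synonym_table.values())
    else:
        vocab = set(vocabulary)
    return CanonicalName(name, name in vocab)


def load_synonyms(path: str | Path | None = None) -> dict[str, str]:
    """Load the synonym table (``synonym<TAB>canonical`` per line).

    Without a path, the table bundled with the package is used; it seeds the
    historically ambiguous names (``pE35S`` for ``p35S``; ``pFMV34S``,
    ``pCmoVb`` and ``peFMV`` for ``pFMV``).
    """
    if path is None:
        text = resources.files("gmomatrix.data").joinpath("synonyms.tsv").read_text("utf-8")
    else:
        text = Path(path).read_text("utf-8")
    table: dict[str, str] = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise MatrixParseError(f"synonyms line {lineno}: expected 2 tab-separated fields")
        syn, canon = parts
        if syn in table and table[syn] != canon:
            raise MatrixParseError(f"synonym {syn!r} maps to both {table[syn]!r} and {canon!r}")
        table[syn] = canon
    return table


# ---------------------------------------------------------------------------
# TSV I/O
#
# Layout: UTF-8, tab-separated, first row header.  Five fixed metadata
# columns, then one column per element headed "section:canonical_name".
# Cells are "1" / "0" / empty.  The optional first header cell may carry a
# "#version=..." comment line above the header.

def _parse_element_header(header: str) -> tuple[str, str]:
    if ":" not in header:
        raise MatrixSchemaError(
            f"element column header {header!r} must have the form 'section:name'"
        )
    section, name = header.split(":", 1)
    if section not in SECTIONS:
        raise MatrixSchemaError(f"unknown section {section!r} in column header {header!r}")
    if not name:
        raise MatrixSchemaError(f"empty element name in column header {header!r}")
    return section, name


def read_matrix(path: str | Path, synonyms: Mapping[str, str] | None = None) -> ScreeningMatrix:
    """Read a screening matrix from its tab-separated representation."""
    text = Path(path).read_text("utf-8")
    return _read_matrix_text(text, synonyms or {})


def _read_matrix_text(text: str, synonyms: Mapping[str, str]) -> ScreeningMatrix:
    version_tag = ""
    lines = text.splitlines()
    if lines and lines[0].startswith("#version="):
        version_tag = lines[0][len("#version="):]
        lines = lines[1:]
    reader = csv.reader(io.StringIO("\n".join(lines)), delimiter="\t")
    try:
        header = next(reader)
    except StopIteration:
        raise MatrixSchemaError("empty file: missing header row") from None
    if tuple(header[: len(METADATA_COLUMNS)]) != METADATA_COLUMNS:
        raise MatrixSchemaError(
            f"first {len(METADATA_COLUMNS)} columns must be {', '.join(METADATA_COLUMNS)}"
        )
    elements: list[ElementDescriptor] = []
    seen_names: set[str] = set()
    for col in header[len(METADATA_COLUMNS):]:
        section, name = _parse_element_header(col)
        if name in seen_names:
            raise MatrixSchemaError(f"duplicate element column {name!r}")
        seen_names.add(name)
        syns = tuple(s for s, c in synonyms.items() if c == name)
        elements.append(ElementDescriptor(name, section, syns))
    names = [e.canonical_name for e in elements]

    events: list[GmoEvent] = []
    for rowno, row in enumerate(reader, 2):
        if not row or all(not c for c in row):
            continue
        if len(row) < len(METADATA_COLUMNS):
            raise MatrixParseError(f"row {rowno}: fewer fields than metadata columns")
        row = row + [""] * (len(header) - len(row))
        meta = row[: len(METADATA_COLUMNS)]
        profile: dict[str, TriState] = {}
        for name, token in zip(names, row[len(METADATA_COLUMNS):]):
            try:
                state = TriState.from_token(token)
            except MatrixParseError as exc:
                raise MatrixParseError(f"row {rowno}, column {name!r}: {exc}") from None
            if state is not TriState.UNKNOWN:
                profile[name] = state
        events.append(
            GmoEvent(
                trade_name=meta[0],
                unique_id=meta[1],
                crop_species=meta[2],
                event_type=meta[3] or "single",
                eu_status=meta[4] or "not_authorized",
                profile=profile,
            )
        )
    return ScreeningMatrix(elements=elements, events=events, version_tag=version_tag)


def write_matrix(matrix: ScreeningMatrix, path: str | Path) -> None:
    """Write ``matrix`` as deterministic UTF-8 TSV (stable order, LF endings)."""
    Path(path).write_text(matrix_to_text(matrix), "utf-8", newline="")


def matrix_to_text(matrix: ScreeningMatrix) -> str:
    buf = io.StringIO()
    writer = csv.writer(buf, delimiter="\t", lineterminator="\n")
    if matrix.version_tag:
        buf.write(f"#version={matrix.version_tag}\n")
    header = list(METADATA_COLUMNS) + [
        f"{e.section}:{e.canonical_name}" for e in matrix.elements
    ]
    writer.writerow(header)
    names = matrix.element_names()
    for ev in matrix.events:
        row = [ev.trade_name, ev.unique_id, ev.crop_species, ev.event_type, ev.eu_status]
        row += [ev.state(n).to_token() for n in names]
        writer.writerow(row)
    return buf.getvalue()


def read_matrix_excel(path: str | Path, sheet: str | None = None,
                      synonyms: Mapping[str, str] | None = None) -> ScreeningMatrix:
    """Import a matrix from an Excel workbook laid out like the TSV format.

    Read-only convenience: the first worksheet (or ``sheet``) must carry the
    same header row as the TSV format; cell values 1/0/blank map to
    present/absent/unknown.  The TSV format remains canonical.
    """
    from openpyxl import load_workbook

    wb = load_workbook(filename=str(path), read_only=True, data_only=True)
    ws = wb[sheet] if sheet else wb.worksheets[0]
    rows = []
    for raw in ws.iter_rows(values_only=True):
        rows.append(["" if v is None else str(int(v)) if isinstance(v, float) and v == int(v)
                     else str(v) for v in raw])
    wb.close()
    buf = io.StringIO()
    writer = csv.writer(buf, delimiter="\t", lineterminator="\n")
    for row in rows:
        writer.writerow(row)
    return _read_matrix_text(buf.getvalue(), synonyms or {})


# ---------------------------------------------------------------------------
# Validation

def validate_matrix(matrix: ScreeningMatrix) -> list[str]:
    """Return a list of violation messages (empty when the matrix is valid).

    Violations are data, not exceptions: duplicate identifiers, profile keys
    outside the declared element list, synonym collisions.  Section legality
    is enforced at construction by :class:`ElementDescriptor`.
    """
    violations: list[str] = []
    names = matrix.element_names()
    declared = set(names)
    if len(declared) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        violations.append(f"duplicate element name(s): {', '.join(dupes)}")

    syn_owner: dict[str, str] = {}
    for el in matrix.elements:
        for syn in el.synonyms:
            if syn in syn_owner and syn_owner[syn] != el.canonical_name:
                violations.append(
                    f"synonym collision: {syn!r} attached to both "
                    f"{syn_owner[syn]!r} and {el.canonical_name!r}"
                )
            syn_owner.setdefault(syn, el.canonical_name)

    seen_pairs: set[tuple[str, str]] = set()
    seen_uids: set[str] = set()
    for ev in matrix.events:
        pair = (ev.trade_name, ev.unique_id)
        if pair in seen_pairs:
            violations.append(f"duplicate event (trade_name, unique_id) pair: {pair!r}")
        seen_pairs.add(pair)
        if ev.unique_id:
            if ev.unique_id in seen_uids:
                violations.append(f"duplicate unique_id: {ev.unique_id!r}")
            seen_uids.add(ev.unique_id)
        undeclared = sorted(set(ev.profile) - declared)
        if undeclared:
            violations.append(
                f"event {ev.label()!r}: profile key(s) not declared as elements: "
                f"{', '.join(undeclared)}"
            )
    return violations


def section_counts(matrix: ScreeningMatrix) -> dict[str, int]:
    """Number of elements per section (all six sections always present)."""
    counts = {s: 0 for s in SECTIONS}
    for el in matrix.elements:
        counts[el.section] += 1
    return counts


def gm_element_count(matrix: ScreeningMatrix) -> int:
    """Total distinct GM elements: sum over the five non-endogenous sections."""
    counts = section_counts(matrix)
    return sum(counts[s] for s in GM_SECTIONS)
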