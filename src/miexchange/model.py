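"""Format-agnostic molecular interaction data model.

Every reader in this library populates these types and every writer consumes
them, so a conversion is always a single read into the model followed by a
single write — never a chain of format-to-format translations.

The central unit is the :class:`Interaction`: one piece of interaction
evidence with N participants, an interaction type, an experimental context
and confidence scores. Binary formats (MITAB, MI-JSON) see the data through
:class:`BinaryInteraction`, an exactly-two-slot view produced either by a
reader of a natively binary format or by spoke/matrix expansion
(:mod:`miexchange.expansion`).

All annotation, in every dialect, bottoms out in two atoms:

* :class:`CvTerm` — a controlled-vocabulary concept, normally carrying a
  PSI-MI accession of the form ``MI:NNNN``;
* :class:`Xref` — a database cross-reference (database CV term + identifier).

Collections are order-preserving on read/write but order-insensitive under
:func:`semantic_equals`: files are ordered, semantics are not. Unknown CV
terms are retained as bare short names, never dropped — the library is a
carrier, not a censor.
"""

from __future__ import annotations

import copy
import re
from collections import Counter
from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Optional

_MI_PATTERN = re.compile(r"^MI:\d{4}$")

#: NCBI taxid stand-ins defined by the PSI-MI formats for non-organismal contexts.
RESERVED_TAXIDS = {
    -1: "in vitro",
    -2: "chemical synthesis",
    -3: "unknown",
    -4: "in vivo",
    -5: "in silico",
}

STRINGENCIES = ("identity", "default", "exact")


@dataclass
class CvTerm:
    """A controlled-vocabulary term (PSI-MI ontology class or foreign CV)."""

    short_name: str
    full_name: Optional[str] = None
    mi_identifier: Optional[str] = None
    xrefs: list["Xref"] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.short_name:
            raise ValueError("CvTerm.short_name must be non-empty")
        if self.mi_identifier is not None and not _MI_PATTERN.match(self.mi_identifier):
            raise ValueError(
                f"mi_identifier {self.mi_identifier!r} does not match 'MI:' + 4 digits"
            )

    def key(self) -> str:
        """Comparison key: the MI accession when present, else the short name."""
        return self.mi_identifier if self.mi_identifier else self.short_name.lower()


def cv(short_name: str, mi: Optional[str] = None, full_name: Optional[str] = None) -> CvTerm:
    """Shorthand CvTerm constructor used throughout the library."""
    return CvTerm(short_name=short_name, full_name=full_name, mi_identifier=mi)


# Well-known terms the model itself needs (defaults and expansion tags).
def unspecified_role() -> CvTerm:
    return cv("unspecified role", "MI:0499")


def unspecified_method() -> CvTerm:
    return cv("unspecified method", "MI:0686")


def spoke_expansion_term() -> CvTerm:
    return cv("spoke expansion", "MI:1060")


def matrix_expansion_term() -> CvTerm:
    return cv("matrix expansion", "MI:1061")


@dataclass
class Xref:
    database: CvTerm
    identifier: str
    version: Optional[str] = None
    qualifier: Optional[CvTerm] = None

    def __post_init__(self) -> None:
        if not self.identifier:
            raise ValueError("Xref.identifier must be non-empty")

    def key(self) -> str:
        return f"{self.database.short_name.lower()}:{self.identifier}"


@dataclass
class Alias:
    name: str
    alias_type: Optional[CvTerm] = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("Alias.name must be non-empty")


@dataclass
class Annotation:
    topic: CvTerm
    value: Optional[str] = None


@dataclass
class Organism:
    taxid: int
    common_name: Optional[str] = None
    scientific_name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.taxid <= 0 and self.taxid not in RESERVED_TAXIDS:
            raise ValueError(
                f"taxid must be positive or one of {sorted(RESERVED_TAXIDS)}; got {self.taxid}"
            )


@dataclass
class Interactor:
    """A molecule: protein, small molecule, nucleic acid or complex."""

    preferred_id: Xref
    interactor_type: CvTerm
    alternative_ids: list[Xref] = field(default_factory=list)
    aliases: list[Alias] = field(default_factory=list)
    organism: Optional[Organism] = None
    sequence: Optional[str] = None
    xrefs: list[Xref] = field(default_factory=list)
    annotations: list[Annotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.preferred_id is None:
            raise ValueError("Interactor.preferred_id is required")
        if self.sequence is not None:
            if not self.sequence or any(c.isspace() for c in self.sequence):
                raise ValueError("Interactor.sequence must be non-empty and whitespace-free")


@dataclass
class Position:
    """One end of a feature range: a status CV term plus an optional coordinate.

    Coordinates are 1-based and inclusive. A position is *determinate* when
    it carries a coordinate (status such as ``certain``); undetermined or
    fuzzy ends carry only the status.
    """

    status: CvTerm
    coordinate: Optional[int] = None

    def is_determinate(self) -> bool:
        return self.coordinate is not None


@dataclass
class Range:
    start: Position
    end: Position
    is_link: bool = False

    def __post_init__(self) -> None:
        if (
            self.start.is_determinate()
            and self.end.is_determinate()
            and self.start.coordinate > self.end.coordinate
        ):
            raise ValueError(
                f"range start {self.start.coordinate} > end {self.end.coordinate}"
            )


def certain_range(start: int, end: int) -> Range:
    """A fully determinate 1-based inclusive range."""
    certain = cv("certain", "MI:0335")
    return Range(Position(certain, start), Position(copy.deepcopy(certain), end))


@dataclass
class Feature:
    """A sequence feature of a participant: binding region, tag, mutation..."""

    feature_type: Optional[CvTerm] = None
    ranges: list[Range] = field(default_factory=list)
    detection_method: Optional[CvTerm] = None
    names: list[Alias] = field(default_factory=list)


@dataclass
class Stoichiometry:
    min_value: int
    max_value: int

    def __post_init__(self) -> None:
        if self.min_value < 0 or self.max_value < 0:
            raise ValueError("stoichiometry values must be non-negative")
        if self.min_value > self.max_value:
            raise ValueError("stoichiometry min_value must be <= max_value")


@dataclass
class Participant:
    """An interactor within one interaction, with roles, features and stoichiometry."""

    interactor: Interactor
    biological_role: Optional[CvTerm] = None
    experimental_role: Optional[CvTerm] = None
    identification_methods: list[CvTerm] = field(default_factory=list)
    features: list[Feature] = field(default_factory=list)
    stoichiometry: Optional[Stoichiometry] = None
    xrefs: list[Xref] = field(default_factory=list)
    annotations: list[Annotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.biological_role is None:
            self.biological_role = unspecified_role()

    def is_bait(self) -> bool:
        role = self.experimental_role
        if role is None:
            return False
        return role.short_name.lower() == "bait" or role.mi_identifier == "MI:0496"


@dataclass
class Publication:
    """The publication an evidence was curated from.

    May carry a cross-reference identifier (pubmed/doi) AND inline attributes
    (title, journal, authors) at the same time: XML 2.5 forces a choice
    between the two representations, XML 3.0 allows both on one experiment,
    and this type is the superset both map onto.
    """

    pubmed_id: Optional[str] = None
    doi: Optional[str] = None
    title: Optional[str] = None
    journal: Optional[str] = None
    authors: list[str] = field(default_factory=list)
    publication_date: Optional[date] = None
    source: Optional[CvTerm] = None
    identifiers: list[Xref] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (self.pubmed_id or self.doi or self.identifiers or self.title):
            raise ValueError(
                "Publication needs at least one of pubmed_id, doi, identifiers, title"
            )

    def has_inline_attributes(self) -> bool:
        return bool(self.title or self.journal or self.authors)


@dataclass
class Experiment:
    detection_method: Optional[CvTerm] = None
    publication: Optional[Publication] = None
    host_organism: Optional[Organism] = None
    annotations: list[Annotation] = field(default_factory=list)
    xrefs: list[Xref] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.detection_method is None:
            self.detection_method = unspecified_method()


@dataclass
class Interaction:
    """One interaction evidence with N participants."""

    participants: list[Participant]
    id: Optional[str] = None
    interaction_type: Optional[CvTerm] = None
    experiment: Optional[Experiment] = None
    confidences: list[tuple[CvTerm, str]] = field(default_factory=list)
    parameters: list[tuple[CvTerm, str]] = field(default_factory=list)
    is_negative: bool = False
    xrefs: list[Xref] = field(default_factory=list)
    annotations: list[Annotation] = field(default_factory=list)
    checksums: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.participants:
            raise ValueError("Interaction.participants must be non-empty")

    def arity(self) -> int:
        return len(self.participants)


@dataclass
class BinaryInteraction(Interaction):
    """Exactly-two-participant view of an interaction.

    ``complex_expansion`` records the expansion method that produced it;
    it is absent iff the record was natively binary. A self-interaction is
    represented with equal participants in both slots.
    """

    complex_expansion: Optional[CvTerm] = None

    def __post_init__(self) -> None:
        super().__post_init__()
        if len(self.participants) == 1:
            # one-slot input: promote to a self-interaction
            self.participants = [self.participants[0], copy.deepcopy(self.participants[0])]
        if len(self.participants) != 2:
            raise ValueError(
                f"BinaryInteraction needs exactly two participant slots, got {len(self.participants)}"
            )

    @property
    def participant_a(self) -> Participant:
        return self.participants[0]

    @property
    def participant_b(self) -> Participant:
        return self.participants[1]

    def is_self_interaction(self) -> bool:
        return (
            self.participant_a.interactor.preferred_id.key()
            == self.participant_b.interactor.preferred_id.key()
        )


@dataclass
class ComplexRecord:
    """A curated macromolecular assembly (abstract interaction), distinct from
    a single experimental evidence. Writable only at PSI-MI XML 3.0."""

    recommended_name: str
    participants: list[Participant]
    evidence_type: Optional[CvTerm] = None
    organism: Optional[Organism] = None
    xrefs: list[Xref] = field(default_factory=list)
    annotations: list[Annotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.participants:
            raise ValueError("ComplexRecord.participants must be non-empty")


@dataclass(frozen=True)
class FormatDescriptor:
    """(format, version, direction) triple governing registry support."""

    format: str
    direction: str
    version: Optional[str] = None

    _FORMATS = ("mitab", "psi-xml", "mi-json", "html")
    _DIRECTIONS = ("read", "write")

    def __post_init__(self) -> None:
        if self.format not in self._FORMATS:
            raise ValueError(f"unknown format {self.format!r}")
        if self.direction not in self._DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.format in ("mi-json", "html") and self.direction == "read":
            raise ValueError(f"({self.format}, read) is not a valid descriptor: write-only format")


@dataclass
class ReportEntry:
    severity: str  # "error" or "warning"
    kind: str
    message: str
    line: Optional[int] = None
    column: Optional[int] = None
    locator: Optional[str] = None


@dataclass
class ParseReport:
    """Record-level problems collected while a reader kept going."""

    entries: list[ReportEntry] = field(default_factory=list)

    def add(self, severity: str, kind: str, message: str, **loc) -> None:
        self.entries.append(ReportEntry(severity=severity, kind=kind, message=message, **loc))

    @property
    def errors(self) -> list[ReportEntry]:
        return [e for e in self.entries if e.severity == "error"]

    @property
    def warnings(self) -> list[ReportEntry]:
        return [e for e in self.entries if e.severity == "warning"]

    def __bool__(self) -> bool:
        return bool(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


# ---------------------------------------------------------------------------
# Semantic comparison
# ---------------------------------------------------------------------------

def _cv_key(term: Optional[CvTerm]) -> Optional[str]:
    return term.key() if term is not None else None


def _range_sig(r: Range) -> tuple:
    return (
        _cv_key(r.start.status),
        r.start.coordinate,
        _cv_key(r.end.status),
        r.end.coordinate,
        r.is_link,
    )


def _feature_sig(f: Feature) -> tuple:
    return (
        _cv_key(f.feature_type),
        tuple(sorted(_range_sig(r) for r in f.ranges)),
        _cv_key(f.detection_method),
    )


def _participant_sig(p: Participant, stringency: str) -> tuple:
    pid = p.interactor.preferred_id.key()
    if stringency == "identity":
        return (pid,)
    sig = (pid, _cv_key(p.biological_role), _cv_key(p.experimental_role))
    if stringency == "default":
        return sig
    stoich = (
        (p.stoichiometry.min_value, p.stoichiometry.max_value)
        if p.stoichiometry is not None
        else None
    )
    return sig + (
        stoich,
        tuple(sorted(_feature_sig(f) for f in p.features)),
    )


def _interaction_sig(i: Interaction, stringency: str):
    participants = Counter(_participant_sig(p, stringency) for p in i.participants)
    if stringency == "identity":
        return participants
    base = (participants, _cv_key(i.interaction_type), i.is_negative)
    if stringency == "default":
        return base
    return base + (
        Counter((c[0].key(), c[1]) for c in i.confidences),
        Counter((a.topic.key(), a.value) for a in i.annotations),
    )


def semantic_equals(a: Interaction, b: Interaction, stringency: str = "default") -> bool:
    """Order-insensitive semantic comparison of two interactions.

    Stringency levels (each implies the previous):

    * ``identity`` — participant interactor preferred ids as an unordered
      multiset;
    * ``default`` — adds interaction type, negativity, and the biological /
      experimental roles of each participant;
    * ``exact`` — adds features, stoichiometry, confidences and annotations.

    All collections are compared as multisets; list order never matters.
    """
    if stringency not in STRINGENCIES:
        raise ValueError(f"unknown stringency {stringency!r}; expected one of {STRINGENCIES}")
    return _interaction_sig(a, stringency) == _interaction_sig(b, stringency)


def apply_defaults(interaction: Interaction) -> Interaction:
    """Return a copy with the 'unspecified' CV terms filled into any missing
    participant biological role or experiment detection method. Idempotent."""
    out = copy.deepcopy(interaction)
    for p in out.participants:
        if p.biological_role is None:  # constructor fills it, but stay defensive
            p.biological_role = unspecified_role()
    if out.experiment is not None and out.experiment.detection_method is None:
        out.experiment.detection_method = unspecified_method()
    return out


def distinct_interactors(interactions: Iterable[Interaction]) -> dict[str, Interactor]:
    """Map preferred-id key -> first-seen Interactor across a stream."""
    seen: dict[str, Interactor] = {}
    for i in interactions:
        for p in i.participants:
            key = p.interactor.preferred_id.key()
            seen.setdefault(key, p.interactor)
    return seen
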