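"""MITAB 2.5 / 2.6 / 2.7 reader and writer.

MITAB is the tab-delimited PSI-MI dialect: one row per binary interaction
evidence, ``\\t`` separating columns, ``|`` separating multiple values
within a column, ``-`` denoting an empty column, and each value following
the ``db:identifier(free text)`` grammar with double-quote escaping of the
reserved characters.

Version lattice (the later versions strictly extend the earlier):

* 2.5 — columns 1-15: ids, alternatives, aliases, detection method, first
  author, publication ids, taxids, interaction type, source db, interaction
  ids, confidences.
* 2.6 — adds columns 16-36: complex expansion, biological/experimental
  roles, interactor types, xrefs, annotations, host taxid, parameters,
  dates, checksums, negative flag.
* 2.7 — adds columns 37-42: features, stoichiometries, participant
  identification methods.

The reader is permissive (accepts quoted and bare sub-fields, tolerates a
missing header); the writer is strict (always quotes reserved characters,
always emits a header and exactly the version's column count). Rows that do
not parse are collected into a :class:`~miexchange.model.ParseReport` and
skipped; parsing only fails outright when the very first row cannot decide
the dialect.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import IO, Iterable, Iterator, Optional

from .errors import CapabilityError, MalformedFieldError, UnsupportedDialectError
from .model import (
    Alias,
    Annotation,
    BinaryInteraction,
    CvTerm,
    Experiment,
    Feature,
    Interactor,
    Organism,
    ParseReport,
    Participant,
    Position,
    Publication,
    Range,
    Stoichiometry,
    Xref,
    certain_range,
    cv,
)

EMPTY = "-"
RESERVED = set('|():"\t')  # plus whitespace-sensitive values, quoted by _escape

COLUMN_COUNTS = {"2.5": 15, "2.6": 36, "2.7": 42}
VERSIONS = tuple(COLUMN_COUNTS)

HEADER_42 = [
    "ID(s) interactor A", "ID(s) interactor B",
    "Alt. ID(s) interactor A", "Alt. ID(s) interactor B",
    "Alias(es) interactor A", "Alias(es) interactor B",
    "Interaction detection method(s)", "Publication 1st author(s)",
    "Publication Identifier(s)",
    "Taxid interactor A", "Taxid interactor B",
    "Interaction type(s)", "Source database(s)",
    "Interaction identifier(s)", "Confidence value(s)",
    "Expansion method(s)",
    "Biological role(s) interactor A", "Biological role(s) interactor B",
    "Experimental role(s) interactor A", "Experimental role(s) interactor B",
    "Type(s) interactor A", "Type(s) interactor B",
    "Xref(s) interactor A", "Xref(s) interactor B", "Interaction Xref(s)",
    "Annotation(s) interactor A", "Annotation(s) interactor B",
    "Interaction annotation(s)",
    "Host organism(s)", "Interaction parameter(s)",
    "Creation date", "Update date",
    "Checksum(s) interactor A", "Checksum(s) interactor B",
    "Interaction Checksum(s)", "Negative",
    "Feature(s) interactor A", "Feature(s) interactor B",
    "Stoichiometry(s) interactor A", "Stoichiometry(s) interactor B",
    "Identification method participant A", "Identification method participant B",
]


@dataclass
class MitabField:
    """One ``db:identifier(free text)`` value within a MITAB column."""

    db: str
    identifier: str
    free_text: Optional[str] = None


def detect_mitab_version(column_count: int) -> str:
    """Map a data row's column count onto the MITAB version lattice."""
    for version, count in COLUMN_COUNTS.items():
        if column_count == count:
            return version
    raise UnsupportedDialectError(
        f"{column_count} columns matches no supported MITAB version "
        f"(expected one of {sorted(COLUMN_COUNTS.values())})"
    )


# ---------------------------------------------------------------------------
# Field grammar
# ---------------------------------------------------------------------------

def _split_unquoted(text: str, sep: str) -> list[str]:
    """Split on `sep` occurrences outside double quotes; backslash escapes."""
    parts: list[str] = []
    buf: list[str] = []
    in_quotes = False
    escaped = False
    for ch in text:
        if escaped:
            buf.append(ch)
            escaped = False
        elif ch == "\\":
            buf.append(ch)
            escaped = True
        elif ch == '"':
            in_quotes = not in_quotes
            buf.append(ch)
        elif ch == sep and not in_quotes:
            parts.append("".join(buf))
            buf = []
        else:
            buf.append(ch)
    if in_quotes:
        raise MalformedFieldError(f"unbalanced quote in {text!r}")
    parts.append("".join(buf))
    return parts


def _unquote(token: str) -> str:
    token = token.strip()
    if len(token) >= 2 and token.startswith('"') and token.endswith('"'):
        inner = token[1:-1]
        return inner.replace('\\"', '"').replace("\\\\", "\\")
    return token


def _parse_entry(entry: str) -> MitabField:
    # db : identifier [( free_text )] -- any token may be quoted
    head_parts = _split_unquoted(entry, ":")
    if len(head_parts) < 2:
        raise MalformedFieldError(f"no ':' separator in {entry!r}")
    db = _unquote(head_parts[0])
    rest = ":".join(head_parts[1:])
    free_text = None
    # locate an unquoted '(' opening a trailer
    depth = 0
    in_quotes = False
    escaped = False
    open_idx = None
    for idx, ch in enumerate(rest):
        if escaped:
            escaped = False
            continue
        if ch == "\\":
            escaped = True
        elif ch == '"':
            in_quotes = not in_quotes
        elif ch == "(" and not in_quotes:
            if depth == 0 and open_idx is None:
                open_idx = idx
            depth += 1
        elif ch == ")" and not in_quotes:
            depth -= 1
            if depth < 0:
                raise MalformedFieldError(f"unbalanced ')' in {entry!r}")
    if depth != 0:
        raise MalformedFieldError(f"unbalanced '(' in {entry!r}")
    if open_idx is not None:
        if not rest.rstrip().endswith(")"):
            raise MalformedFieldError(f"trailing text after ')' in {entry!r}")
        free_text = _unquote(rest.rstrip()[open_idx + 1 : -1])
        rest = rest[:open_idx]
    identifier = _unquote(rest)
    return MitabField(db=db, identifier=identifier, free_text=free_text)


def parse_mitab_field(raw: str) -> list[MitabField]:
    """Parse one tab-separated cell into its ``|``-separated entries.

    ``-`` (the empty-field sentinel) parses to an empty list.
    """
    raw = raw.strip()
    if raw == EMPTY or raw == "":
        return []
    return [_parse_entry(e) for e in _split_unquoted(raw, "|") if e.strip() != ""]


def _escape(value: str) -> str:
    """Quote a sub-field iff it contains reserved characters, would be
    whitespace-trimmed on read, or could be misread as the empty sentinel
    (strict-out)."""
    if (
        value == ""
        or value == EMPTY
        or value != value.strip()
        or any(c in RESERVED or c == ":" for c in value)
    ):
        return '"' + value.replace("\\", "\\\\").replace('"', '\\"') + '"'
    return value


def format_mitab_field(fields: list[MitabField]) -> str:
    if not fields:
        return EMPTY
    out = []
    for f in fields:
        s = f"{_escape(f.db)}:{_escape(f.identifier)}"
        if f.free_text is not None:
            s += f"({_escape(f.free_text)})"
        out.append(s)
    return "|".join(out)


# ---------------------------------------------------------------------------
# Column <-> model mappings
# ---------------------------------------------------------------------------

def _cv_to_field(term: Optional[CvTerm]) -> list[MitabField]:
    if term is None:
        return []
    if term.mi_identifier:
        return [MitabField("psi-mi", term.mi_identifier, term.short_name)]
    return [MitabField("unknown", term.short_name)]


def _cv_from_fields(fields: list[MitabField]) -> Optional[CvTerm]:
    if not fields:
        return None
    f = fields[0]
    if f.db == "psi-mi" and f.identifier.startswith("MI:"):
        return cv(f.free_text or f.identifier, f.identifier)
    return cv(f.free_text or f.identifier)


def _xrefs_to_fields(xrefs: list[Xref]) -> list[MitabField]:
    return [MitabField(x.database.short_name, x.identifier) for x in xrefs]


def _xrefs_from_fields(fields: list[MitabField]) -> list[Xref]:
    return [Xref(cv(f.db), f.identifier) for f in fields if f.identifier]


def _aliases_to_fields(aliases: list[Alias]) -> list[MitabField]:
    return [
        MitabField("alias", a.name, a.alias_type.short_name if a.alias_type else None)
        for a in aliases
    ]


def _aliases_from_fields(fields: list[MitabField]) -> list[Alias]:
    return [
        Alias(f.identifier, cv(f.free_text) if f.free_text else None)
        for f in fields
        if f.identifier
    ]


def _organism_to_fields(org: Optional[Organism]) -> list[MitabField]:
    if org is None:
        return []
    out = [MitabField("taxid", str(org.taxid), org.common_name)]
    if org.scientific_name:
        out.append(MitabField("taxid", str(org.taxid), org.scientific_name))
    return out


def _organism_from_fields(fields: list[MitabField]) -> Optional[Organism]:
    if not fields:
        return None
    taxid = int(fields[0].identifier)
    common = fields[0].free_text
    scientific = fields[1].free_text if len(fields) > 1 else None
    return Organism(taxid=taxid, common_name=common, scientific_name=scientific)


def _annotations_to_fields(annotations: list[Annotation]) -> list[MitabField]:
    return [
        MitabField(a.topic.short_name, a.value if a.value is not None else "")
        for a in annotations
    ]


def _annotations_from_fields(fields: list[MitabField]) -> list[Annotation]:
    return [Annotation(cv(f.db), f.identifier or None) for f in fields]


def _range_token(r: Range) -> str:
    start = str(r.start.coordinate) if r.start.is_determinate() else "?"
    end = str(r.end.coordinate) if r.end.is_determinate() else "?"
    return f"{start}-{end}"


def _parse_range_token(token: str) -> Range:
    token = token.strip()
    if "-" not in token:
        raise MalformedFieldError(f"feature range {token!r} lacks '-'")
    start_s, end_s = token.split("-", 1)

    def pos(s: str) -> Position:
        s = s.strip()
        if s == "?":
            return Position(cv("undetermined", "MI:0339"))
        return Position(cv("certain", "MI:0335"), int(s))

    return Range(pos(start_s), pos(end_s))


def _features_to_fields(features: list[Feature]) -> list[MitabField]:
    out = []
    for f in features:
        db = f.feature_type.short_name if f.feature_type else "unknown"
        ranges = ",".join(_range_token(r) for r in f.ranges) or "?-?"
        text = f.names[0].name if f.names else None
        out.append(MitabField(db, ranges, text))
    return out


def _features_from_fields(fields: list[MitabField]) -> list[Feature]:
    feats = []
    for f in fields:
        ranges = [_parse_range_token(t) for t in f.identifier.split(",") if t.strip()]
        # "?-?" is the writer's stand-in for a feature of unknown position
        if len(ranges) == 1 and not ranges[0].start.is_determinate() and not ranges[0].end.is_determinate():
            ranges = []
        feats.append(
            Feature(
                feature_type=cv(f.db) if f.db != "unknown" else None,
                ranges=ranges,
                names=[Alias(f.free_text)] if f.free_text else [],
            )
        )
    return feats


def _stoich_to_cell(s: Optional[Stoichiometry]) -> str:
    if s is None:
        return EMPTY
    if s.min_value == s.max_value:
        return str(s.min_value)
    return f"{s.min_value},{s.max_value}"


def _stoich_from_cell(cell: str) -> Optional[Stoichiometry]:
    cell = cell.strip()
    if cell in (EMPTY, ""):
        return None
    if "," in cell:
        lo, hi = cell.split(",", 1)
        return Stoichiometry(int(lo), int(hi))
    v = int(cell)
    return Stoichiometry(v, v)


def _cvlist_to_fields(terms: list[CvTerm]) -> list[MitabField]:
    out = []
    for t in terms:
        out.extend(_cv_to_field(t))
    return out


def _cvlist_from_fields(fields: list[MitabField]) -> list[CvTerm]:
    terms = []
    for f in fields:
        t = _cv_from_fields([f])
        if t is not None:
            terms.append(t)
    return terms


def _interactor_id_fields(interactor: Interactor) -> list[MitabField]:
    pid = interactor.preferred_id
    return [MitabField(pid.database.short_name, pid.identifier)]


def _interactor_from_columns(
    id_fields: list[MitabField],
    alt_fields: list[MitabField],
    alias_fields: list[MitabField],
    tax_fields: list[MitabField],
    type_fields: list[MitabField],
    xref_fields: list[MitabField],
    annot_fields: list[MitabField],
) -> Interactor:
    if not id_fields:
        raise MalformedFieldError("interactor id column is empty")
    pid = Xref(cv(id_fields[0].db), id_fields[0].identifier)
    itype = _cv_from_fields(type_fields) or cv("unknown participant", "MI:0329")
    return Interactor(
        preferred_id=pid,
        interactor_type=itype,
        alternative_ids=_xrefs_from_fields(alt_fields),
        aliases=_aliases_from_fields(alias_fields),
        organism=_organism_from_fields(tax_fields),
        xrefs=_xrefs_from_fields(xref_fields),
        annotations=_annotations_from_fields(annot_fields),
    )


# ---------------------------------------------------------------------------
# Row <-> BinaryInteraction
# ---------------------------------------------------------------------------

def _row_to_interaction(cells: list[str], version: str) -> BinaryInteraction:
    n = COLUMN_COUNTS[version]
    # columns that are free text / plain values, not db:id(text) grammar
    plain = {7, 30, 31, 35, 38, 39}
    col = [
        parse_mitab_field(cells[i]) if (i < n and i not in plain) else []
        for i in range(42)
    ]

    self_interaction = cells[1].strip() in (EMPTY, "")

    def col26(i: int) -> list[MitabField]:
        return col[i] if version in ("2.6", "2.7") else []

    def col27(i: int) -> list[MitabField]:
        return col[i] if version == "2.7" else []

    interactor_a = _interactor_from_columns(
        col[0], col[2], col[4], col[9], col26(20), col26(22), col26(25)
    )
    if self_interaction:
        import copy as _copy

        interactor_b = _copy.deepcopy(interactor_a)
    else:
        interactor_b = _interactor_from_columns(
            col[1], col[3], col[5], col[10], col26(21), col26(23), col26(26)
        )

    part_a = Participant(
        interactor=interactor_a,
        biological_role=_cv_from_fields(col26(16)),
        experimental_role=_cv_from_fields(col26(18)),
        features=_features_from_fields(col27(36)),
        stoichiometry=_stoich_from_cell(cells[38]) if version == "2.7" else None,
        identification_methods=_cvlist_from_fields(col27(40)),
    )
    part_b = Participant(
        interactor=interactor_b,
        biological_role=_cv_from_fields(col26(17)) if not self_interaction else _cv_from_fields(col26(16)),
        experimental_role=_cv_from_fields(col26(19)) if not self_interaction else _cv_from_fields(col26(18)),
        features=_features_from_fields(col27(37)),
        stoichiometry=_stoich_from_cell(cells[39]) if version == "2.7" else None,
        identification_methods=_cvlist_from_fields(col27(41)),
    )

    publication = None
    pub_ids = col[8]
    # the first-author column is free text, not db:id grammar
    authors = [] if cells[7].strip() in (EMPTY, "") else [_unquote(cells[7].strip())]
    source = _cv_from_fields(col[12])
    if pub_ids or authors or source:
        pubmed = next((f.identifier for f in pub_ids if f.db == "pubmed"), None)
        doi = next((f.identifier for f in pub_ids if f.db == "doi"), None)
        others = [
            Xref(cv(f.db), f.identifier)
            for f in pub_ids
            if f.db not in ("pubmed", "doi")
        ]
        publication = Publication(
            pubmed_id=pubmed,
            doi=doi,
            authors=authors,
            source=source,
            identifiers=others,
            title=None if (pubmed or doi or others) else (authors[0] if authors else None),
        )

    detection = _cv_from_fields(col[6])
    host = _organism_from_fields(col26(28))
    experiment = None
    if detection or publication or host:
        experiment = Experiment(
            detection_method=detection, publication=publication, host_organism=host
        )

    interaction_id = col[13][0].identifier if col[13] else None
    negative = cells[35].strip().lower() == "true" if version in ("2.6", "2.7") else False

    return BinaryInteraction(
        participants=[part_a, part_b],
        id=interaction_id,
        interaction_type=_cv_from_fields(col[11]),
        experiment=experiment,
        confidences=[(cv(f.db), f.identifier) for f in col[14]],
        parameters=[(cv(f.db), f.identifier) for f in col26(29)],
        is_negative=negative,
        xrefs=_xrefs_from_fields(col26(24)),
        annotations=_annotations_from_fields(col26(27)),
        checksums=[(f.db, f.identifier) for f in col26(34)],
        complex_expansion=_cv_from_fields(col26(15)),
    )


def _interaction_to_row(bi: BinaryInteraction, version: str, report: ParseReport) -> list[str]:
    a, b = bi.participant_a, bi.participant_b
    exp = bi.experiment
    pub = exp.publication if exp else None

    pub_id_fields: list[MitabField] = []
    if pub:
        if pub.pubmed_id:
            pub_id_fields.append(MitabField("pubmed", pub.pubmed_id))
        if pub.doi:
            pub_id_fields.append(MitabField("doi", pub.doi))
        pub_id_fields.extend(_xrefs_to_fields(pub.identifiers))

    cells_42 = [
        format_mitab_field(_interactor_id_fields(a.interactor)),
        format_mitab_field(_interactor_id_fields(b.interactor)),
        format_mitab_field(_xrefs_to_fields(a.interactor.alternative_ids)),
        format_mitab_field(_xrefs_to_fields(b.interactor.alternative_ids)),
        format_mitab_field(_aliases_to_fields(a.interactor.aliases)),
        format_mitab_field(_aliases_to_fields(b.interactor.aliases)),
        format_mitab_field(_cv_to_field(exp.detection_method) if exp else []),
        _escape(pub.authors[0]) if pub and pub.authors else EMPTY,
        format_mitab_field(pub_id_fields),
        format_mitab_field(_organism_to_fields(a.interactor.organism)),
        format_mitab_field(_organism_to_fields(b.interactor.organism)),
        format_mitab_field(_cv_to_field(bi.interaction_type)),
        format_mitab_field(_cv_to_field(pub.source) if pub else []),
        format_mitab_field([MitabField("internal", bi.id)] if bi.id else []),
        format_mitab_field([MitabField(c[0].short_name, c[1]) for c in bi.confidences]),
        # -- 2.6 --
        format_mitab_field(_cv_to_field(bi.complex_expansion)),
        format_mitab_field(_cv_to_field(a.biological_role)),
        format_mitab_field(_cv_to_field(b.biological_role)),
        format_mitab_field(_cv_to_field(a.experimental_role)),
        format_mitab_field(_cv_to_field(b.experimental_role)),
        format_mitab_field(_cv_to_field(a.interactor.interactor_type)),
        format_mitab_field(_cv_to_field(b.interactor.interactor_type)),
        format_mitab_field(_xrefs_to_fields(a.interactor.xrefs)),
        format_mitab_field(_xrefs_to_fields(b.interactor.xrefs)),
        format_mitab_field(_xrefs_to_fields(bi.xrefs)),
        format_mitab_field(_annotations_to_fields(a.interactor.annotations)),
        format_mitab_field(_annotations_to_fields(b.interactor.annotations)),
        format_mitab_field(_annotations_to_fields(bi.annotations)),
        format_mitab_field(_organism_to_fields(exp.host_organism) if exp else []),
        format_mitab_field([MitabField(p[0].short_name, p[1]) for p in bi.parameters]),
        EMPTY,  # creation date: not modelled
        EMPTY,  # update date: not modelled
        EMPTY,  # checksum A: not modelled per-interactor
        EMPTY,  # checksum B
        format_mitab_field([MitabField(m, v) for m, v in bi.checksums]),
        "true" if bi.is_negative else "false",
        # -- 2.7 --
        format_mitab_field(_features_to_fields(a.features)),
        format_mitab_field(_features_to_fields(b.features)),
        _stoich_to_cell(a.stoichiometry),
        _stoich_to_cell(b.stoichiometry),
        format_mitab_field(_cvlist_to_fields(a.identification_methods)),
        format_mitab_field(_cvlist_to_fields(b.identification_methods)),
    ]
    if version == "2.5" and bi.is_negative:
        report.add(
            "warning",
            "negative-dropped",
            "MITAB 2.5 has no negative column; the flag was dropped on write",
            locator=bi.id,
        )
    return cells_42[: COLUMN_COUNTS[version]]


# ---------------------------------------------------------------------------
# Public reader / writer
# ---------------------------------------------------------------------------

class MitabReader:
    """Lazy MITAB reader: iterate to obtain BinaryInteractions; row-level
    problems accumulate in :attr:`report` while iteration continues."""

    def __init__(self, source: IO[str] | str, version: Optional[str] = None):
        if isinstance(source, str):
            source = io.StringIO(source)
        self._stream = source
        self.declared_version = version
        self.version: Optional[str] = version
        self.report = ParseReport()

    def __iter__(self) -> Iterator[BinaryInteraction]:
        for line_no, line in enumerate(self._stream, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            if line_no == 1 and line.startswith("#"):
                continue
            cells = line.split("\t")
            if self.version is None:
                self.version = detect_mitab_version(len(cells))
            if len(cells) != COLUMN_COUNTS[self.version]:
                self.report.add(
                    "error",
                    "column-count",
                    f"expected {COLUMN_COUNTS[self.version]} columns for MITAB "
                    f"{self.version}, found {len(cells)}",
                    line=line_no,
                )
                continue
            # pad so 2.5/2.6 rows can be indexed with the 42-column accessors
            padded = cells + [EMPTY] * (42 - len(cells))
            try:
                yield _row_to_interaction(padded, self.version)
            except (MalformedFieldError, ValueError) as exc:
                self.report.add("error", "malformed-field", str(exc), line=line_no)


def read_mitab(
    source: IO[str] | str, version: Optional[str] = None
) -> MitabReader:
    """Open a MITAB stream (file object or text). Version auto-detected from
    the first data row's column count when not declared."""
    return MitabReader(source, version)


def read_mitab_all(
    source: IO[str] | str, version: Optional[str] = None
) -> tuple[list[BinaryInteraction], ParseReport]:
    """Eager convenience wrapper: (interactions, parse report)."""
    reader = read_mitab(source, version)
    records = list(reader)
    return records, reader.report


def write_mitab(
    interactions: Iterable[BinaryInteraction],
    version: str = "2.7",
    stream: Optional[IO[str]] = None,
    report: Optional[ParseReport] = None,
) -> str:
    """Serialize binaries at the given MITAB version.

    Writing a lower version silently truncates to its columns (the model
    fields without a slot are simply not written); the one exception is the
    negative flag at 2.5, which is dropped with a warning in `report`.
    Returns the full text (also written to `stream` when given).
    """
    if version not in COLUMN_COUNTS:
        raise UnsupportedDialectError(
            f"unsupported MITAB version {version!r}; expected one of {VERSIONS}"
        )
    if report is None:
        report = ParseReport()
    n = COLUMN_COUNTS[version]
    lines = ["#" + "\t".join(HEADER_42[:n])]
    for bi in interactions:
        if not isinstance(bi, BinaryInteraction):
            if bi.arity() > 2:
                raise CapabilityError(
                    "MITAB is a binary format: expand n-ary interactions "
                    "(spoke or matrix) before writing"
                )
            # 1- or 2-participant records are natively binary; adopt them
            from .expansion import expand as _expand

            (bi,) = _expand(bi, "none")
        lines.append("\t".join(_interaction_to_row(bi, version, report)))
    text = "\n".join(lines) + "\n"
    if stream is not None:
        stream.write(text)
    return text
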