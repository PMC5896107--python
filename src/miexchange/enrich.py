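"""Enrichment of sparsely annotated records from pluggable fetchers.

The fetcher layer is an abstraction boundary: an enricher only sees the
``fetch(identifier) -> FetcherRecord | None`` contract, never where the
record came from. The implementations shipped here are file-backed — a TSV
table of interactor records standing in for protein/small-molecule
reference databases, and an OBO ontology for CV terms — which keeps the
architecture of a web-service bridge while staying fully offline.

Policies:

* ``fill_only`` — only absent scalar fields are set; a present field that
  disagrees with the fetched value is left untouched and recorded as a
  conflict.
* ``overwrite`` — disagreeing scalar fields are replaced, each replacement
  recorded as a conflict entry.

List fields (aliases, xrefs) are merged set-wise under both policies.
Enrichment never removes information and is idempotent at fixed
fetcher + policy.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Protocol

from .errors import ConfigurationError
from .model import Alias, CvTerm, Interactor, Organism, Publication, Xref, cv


@dataclass
class FetcherRecord:
    """One reference record for an interactor identifier."""

    identifier: str
    full_name: Optional[str] = None
    organism: Optional[Organism] = None
    sequence: Optional[str] = None
    aliases: list[Alias] = field(default_factory=list)
    xrefs: list[Xref] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.identifier:
            raise ValueError("FetcherRecord.identifier must be non-empty")


@dataclass
class EnrichmentReport:
    """What an enrichment pass did: fields filled, conflicts seen, ids missed."""

    fields_filled: list[tuple[str, str]] = field(default_factory=list)  # (locator, field)
    conflicts: list[tuple[str, str, str, str]] = field(default_factory=list)  # (locator, field, existing, fetched)
    misses: list[str] = field(default_factory=list)

    def merge(self, other: "EnrichmentReport") -> None:
        self.fields_filled.extend(other.fields_filled)
        self.conflicts.extend(other.conflicts)
        self.misses.extend(other.misses)


class Fetcher(Protocol):
    def fetch(self, identifier: str) -> Optional[FetcherRecord]: ...


class TsvFetcher:
    """File-backed interactor fetcher: one TSV row per identifier.

    Columns: id, name, taxid, common_name, scientific_name, sequence,
    aliases (``name:type`` ``;``-separated), xrefs (``db:id``
    ``;``-separated). Lines starting with ``#`` are comments.
    """

    def __init__(self, path: str | Path):
        self._records: dict[str, FetcherRecord] = {}
        try:
            with open(path, newline="") as fh:
                reader = csv.reader(fh, delimiter="\t")
                for row in reader:
                    if not row or row[0].startswith("#"):
                        continue
                    self._records[row[0]] = self._parse_row(row)
        except OSError as exc:
            raise ConfigurationError(f"cannot read fetcher table {path}: {exc}") from exc

    @staticmethod
    def _parse_row(row: list[str]) -> FetcherRecord:
        def get(idx: int) -> Optional[str]:
            return row[idx].strip() if idx < len(row) and row[idx].strip() else None

        organism = None
        if get(2):
            organism = Organism(
                taxid=int(row[2]), common_name=get(3), scientific_name=get(4)
            )
        aliases = []
        for token in (get(6) or "").split(";"):
            if token.strip():
                name, _, alias_type = token.partition(":")
                aliases.append(Alias(name, cv(alias_type) if alias_type else None))
        xrefs = []
        for token in (get(7) or "").split(";"):
            if token.strip():
                db, _, ident = token.partition(":")
                xrefs.append(Xref(cv(db), ident))
        return FetcherRecord(
            identifier=row[0],
            full_name=get(1),
            organism=organism,
            sequence=get(5),
            aliases=aliases,
            xrefs=xrefs,
        )

    def fetch(self, identifier: str) -> Optional[FetcherRecord]:
        return self._records.get(identifier)

    def __len__(self) -> int:
        return len(self._records)


class OboCvFetcher:
    """Ontology-backed CV term lookup over a local OBO file.

    Resolves by accession (``MI:NNNN``) or, case-insensitively, by term
    name.
    """

    def __init__(self, path: str | Path):
        import obonet

        try:
            self.graph = obonet.read_obo(str(path))
        except OSError as exc:
            raise ConfigurationError(f"cannot read OBO file {path}: {exc}") from exc
        self._by_name = {
            data["name"].lower(): term_id
            for term_id, data in self.graph.nodes(data=True)
            if "name" in data
        }

    def lookup(self, term: CvTerm) -> Optional[tuple[str, str]]:
        """Resolve a term to (accession, canonical name), or None."""
        if term.mi_identifier and term.mi_identifier in self.graph.nodes:
            return term.mi_identifier, self.graph.nodes[term.mi_identifier]["name"]
        term_id = self._by_name.get(term.short_name.lower())
        if term_id is not None:
            return term_id, self.graph.nodes[term_id]["name"]
        return None


def packaged_fetcher() -> TsvFetcher:
    """The fixture interactor fetcher shipped with the package."""
    with resources.as_file(
        resources.files("miexchange.data").joinpath("fetcher-records.tsv")
    ) as path:
        return TsvFetcher(path)


def packaged_cv_fetcher() -> OboCvFetcher:
    """CV fetcher over the packaged mini ontology."""
    with resources.as_file(
        resources.files("miexchange.data").joinpath("mi-mini.obo")
    ) as path:
        return OboCvFetcher(path)


# ---------------------------------------------------------------------------
# Enrichers
# ---------------------------------------------------------------------------

def _merge_aliases(existing: list[Alias], fetched: list[Alias]) -> list[str]:
    have = {(a.name, a.alias_type.short_name if a.alias_type else None) for a in existing}
    added = []
    for a in fetched:
        key = (a.name, a.alias_type.short_name if a.alias_type else None)
        if key not in have:
            existing.append(Alias(a.name, a.alias_type))
            have.add(key)
            added.append(a.name)
    return added


def _merge_xrefs(existing: list[Xref], fetched: list[Xref]) -> list[str]:
    have = {x.key() for x in existing}
    added = []
    for x in fetched:
        if x.key() not in have:
            existing.append(Xref(x.database, x.identifier, x.version, x.qualifier))
            have.add(x.key())
            added.append(x.key())
    return added


def enrich_interactor(
    interactor: Interactor,
    fetcher: Fetcher,
    policy: str = "fill_only",
) -> EnrichmentReport:
    """Enrich one interactor in place from a fetcher; returns the report.

    Scalar candidate fields: full name (stored as a "full name" alias),
    organism, sequence. List fields merged set-wise: aliases, xrefs.
    """
    if policy not in ("fill_only", "overwrite"):
        raise ValueError(f"unknown enrichment policy {policy!r}")
    report = EnrichmentReport()
    locator = interactor.preferred_id.key()
    record = fetcher.fetch(interactor.preferred_id.identifier)
    if record is None:
        report.misses.append(interactor.preferred_id.identifier)
        return report

    def scalar(fieldname: str, existing, fetched, setter, render=str) -> None:
        if fetched is None:
            return
        if existing is None:
            setter(fetched)
            report.fields_filled.append((locator, fieldname))
        elif render(existing) != render(fetched):
            report.conflicts.append((locator, fieldname, render(existing), render(fetched)))
            if policy == "overwrite":
                setter(fetched)

    def set_organism(value: Organism) -> None:
        interactor.organism = Organism(value.taxid, value.common_name, value.scientific_name)

    def set_sequence(value: str) -> None:
        interactor.sequence = value

    scalar(
        "organism",
        interactor.organism,
        record.organism,
        set_organism,
        render=lambda o: str(o.taxid),
    )
    scalar("sequence", interactor.sequence, record.sequence, set_sequence)

    if record.full_name:
        full_name_alias = next(
            (a for a in interactor.aliases
             if a.alias_type is not None and a.alias_type.short_name == "full name"),
            None,
        )
        if full_name_alias is None:
            interactor.aliases.append(Alias(record.full_name, cv("full name")))
            report.fields_filled.append((locator, "full_name"))
        elif full_name_alias.name != record.full_name:
            report.conflicts.append(
                (locator, "full_name", full_name_alias.name, record.full_name)
            )
            if policy == "overwrite":
                full_name_alias.name = record.full_name

    for name in _merge_aliases(interactor.aliases, record.aliases):
        report.fields_filled.append((locator, f"alias:{name}"))
    for key in _merge_xrefs(interactor.xrefs, record.xrefs):
        report.fields_filled.append((locator, f"xref:{key}"))
    return report


def enrich_cvterm(term: CvTerm, ontology_fetcher: OboCvFetcher) -> EnrichmentReport:
    """Fill a CV term's accession, canonical short name and full name from
    the loaded ontology. Idempotent; unknown terms are recorded as misses."""
    report = EnrichmentReport()
    locator = term.key()
    hit = ontology_fetcher.lookup(term)
    if hit is None:
        report.misses.append(locator)
        return report
    accession, canonical = hit
    if term.mi_identifier is None:
        term.mi_identifier = accession
        report.fields_filled.append((locator, "mi_identifier"))
    if term.short_name != canonical:
        # canonical spelling always wins: the ontology is authoritative for
        # names, so this counts as a fill rather than a conflict
        old = term.short_name
        term.short_name = canonical
        report.fields_filled.append((locator, f"short_name:{old}->{canonical}"))
    if term.full_name is None:
        term.full_name = canonical
        report.fields_filled.append((locator, "full_name"))
    return report


def enrich_publication(
    publication: Publication, record: Optional[Publication]
) -> EnrichmentReport:
    """Same fill pattern applied to Publication fields (fill-only)."""
    report = EnrichmentReport()
    if record is None:
        locator = publication.pubmed_id or publication.doi or publication.title or "?"
        report.misses.append(str(locator))
        return report
    locator = publication.pubmed_id or record.pubmed_id or "?"
    for name in ("pubmed_id", "doi", "title", "journal", "publication_date"):
        if getattr(publication, name) is None and getattr(record, name) is not None:
            setattr(publication, name, getattr(record, name))
            report.fields_filled.append((locator, name))
    if not publication.authors and record.authors:
        publication.authors = list(record.authors)
        report.fields_filled.append((locator, "authors"))
    return report
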