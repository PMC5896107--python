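"""Structural and CV-usage validation of interaction files.

Two layers, mirroring how a submission pipeline checks a file:

1. :func:`check_syntax` — can the file be parsed at all? Reuses the
   readers' parse reports: wrong column counts, malformed cells, dangling
   XML references, unsupported elements.
2. :func:`check_cv_usage` — are controlled-vocabulary terms real and used
   in the right place? Each :class:`ValidationRule` binds a model slot
   (e.g. ``experiment.detection_method``) to a required ancestor in the
   ontology; a term must exist in the loaded OBO graph and lie inside the
   transitive ``is_a`` closure of that ancestor (self included). ``part_of``
   and other relations are ignored — the MI ontology organises these slots
   purely by ``is_a``.

The default rule set (packaged, YAML) covers detection method, interaction
type, biological/experimental roles and interactor type; rules are data,
not code, so a fuller catalogue can be swapped in.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import yaml

from .errors import ConfigurationError, UnsupportedDialectError
from .mitab import detect_mitab_version, read_mitab
from .model import CvTerm, Interaction, ParseReport
from .xmlio import read_xml

_VALID_LOCATIONS = {
    "experiment.detection_method",
    "interaction.interaction_type",
    "participant.biological_role",
    "participant.experimental_role",
    "participant.identification_methods",
    "interactor.interactor_type",
    "feature.feature_type",
}


@dataclass
class ValidationRule:
    """Require every CV term in `location` to descend from `required_ancestor`."""

    location: str
    required_ancestor: str
    severity: str = "error"

    def __post_init__(self) -> None:
        if self.location not in _VALID_LOCATIONS:
            raise ConfigurationError(
                f"rule location {self.location!r} names no model slot "
                f"(expected one of {sorted(_VALID_LOCATIONS)})"
            )
        if self.severity not in ("error", "warning"):
            raise ConfigurationError(f"rule severity must be error|warning, got {self.severity!r}")


@dataclass
class Finding:
    severity: str
    check: str  # "syntax" | "term-not-found" | "wrong-location"
    locator: str
    message: str

    def as_dict(self) -> dict:
        return {
            "severity": self.severity,
            "check": self.check,
            "locator": self.locator,
            "message": self.message,
        }


@dataclass
class ValidationReport:
    findings: list[Finding] = field(default_factory=list)

    def add(self, severity: str, check: str, locator: str, message: str) -> None:
        self.findings.append(Finding(severity, check, locator, message))

    def extend(self, other: "ValidationReport") -> None:
        self.findings.extend(other.findings)

    def __len__(self) -> int:
        return len(self.findings)

    def __bool__(self) -> bool:
        return bool(self.findings)

    def to_json(self) -> str:
        return json.dumps([f.as_dict() for f in self.findings], indent=2)

    def to_text(self) -> str:
        if not self.findings:
            return "clean: no findings\n"
        lines = [
            f"{f.severity.upper():7s} {f.check:16s} {f.locator}: {f.message}"
            for f in self.findings
        ]
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Rules and ontology loading
# ---------------------------------------------------------------------------

def load_rules(path: Optional[str | Path] = None) -> list[ValidationRule]:
    """Load rules from a YAML file; without a path, the packaged defaults."""
    if path is None:
        text = resources.files("miexchange.data").joinpath("default-rules.yaml").read_text()
    else:
        try:
            text = Path(path).read_text()
        except OSError as exc:
            raise ConfigurationError(f"cannot read rules file {path}: {exc}") from exc
    payload = yaml.safe_load(text)
    if not isinstance(payload, dict) or "rules" not in payload:
        raise ConfigurationError("rules file must contain a top-level 'rules' list")
    return [ValidationRule(**entry) for entry in payload["rules"]]


def load_ontology(path: Optional[str | Path] = None):
    """Load an OBO ontology into a graph; without a path, the packaged
    mini ontology."""
    import obonet

    if path is None:
        with resources.as_file(
            resources.files("miexchange.data").joinpath("mi-mini.obo")
        ) as p:
            return obonet.read_obo(str(p))
    try:
        return obonet.read_obo(str(path))
    except OSError as exc:
        raise ConfigurationError(f"cannot read OBO file {path}: {exc}") from exc


def _isa_ancestors(graph, term_id: str) -> set[str]:
    """Transitive is_a closure of a term, self included (obonet edges point
    child -> parent, keyed by relation)."""
    seen = {term_id}
    stack = [term_id]
    while stack:
        current = stack.pop()
        for _child, parent, key in graph.out_edges(current, keys=True):
            if key == "is_a" and parent not in seen:
                seen.add(parent)
                stack.append(parent)
    return seen


def is_descendant(graph, term_id: str, ancestor_id: str) -> bool:
    """True iff `term_id` lies in the is_a closure under `ancestor_id`
    (a term counts as its own descendant)."""
    return ancestor_id in _isa_ancestors(graph, term_id)


def _resolve(graph, name_index: dict[str, str], term: CvTerm) -> Optional[str]:
    if term.mi_identifier is not None:
        return term.mi_identifier if term.mi_identifier in graph.nodes else None
    return name_index.get(term.short_name.lower())


def _terms_at(interaction: Interaction, location: str):
    """Yield (slot description, CvTerm) for each term a rule's location
    selects within one interaction."""
    kind, _, slot = location.partition(".")
    if kind == "experiment":
        if interaction.experiment is not None:
            term = getattr(interaction.experiment, slot)
            if term is not None:
                yield location, term
    elif kind == "interaction":
        term = getattr(interaction, slot)
        if term is not None:
            yield location, term
    elif kind == "participant":
        for idx, p in enumerate(interaction.participants):
            value = getattr(p, slot)
            terms = value if isinstance(value, list) else [value]
            for term in terms:
                if term is not None:
                    yield f"{location}[{idx}]", term
    elif kind == "interactor":
        for idx, p in enumerate(interaction.participants):
            term = getattr(p.interactor, slot)
            if term is not None:
                yield f"{location}[{idx}]", term
    elif kind == "feature":
        for idx, p in enumerate(interaction.participants):
            for f in p.features:
                if f.feature_type is not None:
                    yield f"{location}[{idx}]", f.feature_type


def check_cv_usage(
    interactions: Iterable[Interaction],
    ontology_graph,
    rules: Optional[list[ValidationRule]] = None,
) -> ValidationReport:
    """Check CV terms against the ontology: existence and location.

    Findings are deterministically ordered by record, then rule order.
    A rule whose required ancestor is absent from the ontology is a
    configuration error, not a finding.
    """
    if rules is None:
        rules = load_rules()
    for rule in rules:
        if rule.required_ancestor not in ontology_graph.nodes:
            raise ConfigurationError(
                f"rule for {rule.location} requires unknown ancestor {rule.required_ancestor}"
            )
    name_index = {
        data["name"].lower(): term_id
        for term_id, data in ontology_graph.nodes(data=True)
        if "name" in data
    }
    report = ValidationReport()
    for idx, interaction in enumerate(interactions):
        locator_base = interaction.id or f"record-{idx + 1}"
        for rule in rules:
            for slot, term in _terms_at(interaction, rule.location):
                term_id = _resolve(ontology_graph, name_index, term)
                if term_id is None:
                    report.add(
                        "error",
                        "term-not-found",
                        f"{locator_base}/{slot}",
                        f"term {term.mi_identifier or term.short_name!r} "
                        "is not in the ontology",
                    )
                elif not is_descendant(ontology_graph, term_id, rule.required_ancestor):
                    ancestor_name = ontology_graph.nodes[rule.required_ancestor].get(
                        "name", rule.required_ancestor
                    )
                    report.add(
                        rule.severity,
                        "wrong-location",
                        f"{locator_base}/{slot}",
                        f"term {term_id} ({term.short_name}) is not a descendant "
                        f"of {rule.required_ancestor} ({ancestor_name})",
                    )
    return report


# ---------------------------------------------------------------------------
# Syntax checking
# ---------------------------------------------------------------------------

def sniff_format(path: str | Path) -> str:
    """Guess "psi-xml" or "mitab" from extension, then content."""
    p = Path(path)
    suffix = p.suffix.lower()
    if suffix == ".xml":
        return "psi-xml"
    if suffix in (".tsv", ".txt", ".mitab", ".tab"):
        return "mitab"
    with open(p, "rb") as fh:
        head = fh.read(512).lstrip()
    return "psi-xml" if head.startswith(b"<") else "mitab"


def _parse_report_to_validation(parse_report: ParseReport, report: ValidationReport) -> None:
    for entry in parse_report.entries:
        locator = entry.locator or (f"line {entry.line}" if entry.line else "?")
        report.add(entry.severity, "syntax", locator, f"{entry.kind}: {entry.message}")


def check_syntax(
    path: str | Path, declared_format: Optional[str] = None
) -> ValidationReport:
    """Structural check of a file on disk; a clean file yields an empty
    report. Returns findings for every row/element the readers could not
    consume."""
    fmt = declared_format or sniff_format(path)
    report = ValidationReport()
    if fmt == "mitab":
        # establish the dialect from the first decidable data row, so a
        # corrupted first row becomes a row-level finding, not a dead stop
        version = None
        with open(path) as fh:
            for line_no, line in enumerate(fh, start=1):
                if not line.strip() or (line_no == 1 and line.startswith("#")):
                    continue
                try:
                    version = detect_mitab_version(len(line.rstrip("\n").split("\t")))
                    break
                except UnsupportedDialectError:
                    continue
        if version is None:
            report.add("error", "syntax", str(path),
                       "no row matches a supported MITAB column count")
            return report
        with open(path) as fh:
            reader = read_mitab(fh, version)
            for _ in reader:
                pass
        _parse_report_to_validation(reader.report, report)
    elif fmt == "psi-xml":
        parse_report = ParseReport()
        with open(path, "rb") as fh:
            try:
                read_xml(fh, report=parse_report)
            except Exception as exc:  # malformed XML / unknown namespace
                report.add("error", "syntax", str(path), str(exc))
                return report
        _parse_report_to_validation(parse_report, report)
    else:
        raise UnsupportedDialectError(f"cannot syntax-check format {fmt!r}")
    return report


def load_interactions(path: str | Path, declared_format: Optional[str] = None) -> list[Interaction]:
    """Read a file into model interactions regardless of dialect (problem
    rows skipped)."""
    fmt = declared_format or sniff_format(path)
    if fmt == "mitab":
        version = None
        with open(path) as fh:
            for line_no, line in enumerate(fh, start=1):
                if not line.strip() or (line_no == 1 and line.startswith("#")):
                    continue
                try:
                    version = detect_mitab_version(len(line.rstrip("\n").split("\t")))
                    break
                except UnsupportedDialectError:
                    continue
        with open(path) as fh:
            return list(read_mitab(fh, version))
    if fmt == "psi-xml":
        with open(path, "rb") as fh:
            return read_xml(fh, report=ParseReport()).interactions()
    raise UnsupportedDialectError(f"cannot read format {fmt!r}")


def check_file(
    path: str | Path,
    ontology_graph=None,
    rules: Optional[list[ValidationRule]] = None,
    declared_format: Optional[str] = None,
) -> ValidationReport:
    """Full validation: syntax findings followed by CV-usage findings."""
    report = check_syntax(path, declared_format)
    if ontology_graph is None:
        ontology_graph = load_ontology()
    interactions = load_interactions(path, declared_format)
    report.extend(check_cv_usage(interactions, ontology_graph, rules))
    return report
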