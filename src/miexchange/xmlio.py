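"""PSI-MI XML reader and writer (2.5 entry sets, with the 3.0 deltas:
dual publication representation and abstract interactions).

A document is an ``entrySet`` of ``entry`` elements; each entry may carry
top-level experiment and interactor lists that interactions point into by
numeric id (*compact* style), or every definition may be inlined at its
point of use (*expanded* style). Both styles read into identical model
objects, and the writer offers both.

Version handling:

* **2.5** — experimental evidences only; an experiment's ``bibref`` is
  either a cross-reference (pubmed/doi) or an inline attribute list, never
  both; no abstract interactions.
* **3.0** — a ``bibref`` may carry the cross-reference *and* the inline
  attributes on the same experiment (both land in one
  :class:`~miexchange.model.Publication`), and curated complexes are
  written as ``abstractInteraction`` elements. Cooperative effects, causal
  statements and variable parameters are out of scope: the reader reports
  them as unsupported elements rather than silently dropping them.

Writer ids are dense, deterministic, document-local sequential integers.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from datetime import date
from typing import IO, Optional

from lxml import etree

from .errors import CapabilityError, DanglingReferenceError, UnsupportedDialectError
from .model import (
    Alias,
    Annotation,
    BinaryInteraction,
    ComplexRecord,
    CvTerm,
    Experiment,
    Feature,
    Interaction,
    Interactor,
    Organism,
    ParseReport,
    Participant,
    Position,
    Publication,
    Range,
    Stoichiometry,
    Xref,
    cv,
)

NS_25 = "http://psi.hupo.org/mi/mif"
NS_30 = "http://psi.hupo.org/mi/mif300"
VERSION_NS = {"2.5": NS_25, "3.0": NS_30}
LEVELS = {"2.5": ("2", "5"), "3.0": ("3", "0")}

# 3.0 constructs outside this library's scope: reported, never silently dropped
UNSUPPORTED_30 = ("cooperativeEffectList", "causalRelationshipList", "variableParameterList")


@dataclass
class Entry:
    """One entry of an entry set: a source plus its interaction records."""

    interactions: list[Interaction] = field(default_factory=list)
    complexes: list[ComplexRecord] = field(default_factory=list)
    source: Optional[CvTerm] = None


@dataclass
class EntrySet:
    entries: list[Entry] = field(default_factory=list)
    version: str = "2.5"

    def interactions(self) -> list[Interaction]:
        return [i for e in self.entries for i in e.interactions]

    def complexes(self) -> list[ComplexRecord]:
        return [c for e in self.entries for c in e.complexes]


def _local(el) -> str:
    return etree.QName(el).localname


def _children(el, name: str):
    return [c for c in el if isinstance(c.tag, str) and _local(c) == name]


def _child(el, name: str):
    found = _children(el, name)
    return found[0] if found else None


def _text(el) -> Optional[str]:
    if el is None or el.text is None:
        return None
    t = el.text.strip()
    return t or None


# ---------------------------------------------------------------------------
# Writer
# ---------------------------------------------------------------------------

class _IdCounter:
    def __init__(self) -> None:
        self._next = 1

    def take(self) -> int:
        v = self._next
        self._next += 1
        return v


class _XmlWriter:
    def __init__(self, version: str, style: str):
        if version not in VERSION_NS:
            raise UnsupportedDialectError(f"unsupported PSI-MI XML version {version!r}")
        if style not in ("compact", "expanded"):
            raise ValueError(f"style must be 'compact' or 'expanded', got {style!r}")
        self.version = version
        self.style = style
        self.ns = VERSION_NS[version]
        self.ids = _IdCounter()

    def q(self, tag: str) -> str:
        return f"{{{self.ns}}}{tag}"

    def el(self, parent, tag: str, text: Optional[str] = None, **attrs):
        node = etree.SubElement(parent, self.q(tag), {k: v for k, v in attrs.items() if v is not None})
        if text is not None:
            node.text = text
        return node

    # -- shared leaf builders ------------------------------------------------

    def names_el(self, parent, short: Optional[str], full: Optional[str] = None,
                 aliases: Optional[list[Alias]] = None):
        if not (short or full or aliases):
            return None
        names = self.el(parent, "names")
        if short:
            self.el(names, "shortLabel", short)
        if full:
            self.el(names, "fullName", full)
        for a in aliases or []:
            self.el(names, "alias", a.name,
                    type=a.alias_type.short_name if a.alias_type else None)
        return names

    def xref_el(self, parent, primary: Optional[Xref], secondary: list[tuple[Xref, Optional[str]]]):
        """<xref> with a primaryRef and (xref, refType) secondaries."""
        if primary is None and not secondary:
            return None
        xr = self.el(parent, "xref")
        refs = ([("primaryRef", primary, "identity")] if primary else []) + [
            ("secondaryRef", x, rt) for x, rt in secondary
        ]
        if primary is None:
            # promote the first secondary to primaryRef: schema requires one
            tag, x, rt = refs[0]
            refs[0] = ("primaryRef", x, rt)
        for tag, x, rt in refs:
            self.el(xr, tag, db=x.database.short_name, id=x.identifier,
                    version=x.version, refType=rt)
        return xr

    def cv_el(self, parent, tag: str, term: Optional[CvTerm]):
        if term is None:
            return None
        node = self.el(parent, tag)
        self.names_el(node, term.short_name, term.full_name)
        if term.mi_identifier or term.xrefs:
            primary = (
                Xref(cv("psi-mi", "MI:0488"), term.mi_identifier)
                if term.mi_identifier
                else None
            )
            self.xref_el(node, primary, [(x, None) for x in term.xrefs])
        return node

    def organism_el(self, parent, tag: str, org: Optional[Organism]):
        if org is None:
            return None
        node = self.el(parent, tag, ncbiTaxId=str(org.taxid))
        self.names_el(node, org.common_name, org.scientific_name)
        return node

    def attributes_el(self, parent, annotations: list[Annotation],
                      extra: Optional[list[tuple[str, str]]] = None):
        items = [(a.topic.short_name, a.topic.mi_identifier, a.value) for a in annotations]
        items += [(name, None, value) for name, value in (extra or [])]
        if not items:
            return None
        al = self.el(parent, "attributeList")
        for name, ac, value in items:
            self.el(al, "attribute", value, name=name, nameAc=ac)
        return al

    # -- structural builders -------------------------------------------------

    def interactor_el(self, parent, interactor: Interactor, xid: int):
        node = self.el(parent, "interactor", id=str(xid))
        self.names_el(node, interactor.preferred_id.identifier, None, interactor.aliases)
        secondary = [(x, "secondary-ac") for x in interactor.alternative_ids]
        secondary += [(x, None) for x in interactor.xrefs]
        self.xref_el(node, interactor.preferred_id, secondary)
        self.cv_el(node, "interactorType", interactor.interactor_type)
        self.organism_el(node, "organism", interactor.organism)
        if interactor.sequence:
            self.el(node, "sequence", interactor.sequence)
        self.attributes_el(node, interactor.annotations)
        return node

    def publication_bibref_el(self, parent, pub: Publication):
        bibref = self.el(parent, "bibref")
        refs: list[tuple[Xref, Optional[str]]] = []
        primary = None
        if pub.pubmed_id:
            primary = Xref(cv("pubmed", "MI:0446"), pub.pubmed_id)
        if pub.doi:
            doi_ref = Xref(cv("doi", "MI:0574"), pub.doi)
            if primary is None:
                primary = doi_ref
            else:
                refs.append((doi_ref, None))
        refs += [(x, None) for x in pub.identifiers]
        has_xref = primary is not None or refs
        inline = pub.has_inline_attributes() or pub.publication_date is not None

        write_xref = has_xref
        write_attrs = inline and (self.version == "3.0" or not has_xref)
        if write_xref:
            self.xref_el(bibref, primary, refs)
        if write_attrs:
            extra: list[tuple[str, str]] = []
            if pub.title:
                extra.append(("publication title", pub.title))
            if pub.journal:
                extra.append(("journal", pub.journal))
            if pub.authors:
                extra.append(("author-list", "; ".join(pub.authors)))
            if pub.publication_date:
                extra.append(("publication date", pub.publication_date.isoformat()))
            self.attributes_el(bibref, [], extra)
        return bibref

    def experiment_el(self, parent, exp: Experiment, xid: int):
        node = self.el(parent, "experimentDescription", id=str(xid))
        if exp.publication is not None:
            self.publication_bibref_el(node, exp.publication)
        if exp.xrefs:
            self.xref_el(node, None, [(x, None) for x in exp.xrefs])
        if exp.host_organism is not None:
            holist = self.el(node, "hostOrganismList")
            self.organism_el(holist, "hostOrganism", exp.host_organism)
        self.cv_el(node, "interactionDetectionMethod", exp.detection_method)
        self.attributes_el(node, exp.annotations)
        return node

    def feature_el(self, parent, feat: Feature):
        node = self.el(parent, "feature", id=str(self.ids.take()))
        if feat.names:
            self.names_el(node, feat.names[0].name, None, feat.names[1:])
        self.cv_el(node, "featureType", feat.feature_type)
        self.cv_el(node, "featureDetectionMethod", feat.detection_method)
        if feat.ranges:
            rl = self.el(node, "featureRangeList")
            for r in feat.ranges:
                fr = self.el(rl, "featureRange")
                self.cv_el(fr, "startStatus", r.start.status)
                if r.start.is_determinate():
                    self.el(fr, "begin", position=str(r.start.coordinate))
                self.cv_el(fr, "endStatus", r.end.status)
                if r.end.is_determinate():
                    self.el(fr, "end", position=str(r.end.coordinate))
                if r.is_link:
                    self.el(fr, "isLink", "true")
        return node

    def participant_el(self, parent, part: Participant,
                       interactor_ids: Optional[dict[str, int]]):
        node = self.el(parent, "participant", id=str(self.ids.take()))
        if part.xrefs:
            self.xref_el(node, None, [(x, None) for x in part.xrefs])
        if interactor_ids is not None:  # compact
            key = part.interactor.preferred_id.key()
            self.el(node, "interactorRef", str(interactor_ids[key]))
        else:
            self.interactor_el(node, part.interactor, self.ids.take())
        if part.identification_methods:
            ml = self.el(node, "participantIdentificationMethodList")
            for m in part.identification_methods:
                self.cv_el(ml, "participantIdentificationMethod", m)
        self.cv_el(node, "biologicalRole", part.biological_role)
        if part.experimental_role is not None:
            rl = self.el(node, "experimentalRoleList")
            self.cv_el(rl, "experimentalRole", part.experimental_role)
        if part.features:
            fl = self.el(node, "featureList")
            for f in part.features:
                self.feature_el(fl, f)
        extra = []
        if part.stoichiometry is not None:
            if self.version == "3.0":
                s = part.stoichiometry
                if s.min_value == s.max_value:
                    self.el(node, "stoichiometry", value=str(s.min_value))
                else:
                    self.el(node, "stoichiometryRange",
                            minValue=str(s.min_value), maxValue=str(s.max_value))
            else:
                s = part.stoichiometry
                token = str(s.min_value) if s.min_value == s.max_value else f"{s.min_value},{s.max_value}"
                extra.append(("stoichiometry", token))
        self.attributes_el(node, part.annotations, extra)
        return node

    def interaction_el(self, parent, interaction: Interaction,
                       experiment_ids: Optional[dict[int, int]],
                       interactor_ids: Optional[dict[str, int]]):
        node = self.el(parent, "interaction", id=str(self.ids.take()))
        if interaction.id:
            self.names_el(node, interaction.id)
        if interaction.xrefs:
            self.xref_el(node, None, [(x, None) for x in interaction.xrefs])
        if interaction.experiment is not None:
            elist = self.el(node, "experimentList")
            if experiment_ids is not None:
                self.el(elist, "experimentRef", str(experiment_ids[id(interaction.experiment)]))
            else:
                self.experiment_el(elist, interaction.experiment, self.ids.take())
        plist = self.el(node, "participantList")
        for p in interaction.participants:
            self.participant_el(plist, p, interactor_ids)
        self.cv_el(node, "interactionType", interaction.interaction_type)
        if interaction.is_negative:
            self.el(node, "negative", "true")
        if interaction.confidences:
            cl = self.el(node, "confidenceList")
            for term, value in interaction.confidences:
                conf = self.el(cl, "confidence")
                self.cv_el(conf, "unit", term)
                self.el(conf, "value", value)
        if interaction.parameters:
            pl = self.el(node, "parameterList")
            for term, value in interaction.parameters:
                self.el(pl, "parameter", value, term=term.short_name,
                        termAc=term.mi_identifier)
        extra = [("checksum", f"{m}:{v}") for m, v in interaction.checksums]
        expansion = getattr(interaction, "complex_expansion", None)
        if expansion is not None:
            extra.append(("complex expansion", expansion.short_name))
        self.attributes_el(node, interaction.annotations, extra)
        return node

    def complex_el(self, parent, rec: ComplexRecord):
        node = self.el(parent, "abstractInteraction", id=str(self.ids.take()))
        self.names_el(node, rec.recommended_name)
        if rec.xrefs:
            self.xref_el(node, None, [(x, None) for x in rec.xrefs])
        plist = self.el(node, "participantList")
        for p in rec.participants:
            self.participant_el(plist, p, None)
        self.cv_el(node, "evidenceType", rec.evidence_type)
        self.organism_el(node, "organism", rec.organism)
        self.attributes_el(node, rec.annotations)
        return node

    # -- document ------------------------------------------------------------

    def write(self, entry_set: EntrySet) -> etree._Element:
        level, minor = LEVELS[self.version]
        root = etree.Element(self.q("entrySet"), nsmap={None: self.ns})
        root.set("level", level)
        root.set("version", minor)
        for entry in entry_set.entries:
            self.entry_el(root, entry)
        return root

    def entry_el(self, parent, entry: Entry):
        node = self.el(parent, "entry")
        if entry.source is not None:
            src = self.el(node, "source")
            self.names_el(src, entry.source.short_name, entry.source.full_name)
        if entry.complexes and self.version != "3.0":
            raise CapabilityError(
                "abstract interactions (complexes) require PSI-MI XML 3.0; "
                "downgrade to a plain n-ary interaction explicitly if 2.5 output is needed"
            )
        experiment_ids: Optional[dict[int, int]] = None
        interactor_ids: Optional[dict[str, int]] = None
        if self.style == "compact":
            experiment_ids = {}
            experiments = []
            for i in entry.interactions:
                if i.experiment is not None and id(i.experiment) not in experiment_ids:
                    experiment_ids[id(i.experiment)] = self.ids.take()
                    experiments.append(i.experiment)
            if experiments:
                elist = self.el(node, "experimentList")
                for exp in experiments:
                    self.experiment_el(elist, exp, experiment_ids[id(exp)])
            interactor_ids = {}
            interactors = []
            pools = [p for i in entry.interactions for p in i.participants]
            pools += [p for c in entry.complexes for p in c.participants]
            for p in pools:
                key = p.interactor.preferred_id.key()
                if key not in interactor_ids:
                    interactor_ids[key] = self.ids.take()
                    interactors.append(p.interactor)
            if interactors:
                ilist = self.el(node, "interactorList")
                for x in interactors:
                    self.interactor_el(ilist, x, interactor_ids[x.preferred_id.key()])
        if entry.interactions:
            xl = self.el(node, "interactionList")
            for i in entry.interactions:
                self.interaction_el(xl, i, experiment_ids, interactor_ids)
        if entry.complexes:
            cl = self.el(node, "abstractInteractionList")
            for c in entry.complexes:
                self.complex_el(cl, c)
        return node


def write_xml(
    entry_set: EntrySet,
    version: Optional[str] = None,
    style: str = "compact",
    stream: Optional[IO[bytes]] = None,
) -> str:
    """Serialize an entry set at the given version ("2.5" or "3.0") and
    reference style ("compact" or "expanded"). Returns the XML text."""
    version = version or entry_set.version
    writer = _XmlWriter(version, style)
    root = writer.write(entry_set)
    data = etree.tostring(root, pretty_print=True, xml_declaration=True, encoding="UTF-8")
    if stream is not None:
        stream.write(data)
    return data.decode("utf-8")


# ---------------------------------------------------------------------------
# Reader
# ---------------------------------------------------------------------------

class _XmlParser:
    def __init__(self, report: Optional[ParseReport]):
        self.report = report

    # -- leaves --------------------------------------------------------------

    def parse_names(self, el) -> tuple[Optional[str], Optional[str], list[Alias]]:
        names = _child(el, "names")
        if names is None:
            return None, None, []
        short = _text(_child(names, "shortLabel"))
        full = _text(_child(names, "fullName"))
        aliases = [
            Alias(a.text.strip(), cv(a.get("type")) if a.get("type") else None)
            for a in _children(names, "alias")
            if a.text and a.text.strip()
        ]
        return short, full, aliases

    def parse_xref(self, el) -> list[tuple[Xref, Optional[str]]]:
        xr = _child(el, "xref")
        if xr is None:
            return []
        out = []
        for ref in list(_children(xr, "primaryRef")) + list(_children(xr, "secondaryRef")):
            db = ref.get("db") or "unknown"
            ident = ref.get("id")
            if not ident:
                continue
            out.append((Xref(cv(db), ident, version=ref.get("version")), ref.get("refType")))
        return out

    def parse_cv(self, el) -> Optional[CvTerm]:
        if el is None:
            return None
        short, full, _ = self.parse_names(el)
        mi = None
        xrefs = []
        for x, _rt in self.parse_xref(el):
            if x.database.short_name == "psi-mi" and x.identifier.startswith("MI:") and mi is None:
                mi = x.identifier
            else:
                xrefs.append(x)
        term = cv(short or mi or "unknown", mi, full)
        term.xrefs = xrefs
        return term

    def parse_organism(self, el) -> Optional[Organism]:
        if el is None:
            return None
        short, full, _ = self.parse_names(el)
        return Organism(taxid=int(el.get("ncbiTaxId")), common_name=short, scientific_name=full)

    def parse_attributes(self, el) -> list[tuple[str, Optional[str], Optional[str]]]:
        """(name, nameAc, value) triples of the element's attributeList."""
        al = _child(el, "attributeList")
        if al is None:
            return []
        return [
            (a.get("name") or "comment", a.get("nameAc"), _text(a) if a.text else None)
            for a in _children(al, "attribute")
        ]

    # -- structures ----------------------------------------------------------

    def parse_interactor(self, el) -> Interactor:
        short, _full, aliases = self.parse_names(el)
        refs = self.parse_xref(el)
        preferred = None
        alternative: list[Xref] = []
        xrefs: list[Xref] = []
        for x, rt in refs:
            if preferred is None:
                preferred = x
            elif rt == "secondary-ac":
                alternative.append(x)
            else:
                xrefs.append(x)
        if preferred is None:
            preferred = Xref(cv("unknown"), short or "unnamed")
        itype = self.parse_cv(_child(el, "interactorType")) or cv("unknown participant", "MI:0329")
        annotations = [
            Annotation(cv(name, ac), value) for name, ac, value in self.parse_attributes(el)
        ]
        return Interactor(
            preferred_id=preferred,
            interactor_type=itype,
            alternative_ids=alternative,
            aliases=aliases,
            organism=self.parse_organism(_child(el, "organism")),
            sequence=_text(_child(el, "sequence")),
            xrefs=xrefs,
            annotations=annotations,
        )

    def parse_publication(self, el) -> Optional[Publication]:
        bibref = _child(el, "bibref")
        if bibref is None:
            return None
        pubmed = doi = title = journal = None
        authors: list[str] = []
        pub_date = None
        identifiers: list[Xref] = []
        for x, _rt in self.parse_xref(bibref):
            db = x.database.short_name.lower()
            if db == "pubmed" and pubmed is None:
                pubmed = x.identifier
            elif db == "doi" and doi is None:
                doi = x.identifier
            else:
                identifiers.append(x)
        for name, _ac, value in self.parse_attributes(bibref):
            if value is None:
                continue
            if name == "publication title":
                title = value
            elif name == "journal":
                journal = value
            elif name == "author-list":
                authors = [a.strip() for a in value.split(";") if a.strip()]
            elif name == "publication date":
                try:
                    pub_date = date.fromisoformat(value)
                except ValueError:
                    pass
        if not (pubmed or doi or title or identifiers):
            return None
        return Publication(
            pubmed_id=pubmed, doi=doi, title=title, journal=journal,
            authors=authors, publication_date=pub_date, identifiers=identifiers,
        )

    def parse_experiment(self, el) -> Experiment:
        host = None
        holist = _child(el, "hostOrganismList")
        if holist is not None:
            host = self.parse_organism(_child(holist, "hostOrganism"))
        annotations = [
            Annotation(cv(name, ac), value) for name, ac, value in self.parse_attributes(el)
        ]
        xrefs = [x for x, _rt in self.parse_xref(el)]
        return Experiment(
            detection_method=self.parse_cv(_child(el, "interactionDetectionMethod")),
            publication=self.parse_publication(el),
            host_organism=host,
            annotations=annotations,
            xrefs=xrefs,
        )

    def parse_feature(self, el) -> Feature:
        short, _full, aliases = self.parse_names(el)
        names = ([Alias(short)] if short else []) + aliases
        ranges = []
        rl = _child(el, "featureRangeList")
        if rl is not None:
            for fr in _children(rl, "featureRange"):
                start_status = self.parse_cv(_child(fr, "startStatus")) or cv("undetermined", "MI:0339")
                end_status = self.parse_cv(_child(fr, "endStatus")) or cv("undetermined", "MI:0339")
                begin = _child(fr, "begin")
                end = _child(fr, "end")
                ranges.append(
                    Range(
                        Position(start_status, int(begin.get("position")) if begin is not None else None),
                        Position(end_status, int(end.get("position")) if end is not None else None),
                        is_link=_text(_child(fr, "isLink")) == "true",
                    )
                )
        return Feature(
            feature_type=self.parse_cv(_child(el, "featureType")),
            detection_method=self.parse_cv(_child(el, "featureDetectionMethod")),
            ranges=ranges,
            names=names,
        )

    def parse_participant(self, el, interactors: dict[int, Interactor]) -> Participant:
        import copy as _copy

        ref = _child(el, "interactorRef")
        if ref is not None:
            ref_id = int(ref.text.strip())
            if ref_id not in interactors:
                raise DanglingReferenceError(ref_id, "interactor")
            interactor = _copy.deepcopy(interactors[ref_id])
        else:
            inline = _child(el, "interactor")
            if inline is None:
                raise DanglingReferenceError(-1, "interactor")
            interactor = self.parse_interactor(inline)

        exp_role = None
        erl = _child(el, "experimentalRoleList")
        if erl is not None:
            exp_role = self.parse_cv(_child(erl, "experimentalRole"))
        ident_methods = []
        iml = _child(el, "participantIdentificationMethodList")
        if iml is not None:
            ident_methods = [
                self.parse_cv(m) for m in _children(iml, "participantIdentificationMethod")
            ]
        features = []
        fl = _child(el, "featureList")
        if fl is not None:
            features = [self.parse_feature(f) for f in _children(fl, "feature")]

        stoich = None
        st = _child(el, "stoichiometry")
        if st is not None:
            v = int(st.get("value"))
            stoich = Stoichiometry(v, v)
        str_range = _child(el, "stoichiometryRange")
        if str_range is not None:
            stoich = Stoichiometry(int(str_range.get("minValue")), int(str_range.get("maxValue")))

        annotations = []
        for name, ac, value in self.parse_attributes(el):
            if name == "stoichiometry" and value and stoich is None:
                if "," in value:
                    lo, hi = value.split(",", 1)
                    stoich = Stoichiometry(int(lo), int(hi))
                else:
                    stoich = Stoichiometry(int(value), int(value))
            else:
                annotations.append(Annotation(cv(name, ac), value))

        return Participant(
            interactor=interactor,
            biological_role=self.parse_cv(_child(el, "biologicalRole")),
            experimental_role=exp_role,
            identification_methods=[m for m in ident_methods if m],
            features=features,
            stoichiometry=stoich,
            xrefs=[x for x, _rt in self.parse_xref(el)],
            annotations=annotations,
        )

    def parse_interaction(
        self,
        el,
        experiments: dict[int, Experiment],
        interactors: dict[int, Interactor],
    ) -> Interaction:
        import copy as _copy

        short, _full, _aliases = self.parse_names(el)
        experiment = None
        elist = _child(el, "experimentList")
        if elist is not None:
            ref = _child(elist, "experimentRef")
            if ref is not None:
                ref_id = int(ref.text.strip())
                if ref_id not in experiments:
                    raise DanglingReferenceError(ref_id, "experiment")
                experiment = _copy.deepcopy(experiments[ref_id])
            else:
                inline = _child(elist, "experimentDescription")
                if inline is not None:
                    experiment = self.parse_experiment(inline)
        plist = _child(el, "participantList")
        participants = [
            self.parse_participant(p, interactors)
            for p in (_children(plist, "participant") if plist is not None else [])
        ]
        confidences = []
        cl = _child(el, "confidenceList")
        if cl is not None:
            for conf in _children(cl, "confidence"):
                unit = self.parse_cv(_child(conf, "unit")) or cv("unknown")
                confidences.append((unit, _text(_child(conf, "value")) or ""))
        parameters = []
        pl = _child(el, "parameterList")
        if pl is not None:
            for par in _children(pl, "parameter"):
                term = cv(par.get("term") or "unknown", par.get("termAc"))
                parameters.append((term, _text(par) or ""))
        checksums = []
        annotations = []
        expansion = None
        for name, ac, value in self.parse_attributes(el):
            if name == "checksum" and value and ":" in value:
                method, v = value.split(":", 1)
                checksums.append((method, v))
            elif name == "complex expansion" and value:
                expansion = cv(value)
            else:
                annotations.append(Annotation(cv(name, ac), value))

        kwargs = dict(
            participants=participants,
            id=short,
            interaction_type=self.parse_cv(_child(el, "interactionType")),
            experiment=experiment,
            confidences=confidences,
            parameters=parameters,
            is_negative=_text(_child(el, "negative")) == "true",
            xrefs=[x for x, _rt in self.parse_xref(el)],
            annotations=annotations,
            checksums=checksums,
        )
        if expansion is not None and len(participants) == 2:
            return BinaryInteraction(complex_expansion=expansion, **kwargs)
        return Interaction(**kwargs)

    def parse_complex(self, el, interactors: dict[int, Interactor]) -> ComplexRecord:
        short, _full, _aliases = self.parse_names(el)
        plist = _child(el, "participantList")
        participants = [
            self.parse_participant(p, interactors)
            for p in (_children(plist, "participant") if plist is not None else [])
        ]
        annotations = [
            Annotation(cv(name, ac), value) for name, ac, value in self.parse_attributes(el)
        ]
        return ComplexRecord(
            recommended_name=short or "unnamed complex",
            participants=participants,
            evidence_type=self.parse_cv(_child(el, "evidenceType")),
            organism=self.parse_organism(_child(el, "organism")),
            xrefs=[x for x, _rt in self.parse_xref(el)],
            annotations=annotations,
        )

    def parse_entry(self, el, version: str) -> Entry:
        entry = Entry()
        src = _child(el, "source")
        if src is not None:
            short, full, _ = self.parse_names(src)
            if short or full:
                entry.source = cv(short or full, full_name=full)

        experiments: dict[int, Experiment] = {}
        elist = _child(el, "experimentList")
        if elist is not None:
            for e in _children(elist, "experimentDescription"):
                experiments[int(e.get("id"))] = self.parse_experiment(e)
        interactors: dict[int, Interactor] = {}
        ilist = _child(el, "interactorList")
        if ilist is not None:
            for x in _children(ilist, "interactor"):
                interactors[int(x.get("id"))] = self.parse_interactor(x)

        xl = _child(el, "interactionList")
        if xl is not None:
            for i in _children(xl, "interaction"):
                unsupported = [u for u in UNSUPPORTED_30 if _child(i, u) is not None]
                if unsupported:
                    message = (
                        f"unsupported PSI-MI XML 3.0 element(s) {unsupported} "
                        f"in interaction id {i.get('id')}"
                    )
                    if self.report is None:
                        raise CapabilityError(message)
                    self.report.add("error", "unsupported-element", message,
                                    locator=i.get("id"))
                    continue
                try:
                    entry.interactions.append(self.parse_interaction(i, experiments, interactors))
                except DanglingReferenceError:
                    if self.report is None:
                        raise
                    self.report.add(
                        "error", "dangling-reference",
                        f"interaction id {i.get('id')} references an undefined object",
                        locator=i.get("id"),
                    )
        cl = _child(el, "abstractInteractionList")
        if cl is not None:
            for c in _children(cl, "abstractInteraction"):
                entry.complexes.append(self.parse_complex(c, interactors))
        return entry


def detect_xml_version(root) -> str:
    ns = etree.QName(root).namespace
    if ns == NS_30:
        return "3.0"
    if ns == NS_25:
        level = root.get("level")
        if level == "3":
            return "3.0"
        return "2.5"
    raise UnsupportedDialectError(f"unknown PSI-MI XML namespace {ns!r}")


def read_xml(source: IO[bytes] | bytes | str, report: Optional[ParseReport] = None) -> EntrySet:
    """Parse a PSI-MI XML document into an :class:`EntrySet`.

    Version is detected from the root namespace/level attributes. Without a
    `report`, a dangling numeric reference or an unsupported 3.0 construct
    raises; with one, the problem is recorded and the interaction skipped.
    """
    if isinstance(source, str):
        source = source.encode("utf-8")
    if isinstance(source, bytes):
        source = io.BytesIO(source)
    tree = etree.parse(source)
    root = tree.getroot()
    if _local(root) != "entrySet":
        raise UnsupportedDialectError(f"root element is <{_local(root)}>, expected <entrySet>")
    version = detect_xml_version(root)
    parser = _XmlParser(report)
    entries = [parser.parse_entry(e, version) for e in _children(root, "entry")]
    return EntrySet(entries=entries, version=version)
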