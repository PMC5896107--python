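"""PSI-MI XML round trips, reference styles, version deltas."""

import pytest

from miexchange.errors import CapabilityError, DanglingReferenceError, UnsupportedDialectError
from miexchange.model import (
    ComplexRecord,
    Interactor,
    ParseReport,
    Participant,
    Publication,
    Xref,
    cv,
    semantic_equals,
)
from miexchange.xmlio import Entry, EntrySet, read_xml, write_xml
from tests.conftest import make_network


def _participants(ids):
    return [
        Participant(
            interactor=Interactor(
                preferred_id=Xref(cv("uniprotkb"), i),
                interactor_type=cv("protein", "MI:0326"),
            )
        )
        for i in ids
    ]


class TestRoundTrip:
    @pytest.mark.parametrize("version", ["2.5", "3.0"])
    @pytest.mark.parametrize("style", ["compact", "expanded"])
    def test_exact_round_trip(self, version, style):
        for seed in range(5):
            entry_set, _ = make_network("xml25", seed=seed)
            text = write_xml(entry_set, version=version, style=style)
            back = read_xml(text)
            assert back.version == version
            originals, rereads = entry_set.interactions(), back.interactions()
            assert len(rereads) == len(originals)
            for a, b in zip(originals, rereads):
                assert semantic_equals(a, b, "exact")

    @pytest.mark.parametrize("version", ["2.5", "3.0"])
    def test_compact_and_expanded_read_to_equal_models(self, version):
        entry_set, _ = make_network("xml25", seed=17)
        compact = read_xml(write_xml(entry_set, version=version, style="compact"))
        expanded = read_xml(write_xml(entry_set, version=version, style="expanded"))
        for a, b in zip(compact.interactions(), expanded.interactions()):
            assert semantic_equals(a, b, "exact")

    def test_participant_counts_preserved(self):
        for seed in range(10):
            entry_set, _ = make_network("xml30", seed=seed, n_interactions=6)
            for style in ("compact", "expanded"):
                back = read_xml(write_xml(entry_set, style=style))
                assert [i.arity() for i in back.interactions()] == [
                    i.arity() for i in entry_set.interactions()
                ]

    def test_compact_writes_each_distinct_interactor_once(self):
        from miexchange.model import BinaryInteraction

        binary = BinaryInteraction(participants=_participants(["P1", "P2"]))
        text = write_xml(EntrySet(entries=[Entry(interactions=[binary])]), style="compact")
        assert text.count("<interactor ") == 2
        assert text.count("<interactorRef>") == 2


class TestPublicationDuality:
    def _entry_set(self):
        from miexchange.model import BinaryInteraction, Experiment

        pub = Publication(
            pubmed_id="11283351",
            title="Synthetic evidence record",
            journal="J Synth Biol",
            authors=["Smith J", "Jones K"],
        )
        exp = Experiment(detection_method=cv("two hybrid", "MI:0018"), publication=pub)
        binary = BinaryInteraction(participants=_participants(["P1", "P2"]), experiment=exp)
        return EntrySet(entries=[Entry(interactions=[binary])])

    def test_30_reads_xref_and_inline_into_one_publication(self):
        text = write_xml(self._entry_set(), version="3.0")
        assert 'db="pubmed"' in text and "publication title" in text
        (record,) = read_xml(text).interactions()
        pub = record.experiment.publication
        assert pub.pubmed_id == "11283351"
        assert pub.title == "Synthetic evidence record"
        assert pub.journal == "J Synth Biol"
        assert pub.authors == ["Smith J", "Jones K"]

    def test_duality_survives_30_round_trip(self):
        once = read_xml(write_xml(self._entry_set(), version="3.0"))
        twice = read_xml(write_xml(once, version="3.0"))
        pub = twice.interactions()[0].experiment.publication
        assert pub.pubmed_id and pub.has_inline_attributes()

    def test_25_forces_the_choice_xref_wins(self):
        text = write_xml(self._entry_set(), version="2.5")
        assert 'db="pubmed"' in text and "publication title" not in text


class TestErrors:
    DANGLING = """<?xml version="1.0"?>
<entrySet xmlns="http://psi.hupo.org/mi/mif" level="2" version="5">
 <entry>
  <interactorList><interactor id="1"><names><shortLabel>P1</shortLabel></names>
   <xref><primaryRef db="uniprotkb" id="P1"/></xref></interactor></interactorList>
  <interactionList><interaction id="2"><participantList>
   <participant id="3"><interactorRef>99</interactorRef></participant>
   <participant id="4"><interactorRef>1</interactorRef></participant>
  </participantList></interaction></interactionList>
 </entry>
</entrySet>"""

    def test_dangling_reference_names_the_id(self):
        with pytest.raises(DanglingReferenceError, match="99"):
            read_xml(self.DANGLING)

    def test_dangling_reference_collected_into_report(self):
        report = ParseReport()
        entry_set = read_xml(self.DANGLING, report=report)
        assert entry_set.interactions() == []
        assert len(report.errors) == 1
        assert report.errors[0].kind == "dangling-reference"

    def test_unknown_namespace_rejected(self):
        doc = '<entrySet xmlns="http://example.org/not-mi" level="2" version="5"/>'
        with pytest.raises(UnsupportedDialectError):
            read_xml(doc)

    def test_unsupported_30_construct_reported_not_dropped(self):
        doc = """<?xml version="1.0"?>
<entrySet xmlns="http://psi.hupo.org/mi/mif300" level="3" version="0">
 <entry><interactionList>
  <interaction id="1">
   <participantList><participant id="2"><interactor id="3">
     <names><shortLabel>P1</shortLabel></names>
     <xref><primaryRef db="uniprotkb" id="P1"/></xref>
   </interactor></participant></participantList>
   <cooperativeEffectList/>
  </interaction>
 </interactionList></entry>
</entrySet>"""
        with pytest.raises(CapabilityError, match="cooperativeEffectList"):
            read_xml(doc)
        report = ParseReport()
        entry_set = read_xml(doc, report=report)
        assert entry_set.interactions() == []
        assert report.errors[0].kind == "unsupported-element"


class TestComplexes:
    def _record(self):
        return ComplexRecord(
            recommended_name="synthetic trimer",
            participants=_participants(["P1", "P2", "P3"]),
            evidence_type=cv("physical association", "MI:0915"),
        )

    def test_complex_requires_30(self):
        entry_set = EntrySet(entries=[Entry(complexes=[self._record()])])
        with pytest.raises(CapabilityError, match="3.0"):
            write_xml(entry_set, version="2.5")

    def test_complex_round_trips_at_30(self):
        entry_set = EntrySet(entries=[Entry(complexes=[self._record()])], version="3.0")
        back = read_xml(write_xml(entry_set, version="3.0"))
        (record,) = back.complexes()
        assert record.recommended_name == "synthetic trimer"
        assert len(record.participants) == 3
        assert record.evidence_type.mi_identifier == "MI:0915"
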