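"""Validator: syntax reuse of parse reports, CV existence and location."""

from collections import Counter

import pytest

from miexchange import mitab, xmlio
from miexchange.errors import ConfigurationError
from miexchange.generate import GeneratorConfig, corrupt, generate_network
from miexchange.model import Experiment, Interaction, Interactor, Participant, Xref, cv
from miexchange.validate import (
    ValidationRule,
    check_cv_usage,
    check_file,
    check_syntax,
    is_descendant,
    load_rules,
)


def interaction_with(detection=None, itype=None):
    participants = [
        Participant(
            interactor=Interactor(
                preferred_id=Xref(cv("uniprotkb"), f"P{i}"),
                interactor_type=cv("protein", "MI:0326"),
            ),
            experimental_role=cv("bait", "MI:0496") if i == 1 else cv("prey", "MI:0498"),
        )
        for i in (1, 2)
    ]
    return Interaction(
        participants=participants,
        id="t-1",
        interaction_type=itype or cv("direct interaction", "MI:0407"),
        experiment=Experiment(detection_method=detection or cv("two hybrid", "MI:0018")),
    )


class TestOntology:
    def test_isa_closure_includes_self_and_transitive_parents(self, ontology_graph):
        assert is_descendant(ontology_graph, "MI:0018", "MI:0018")
        assert is_descendant(ontology_graph, "MI:0018", "MI:0045")
        assert is_descendant(ontology_graph, "MI:0007", "MI:0001")  # two hops up

    def test_unrelated_terms_are_not_descendants(self, ontology_graph):
        assert not is_descendant(ontology_graph, "MI:0326", "MI:0001")


class TestCvUsage:
    def test_clean_interaction_yields_no_findings(self, ontology_graph):
        report = check_cv_usage([interaction_with()], ontology_graph)
        assert len(report) == 0

    def test_wrong_location_reported_once(self, ontology_graph):
        # an interactor-type accession in the detection-method slot
        bad = interaction_with(detection=cv("protein", "MI:0326"))
        report = check_cv_usage([bad], ontology_graph)
        assert len(report) == 1
        (finding,) = report.findings
        assert finding.check == "wrong-location"
        assert "MI:0326" in finding.message

    def test_unknown_accession_reported_once(self, ontology_graph):
        bad = interaction_with(detection=cv("mystery method", "MI:9999"))
        report = check_cv_usage([bad], ontology_graph)
        assert len(report) == 1
        assert report.findings[0].check == "term-not-found"

    def test_accessionless_term_resolved_by_name(self, ontology_graph):
        ok = interaction_with(detection=cv("two hybrid"))  # no accession
        assert len(check_cv_usage([ok], ontology_graph)) == 0

    def test_rule_with_unknown_ancestor_is_configuration_error(self, ontology_graph):
        rule = ValidationRule("experiment.detection_method", "MI:8888")
        with pytest.raises(ConfigurationError):
            check_cv_usage([interaction_with()], ontology_graph, [rule])

    def test_rule_with_unknown_location_rejected(self):
        with pytest.raises(ConfigurationError):
            ValidationRule("interaction.frobnicator", "MI:0001")

    def test_packaged_rules_load(self):
        rules = load_rules()
        assert {r.location for r in rules} >= {
            "experiment.detection_method",
            "interaction.interaction_type",
        }

    def test_findings_deterministically_ordered(self, ontology_graph):
        bad1 = interaction_with(detection=cv("protein", "MI:0326"))
        bad1.id = "a-1"
        bad2 = interaction_with(detection=cv("mystery", "MI:9999"))
        bad2.id = "a-2"
        first = check_cv_usage([bad1, bad2], ontology_graph)
        second = check_cv_usage([bad1, bad2], ontology_graph)
        assert [f.locator for f in first.findings] == [f.locator for f in second.findings]
        assert first.findings[0].locator.startswith("a-1")


class TestSyntax:
    def test_clean_generated_27_file_is_clean(self, tmp_path):
        entry_set, _ = generate_network(GeneratorConfig.for_dialect("mitab27", seed=1))
        path = tmp_path / "clean.tsv"
        path.write_text(mitab.write_mitab(entry_set.interactions(), "2.7"))
        assert len(check_syntax(path)) == 0

    def test_short_row_in_27_file_is_one_entry(self, tmp_path):
        entry_set, _ = generate_network(GeneratorConfig.for_dialect("mitab27", seed=2))
        text = mitab.write_mitab(entry_set.interactions(), "2.7")
        bad, truth = corrupt(text, {"column-count": 1}, seed=5, fmt="mitab")
        path = tmp_path / "bad.tsv"
        path.write_text(bad)
        report = check_syntax(path)
        assert len(report) == 1
        assert report.findings[0].check == "syntax"
        assert f"line {truth[0]['line']}" == report.findings[0].locator

    def test_dangling_xml_ref_is_one_entry_naming_the_record(self, tmp_path):
        entry_set, _ = generate_network(
            GeneratorConfig.for_dialect("xml25", seed=3, n_interactions=5)
        )
        text = xmlio.write_xml(entry_set, style="compact")
        bad, truth = corrupt(text, {"dangling-ref": 1}, seed=5, fmt="psi-xml")
        path = tmp_path / "bad.xml"
        path.write_text(bad)
        report = check_syntax(path)
        assert len(report) == 1
        assert report.findings[0].check == "syntax"


class TestFullCheck:
    def test_every_injected_corruption_reported_exactly_once(self, tmp_path):
        entry_set, _ = generate_network(
            GeneratorConfig.for_dialect("mitab27", seed=7, n_interactions=20)
        )
        text = mitab.write_mitab(entry_set.interactions(), "2.7")
        spec = {
            "column-count": 3,
            "unbalanced-quote": 3,
            "wrong-location-cv": 3,
            "unknown-cv": 3,
        }
        bad, truth = corrupt(text, spec, seed=11, fmt="mitab")
        path = tmp_path / "bad.tsv"
        path.write_text(bad)
        report = check_file(path)
        assert len(report) == sum(spec.values())
        counts = Counter(f.check for f in report.findings)
        assert counts == {"syntax": 6, "wrong-location": 3, "term-not-found": 3}

    def test_zero_false_positives_on_clean_output_all_dialects(self, tmp_path):
        for dialect, writer in [
            ("mitab25", lambda es: mitab.write_mitab(es.interactions(), "2.5")),
            ("mitab27", lambda es: mitab.write_mitab(es.interactions(), "2.7")),
            ("xml25", lambda es: xmlio.write_xml(es, version="2.5")),
            ("xml30", lambda es: xmlio.write_xml(es, version="3.0")),
        ]:
            entry_set, _ = generate_network(GeneratorConfig.for_dialect(dialect, seed=9))
            path = tmp_path / f"{dialect}.dat"
            path.write_text(writer(entry_set))
            report = check_file(path)
            assert len(report) == 0, f"{dialect}: {report.to_text()}"

    def test_report_serializes_to_json(self, tmp_path, ontology_graph):
        import json

        bad = interaction_with(detection=cv("mystery", "MI:9999"))
        report = check_cv_usage([bad], ontology_graph)
        payload = json.loads(report.to_json())
        assert payload[0]["check"] == "term-not-found"
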