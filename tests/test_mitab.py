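"""MITAB grammar, version detection, reader/writer round trips."""

import pytest
from hypothesis import given, settings, strategies as st

from miexchange import mitab
from miexchange.errors import CapabilityError, MalformedFieldError, UnsupportedDialectError
from miexchange.mitab import (
    MitabField,
    detect_mitab_version,
    format_mitab_field,
    parse_mitab_field,
    read_mitab_all,
    write_mitab,
)
from miexchange.model import semantic_equals
from tests.conftest import make_network


class TestVersionDetection:
    @pytest.mark.parametrize("count,version", [(15, "2.5"), (36, "2.6"), (42, "2.7")])
    def test_known_column_counts(self, count, version):
        assert detect_mitab_version(count) == version

    @pytest.mark.parametrize("count", [1, 14, 17, 37, 43])
    def test_other_counts_rejected_naming_the_count(self, count):
        with pytest.raises(UnsupportedDialectError, match=str(count)):
            detect_mitab_version(count)


class TestFieldGrammar:
    def test_plain_db_id(self):
        (f,) = parse_mitab_field("uniprotkb:P12345")
        assert (f.db, f.identifier, f.free_text) == ("uniprotkb", "P12345", None)

    def test_empty_sentinel(self):
        assert parse_mitab_field("-") == []

    def test_quoted_identifier_with_free_text(self):
        (f,) = parse_mitab_field('psi-mi:"MI:0407"(direct interaction)')
        assert (f.db, f.identifier, f.free_text) == ("psi-mi", "MI:0407", "direct interaction")

    def test_multiple_entries_split_on_pipes(self):
        fields = parse_mitab_field("pubmed:123|doi:10.1/x")
        assert [(f.db, f.identifier) for f in fields] == [("pubmed", "123"), ("doi", "10.1/x")]

    def test_pipe_inside_quotes_not_a_separator(self):
        (f,) = parse_mitab_field('db:"a|b"')
        assert f.identifier == "a|b"

    @pytest.mark.parametrize("raw", ['db:"unclosed', "db:id(unclosed", "db:id)extra("])
    def test_unbalanced_quote_or_paren_rejected(self, raw):
        with pytest.raises(MalformedFieldError):
            parse_mitab_field(raw)

    @given(
        st.lists(
            st.tuples(
                st.text(alphabet='ab|:()" \t', min_size=1, max_size=8),
                st.text(alphabet='cd|:()" \t', min_size=1, max_size=8),
                st.one_of(st.none(), st.text(alphabet='ef|:()" ', max_size=8)),
            ),
            min_size=0,
            max_size=4,
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_format_parse_inverse_under_escaping(self, triples):
        fields = [MitabField(db, ident, text) for db, ident, text in triples]
        cell = format_mitab_field(fields)
        back = parse_mitab_field(cell)
        assert [(f.db, f.identifier, f.free_text) for f in back] == [
            (f.db, f.identifier, f.free_text) for f in fields
        ]


MINI_25 = (
    "#header\n"
    "uniprotkb:P1\tuniprotkb:P2\t-\t-\t-\t-\t-\t-\t-\t-\t-\t-\t-\t-\t-\n"
    "uniprotkb:P3\tuniprotkb:P4\t-\t-\t-\t-\t-\t-\t-\t-\t-\t-\t-\t-\t-\n"
)


class TestReader:
    def test_two_row_25_fixture(self):
        records, report = read_mitab_all(MINI_25)
        assert not report
        ids = [
            (
                r.participant_a.interactor.preferred_id.identifier,
                r.participant_b.interactor.preferred_id.identifier,
            )
            for r in records
        ]
        assert ids == [("P1", "P2"), ("P3", "P4")]

    def test_header_is_optional(self):
        records, report = read_mitab_all(MINI_25.split("\n", 1)[1])
        assert len(records) == 2 and not report

    def test_empty_stream(self):
        records, report = read_mitab_all("")
        assert records == [] and not report

    def test_self_interaction_dash_convention(self):
        row = "uniprotkb:P9\t-" + "\t-" * 13
        (record,), report = read_mitab_all(row)
        assert not report
        assert record.is_self_interaction()
        assert record.participant_b.interactor.preferred_id.identifier == "P9"

    def test_feature_column_yields_range(self):
        cells = ["uniprotkb:A", "uniprotkb:B"] + ["-"] * 40
        cells[36] = "binding-associated region:1-10"
        (record,), report = read_mitab_all("\t".join(cells))
        assert not report
        (feature,) = record.participant_a.features
        assert feature.feature_type.short_name == "binding-associated region"
        (rng,) = feature.ranges
        assert (rng.start.coordinate, rng.end.coordinate) == (1, 10)

    def test_bad_row_collected_and_reader_continues(self):
        text = MINI_25 + "uniprotkb:P5\tuniprotkb:P6\t-\t-\t-\n"  # 5 columns
        records, report = read_mitab_all(text)
        assert len(records) == 2
        assert len(report.errors) == 1
        assert report.errors[0].kind == "column-count"
        assert report.errors[0].line == 4

    def test_record_conservation_with_errors(self):
        """rows in = records out + error entries."""
        bad = "\t".join(["x:1"] * 36)  # 2.6-shaped row in a 2.5 stream
        text = MINI_25 + bad + "\n"
        records, report = read_mitab_all(text)
        assert 3 == len(records) + len(report.errors)

    def test_first_row_of_unknown_shape_is_fatal(self):
        with pytest.raises(UnsupportedDialectError):
            read_mitab_all("a:1\tb:2\tc:3")


class TestWriter:
    @pytest.mark.parametrize("dialect,version", [
        ("mitab25", "2.5"), ("mitab26", "2.6"), ("mitab27", "2.7"),
    ])
    def test_round_trip_exact_within_version(self, dialect, version):
        for seed in range(5):
            entry_set, _ = make_network(dialect, seed=seed)
            originals = entry_set.interactions()
            text = write_mitab(originals, version)
            records, report = read_mitab_all(text)
            assert not report
            assert len(records) == len(originals)
            for a, b in zip(originals, records):
                assert semantic_equals(a, b, "exact")

    def test_column_counts_match_version(self):
        entry_set, _ = make_network("mitab27", seed=2)
        for version, count in [("2.5", 15), ("2.6", 36), ("2.7", 42)]:
            text = write_mitab(entry_set.interactions(), version)
            for line in text.splitlines():
                if line and not line.startswith("#"):
                    assert len(line.split("\t")) == count

    def test_downgrade_to_25_preserves_identity(self):
        entry_set, _ = make_network("mitab27", seed=4)
        originals = entry_set.interactions()
        text = write_mitab(originals, "2.5")
        records, _ = read_mitab_all(text)
        for a, b in zip(originals, records):
            assert semantic_equals(a, b, "identity")

    def test_truncation_monotone_across_versions(self):
        """Fields surviving 2.5 are a subset of 2.6, which is a subset of 2.7."""
        entry_set, _ = make_network("mitab27", seed=6)
        originals = entry_set.interactions()
        by_version = {}
        for version in ("2.5", "2.6", "2.7"):
            records, _ = read_mitab_all(write_mitab(originals, version))
            by_version[version] = records
        for a25, a26, a27, orig in zip(
            by_version["2.5"], by_version["2.6"], by_version["2.7"], originals
        ):
            assert semantic_equals(a25, orig, "identity")
            assert semantic_equals(a26, orig, "default")
            assert semantic_equals(a27, orig, "exact")

    def test_empty_input_writes_header_only(self):
        text = write_mitab([], "2.7")
        assert text.startswith("#") and len(text.splitlines()) == 1

    def test_unsupported_version_rejected(self):
        with pytest.raises(UnsupportedDialectError):
            write_mitab([], "2.8")

    def test_negative_dropped_with_warning_at_25(self):
        entry_set, _ = make_network("mitab26", seed=8, p_negative=1.0)
        originals = entry_set.interactions()
        assert all(i.is_negative for i in originals)
        from miexchange.model import ParseReport

        report = ParseReport()
        text = write_mitab(originals, "2.5", report=report)
        assert len(report.warnings) == len(originals)
        records, _ = read_mitab_all(text)
        assert not any(r.is_negative for r in records)

    def test_nary_input_rejected(self):
        entry_set, _ = make_network(
            "xml25", seed=1, arity_distribution={3: 1.0}, n_interactions=2
        )
        with pytest.raises(CapabilityError, match="expand"):
            write_mitab(entry_set.interactions(), "2.7")
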