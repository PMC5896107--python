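"""Data model invariants and the semantic comparator."""

import copy

import pytest

from miexchange.model import (
    Annotation,
    BinaryInteraction,
    CvTerm,
    FormatDescriptor,
    Interaction,
    Interactor,
    Organism,
    Participant,
    Publication,
    Range,
    Position,
    Stoichiometry,
    Xref,
    apply_defaults,
    cv,
    semantic_equals,
)
from tests.conftest import make_network


def simple_interaction(type_name="direct interaction", ids=("P1", "P2")):
    parts = [
        Participant(
            interactor=Interactor(
                preferred_id=Xref(cv("uniprotkb"), i),
                interactor_type=cv("protein", "MI:0326"),
            )
        )
        for i in ids
    ]
    return Interaction(participants=parts, interaction_type=cv(type_name))


class TestInvariants:
    def test_cvterm_requires_nonempty_short_name(self):
        with pytest.raises(ValueError):
            CvTerm(short_name="")

    @pytest.mark.parametrize("bad", ["MI:12", "MI:12345", "GO:0005515", "0407"])
    def test_cvterm_mi_accession_pattern(self, bad):
        with pytest.raises(ValueError):
            CvTerm(short_name="x", mi_identifier=bad)

    @pytest.mark.parametrize("taxid", [9606, 1, -1, -5])
    def test_organism_accepts_positive_and_reserved_taxids(self, taxid):
        assert Organism(taxid=taxid).taxid == taxid

    @pytest.mark.parametrize("taxid", [0, -6, -100])
    def test_organism_rejects_other_nonpositive_taxids(self, taxid):
        with pytest.raises(ValueError):
            Organism(taxid=taxid)

    def test_range_rejects_inverted_coordinates(self):
        certain = cv("certain", "MI:0335")
        with pytest.raises(ValueError):
            Range(Position(certain, 10), Position(copy.deepcopy(certain), 3))

    def test_stoichiometry_ordering(self):
        with pytest.raises(ValueError):
            Stoichiometry(3, 1)

    def test_publication_needs_some_identifier(self):
        with pytest.raises(ValueError):
            Publication()
        assert Publication(title="only a title").title

    def test_publication_can_hold_xref_and_inline_attributes_together(self):
        pub = Publication(pubmed_id="12345", title="T", journal="J", authors=["A"])
        assert pub.pubmed_id and pub.has_inline_attributes()

    def test_interaction_requires_participants(self):
        with pytest.raises(ValueError):
            Interaction(participants=[])

    def test_binary_requires_two_slots(self):
        i = simple_interaction(ids=("P1", "P2", "P3"))
        with pytest.raises(ValueError):
            BinaryInteraction(participants=i.participants)

    def test_interactor_sequence_must_be_whitespace_free(self):
        with pytest.raises(ValueError):
            Interactor(
                preferred_id=Xref(cv("uniprotkb"), "P1"),
                interactor_type=cv("protein"),
                sequence="MK TT",
            )

    def test_participant_defaults_biological_role_on_construction(self):
        p = Participant(
            interactor=Interactor(
                preferred_id=Xref(cv("uniprotkb"), "P1"), interactor_type=cv("protein")
            )
        )
        assert p.biological_role.short_name == "unspecified role"

    @pytest.mark.parametrize("fmt", ["mi-json", "html"])
    def test_write_only_formats_reject_read_descriptors(self, fmt):
        with pytest.raises(ValueError):
            FormatDescriptor(format=fmt, direction="read")
        assert FormatDescriptor(format=fmt, direction="write").direction == "write"


class TestSemanticEquals:
    def test_reflexive_at_every_stringency(self):
        i = simple_interaction()
        for s in ("identity", "default", "exact"):
            assert semantic_equals(i, i, s)

    def test_type_difference_splits_identity_and_default(self):
        a = simple_interaction("direct interaction")
        b = simple_interaction("colocalization")
        assert semantic_equals(a, b, "identity")
        assert not semantic_equals(a, b, "default")

    def test_annotation_order_is_irrelevant_at_exact(self):
        a = simple_interaction()
        b = copy.deepcopy(a)
        a.annotations = [Annotation(cv("comment"), "x"), Annotation(cv("caution"), "y")]
        b.annotations = [Annotation(cv("caution"), "y"), Annotation(cv("comment"), "x")]
        assert semantic_equals(a, b, "exact")

    def test_participant_order_is_irrelevant(self):
        a = simple_interaction()
        b = copy.deepcopy(a)
        b.participants.reverse()
        for s in ("identity", "default", "exact"):
            assert semantic_equals(a, b, s)

    def test_unknown_stringency_rejected(self):
        i = simple_interaction()
        with pytest.raises(ValueError):
            semantic_equals(i, i, "strictest")

    def test_stringency_implication_chain_over_generated_pairs(self):
        """exact => default => identity over >=1000 generated pairs."""
        pool = []
        for seed in range(8):
            entry_set, _ = make_network("xml25", seed=seed, n_interactions=10)
            pool.extend(entry_set.interactions())
        pairs = [(a, b) for a in pool for b in pool[:16]]
        assert len(pairs) >= 1000
        for a, b in pairs:
            if semantic_equals(a, b, "exact"):
                assert semantic_equals(a, b, "default")
            if semantic_equals(a, b, "default"):
                assert semantic_equals(a, b, "identity")

    def test_symmetry_on_generated_records(self):
        entry_set, _ = make_network("xml25", seed=3, n_interactions=8)
        ints = entry_set.interactions()
        for a in ints:
            for b in ints:
                for s in ("identity", "default", "exact"):
                    assert semantic_equals(a, b, s) == semantic_equals(b, a, s)


class TestApplyDefaults:
    def test_fully_specified_interaction_unchanged(self):
        i = simple_interaction()
        assert semantic_equals(apply_defaults(i), i, "exact")

    def test_idempotent_at_exact(self):
        entry_set, _ = make_network("xml25", seed=9, n_interactions=5)
        for i in entry_set.interactions():
            once = apply_defaults(i)
            twice = apply_defaults(once)
            assert semantic_equals(once, twice, "exact")

    def test_missing_role_filled_with_unspecified(self):
        p = Participant(
            interactor=Interactor(
                preferred_id=Xref(cv("uniprotkb"), "P1"), interactor_type=cv("protein")
            )
        )
        p.biological_role = None  # simulate a reader that bypassed the default
        i = Interaction(participants=[p, copy.deepcopy(p)])
        out = apply_defaults(i)
        assert out.participants[0].biological_role.short_name == "unspecified role"
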