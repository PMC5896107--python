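"""Synthetic generator: determinism, sidecar arithmetic, corruption sites."""

import pytest

from miexchange import mitab, xmlio
from miexchange.errors import ConfigurationError
from miexchange.expansion import matrix_expand, spoke_expand
from miexchange.generate import GeneratorConfig, corrupt, generate_network
from miexchange.model import BinaryInteraction


class TestConfig:
    def test_probabilities_validated(self):
        with pytest.raises(ConfigurationError):
            GeneratorConfig(p_feature=1.5)

    def test_arity_distribution_must_sum_to_one(self):
        with pytest.raises(ConfigurationError):
            GeneratorConfig(arity_distribution={2: 0.5, 3: 0.4})

    def test_arity_cannot_exceed_pool(self):
        with pytest.raises(ConfigurationError):
            GeneratorConfig(n_interactors=3, arity_distribution={4: 1.0})

    def test_unknown_dialect_preset_rejected(self):
        with pytest.raises(ConfigurationError):
            GeneratorConfig.for_dialect("mitab28")


class TestDeterminism:
    def test_same_seed_gives_byte_identical_serializations(self):
        for dialect, render in [
            ("mitab27", lambda es: mitab.write_mitab(es.interactions(), "2.7")),
            ("xml25", lambda es: xmlio.write_xml(es, style="compact")),
        ]:
            cfg = GeneratorConfig.for_dialect(dialect, seed=123)
            first, side_a = generate_network(cfg)
            second, side_b = generate_network(GeneratorConfig.for_dialect(dialect, seed=123))
            assert render(first) == render(second)
            assert side_a == side_b

    def test_different_seeds_differ(self):
        a, _ = generate_network(GeneratorConfig.for_dialect("mitab27", seed=1))
        b, _ = generate_network(GeneratorConfig.for_dialect("mitab27", seed=2))
        assert mitab.write_mitab(a.interactions(), "2.7") != mitab.write_mitab(
            b.interactions(), "2.7"
        )


class TestOutputShape:
    def test_binary_distribution_yields_binary_interactions(self):
        entry_set, _ = generate_network(
            GeneratorConfig(arity_distribution={2: 1.0}, n_interactions=8)
        )
        assert all(isinstance(i, BinaryInteraction) for i in entry_set.interactions())
        assert all(i.arity() == 2 for i in entry_set.interactions())

    def test_sidecar_records_every_interaction(self):
        entry_set, sidecar = generate_network(GeneratorConfig(seed=5, n_interactions=15))
        assert len(sidecar["interactions"]) == 15
        for interaction, record in zip(entry_set.interactions(), sidecar["interactions"]):
            assert interaction.arity() == record["arity"]
            assert [
                p.interactor.preferred_id.identifier for p in interaction.participants
            ] == record["participant_ids"]

    def test_matrix_expansion_count_equals_sidecar_arithmetic(self):
        cfg = GeneratorConfig(
            seed=21, n_interactions=50, arity_distribution={2: 0.5, 4: 0.5}
        )
        entry_set, sidecar = generate_network(cfg)
        expected = sum(
            r["arity"] * (r["arity"] - 1) // 2 for r in sidecar["interactions"]
        )
        produced = sum(len(matrix_expand(i)) for i in entry_set.interactions())
        assert produced == expected

    def test_spoke_expansion_count_over_hub_bearing_interactions(self):
        cfg = GeneratorConfig(
            seed=22, n_interactions=30, arity_distribution={3: 0.5, 4: 0.5},
            p_bait_present=0.7,
        )
        entry_set, sidecar = generate_network(cfg)
        expected = sum(
            r["arity"] - 1 for r in sidecar["interactions"] if r["has_bait"]
        )
        produced = sum(
            len(spoke_expand(i))
            for i, r in zip(entry_set.interactions(), sidecar["interactions"])
            if r["has_bait"]
        )
        assert produced == expected

    def test_features_stay_within_sequence_bounds(self):
        entry_set, _ = generate_network(GeneratorConfig(seed=8, p_feature=1.0))
        for interaction in entry_set.interactions():
            for participant in interaction.participants:
                limit = (
                    len(participant.interactor.sequence)
                    if participant.interactor.sequence
                    else 50
                )
                for feature in participant.features:
                    for rng in feature.ranges:
                        assert 1 <= rng.start.coordinate <= rng.end.coordinate <= limit


class TestCorrupt:
    def _mitab_text(self, seed=3, n=20):
        entry_set, _ = generate_network(
            GeneratorConfig.for_dialect("mitab27", seed=seed, n_interactions=n)
        )
        return mitab.write_mitab(entry_set.interactions(), "2.7")

    def test_zero_spec_leaves_file_unchanged(self):
        text = self._mitab_text()
        out, truth = corrupt(text, {}, seed=1, fmt="mitab")
        assert out == text and truth == []

    def test_same_seed_same_sites(self):
        text = self._mitab_text()
        spec = {"column-count": 2, "unknown-cv": 2}
        first = corrupt(text, spec, seed=9, fmt="mitab")
        second = corrupt(text, spec, seed=9, fmt="mitab")
        assert first == second

    def test_sites_hit_distinct_rows(self):
        text = self._mitab_text()
        _, truth = corrupt(
            text,
            {"column-count": 3, "unbalanced-quote": 3, "unknown-cv": 3},
            seed=4,
            fmt="mitab",
        )
        lines = [t["line"] for t in truth]
        assert len(lines) == len(set(lines)) == 9

    def test_inapplicable_kind_is_configuration_error(self):
        text = self._mitab_text()
        with pytest.raises(ConfigurationError):
            corrupt(text, {"dangling-ref": 1}, seed=1, fmt="mitab")

    def test_unknown_kind_rejected(self):
        with pytest.raises(ConfigurationError):
            corrupt("x", {"bit-rot": 1}, seed=1, fmt="mitab")

    def test_too_many_corruptions_for_file_rejected(self):
        entry_set, _ = generate_network(
            GeneratorConfig.for_dialect("mitab27", seed=1, n_interactions=2)
        )
        text = mitab.write_mitab(entry_set.interactions(), "2.7")
        with pytest.raises(ConfigurationError):
            corrupt(text, {"column-count": 5}, seed=1, fmt="mitab")
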