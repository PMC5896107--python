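"""Seeded synthetic interaction networks and corrupted variants.

Every round-trip, expansion, enrichment and validation test in this
library runs on output of this generator — no downloads, no external
fixtures. The generator draws interactors from a synthetic accession pool
(``GEN0001``...) whose identifiers the packaged fixture fetcher table also
knows, organisms from a small fixed pool, and CV terms exclusively from the
packaged mini ontology, so generated files always validate cleanly.

Identical config + seed produces identical output, byte-for-byte after
serialization. A ground-truth *sidecar* records every sampled choice
(arity, bait presence, participant ids, negativity) so tests can compute
expected expansion counts and statistics independently of the code under
test.

:func:`corrupt` injects a stated number of each corruption kind into a
serialized file and returns the injection sites, giving validator tests an
exact expected-findings list.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, asdict
from typing import Optional

from lxml import etree

from .errors import ConfigurationError
from .model import (
    Alias,
    Annotation,
    BinaryInteraction,
    CvTerm,
    Experiment,
    Feature,
    Interaction,
    Interactor,
    Organism,
    Participant,
    Publication,
    Stoichiometry,
    Xref,
    certain_range,
    cv,
)
from .xmlio import Entry, EntrySet

_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_ORGANISM_POOL = [
    (9606, "human", "Homo sapiens"),
    (10090, "mouse", "Mus musculus"),
    (4932, "yeast", "Saccharomyces cerevisiae"),
    (562, "ecoli", "Escherichia coli"),
    (-1, "in vitro", None),
]

_DETECTION_POOL = [
    ("two hybrid", "MI:0018"),
    ("anti tag coimmunoprecipitation", "MI:0007"),
    ("pull down", "MI:0096"),
    ("x-ray crystallography", "MI:0114"),
]

_TYPE_POOL = [
    ("direct interaction", "MI:0407"),
    ("physical association", "MI:0915"),
    ("association", "MI:0914"),
    ("colocalization", "MI:0403"),
]

# short-name-only terms: every dialect carries names for these slots, but not
# all carry accessions, so accession-less terms round-trip everywhere
_FEATURE_TYPE_POOL = ["binding-associated region", "experimental feature", "tag"]
_CONFIDENCE_TYPE = "mi-score"
_ANNOTATION_TOPIC = "comment"

CORRUPTION_KINDS = (
    "column-count",
    "unbalanced-quote",
    "dangling-ref",
    "wrong-location-cv",
    "unknown-cv",
)


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic network.

    The expressibility knobs (`with_roles`, `with_annotations`,
    `p_feature`, `p_stoichiometry`, `p_negative`) exist because the MITAB
    version lattice cannot hold every model field: round-trip tests
    generate data expressible in the dialect under test
    (see :meth:`for_dialect`).
    """

    n_interactors: int = 25
    n_interactions: int = 12
    arity_distribution: dict[int, float] = field(
        default_factory=lambda: {2: 0.5, 3: 0.25, 4: 0.25}
    )
    p_bait_present: float = 0.9
    p_feature: float = 0.3
    p_negative: float = 0.05
    p_stoichiometry: float = 0.3
    with_roles: bool = True
    with_annotations: bool = True
    seed: int = 42

    def __post_init__(self) -> None:
        for name in ("p_bait_present", "p_feature", "p_negative", "p_stoichiometry"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name}={value} outside [0, 1]")
        total = sum(self.arity_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"arity distribution sums to {total}, not 1")
        if any(a < 1 for a in self.arity_distribution):
            raise ConfigurationError("arities must be >= 1")
        if max(self.arity_distribution) > self.n_interactors:
            raise ConfigurationError("largest arity exceeds the interactor pool")

    @classmethod
    def for_dialect(cls, dialect: str, seed: int = 42, **overrides) -> "GeneratorConfig":
        """A config whose output is fully expressible in the given dialect.

        ``mitab25`` strips everything 2.5 has no columns for (roles,
        features, stoichiometry, annotations, the negative flag) and keeps
        interactions natively binary; ``mitab26`` restores roles,
        annotations and negativity; ``mitab27`` restores features and
        stoichiometry; ``xml25``/``xml30`` lift the binary restriction.
        """
        binary = {2: 1.0}
        presets: dict[str, dict] = {
            "mitab25": dict(
                arity_distribution=binary, with_roles=False, with_annotations=False,
                p_feature=0.0, p_stoichiometry=0.0, p_negative=0.0, p_bait_present=0.0,
            ),
            "mitab26": dict(
                arity_distribution=binary, p_feature=0.0, p_stoichiometry=0.0,
            ),
            "mitab27": dict(arity_distribution=binary),
            "xml25": {},
            "xml30": {},
        }
        if dialect not in presets:
            raise ConfigurationError(f"no generator preset for dialect {dialect!r}")
        kwargs = presets[dialect] | overrides | {"seed": seed}
        return cls(**kwargs)


def _make_interactor(index: int, rng: random.Random) -> Interactor:
    accession = f"GEN{index:04d}"
    organism = None
    if rng.random() < 0.9:
        taxid, common, scientific = rng.choice(_ORGANISM_POOL)
        organism = Organism(taxid, common, scientific)
    sequence = None
    if rng.random() < 0.8:
        sequence = "".join(rng.choice(_AMINO_ACIDS) for _ in range(rng.randint(40, 120)))
    aliases = [Alias(f"gen{index}", cv("gene name"))]
    return Interactor(
        preferred_id=Xref(cv("uniprotkb"), accession),
        interactor_type=cv("protein", "MI:0326"),
        organism=organism,
        sequence=sequence,
        aliases=aliases,
    )


def _make_features(interactor: Interactor, rng: random.Random) -> list[Feature]:
    limit = len(interactor.sequence) if interactor.sequence else 50
    start = rng.randint(1, max(1, limit - 10))
    end = rng.randint(start, min(limit, start + 25))
    return [
        Feature(
            feature_type=cv(rng.choice(_FEATURE_TYPE_POOL)),
            ranges=[certain_range(start, end)],
        )
    ]


def _sample_arity(cfg: GeneratorConfig, rng: random.Random) -> int:
    arities = sorted(cfg.arity_distribution)
    weights = [cfg.arity_distribution[a] for a in arities]
    return rng.choices(arities, weights=weights, k=1)[0]


def generate_network(cfg: GeneratorConfig) -> tuple[EntrySet, dict]:
    """Build a synthetic entry set plus its ground-truth sidecar.

    The sidecar records, per interaction: id, arity, bait presence,
    participant accessions and negativity — everything needed to compute
    expected expansion counts and statistics without re-reading the model.
    """
    rng = random.Random(cfg.seed)
    import copy as _copy

    pool = [_make_interactor(i + 1, rng) for i in range(cfg.n_interactors)]
    entry = Entry(source=cv("miexchange synthetic generator"))
    sidecar: dict = {
        "seed": cfg.seed,
        "n_interactors": cfg.n_interactors,
        "interactions": [],
    }
    used_accessions: set[str] = set()

    for index in range(cfg.n_interactions):
        arity = _sample_arity(cfg, rng)
        members = rng.sample(pool, arity)
        has_bait = cfg.with_roles and rng.random() < cfg.p_bait_present
        participants = []
        for slot, interactor in enumerate(members):
            interactor = _copy.deepcopy(interactor)
            used_accessions.add(interactor.preferred_id.identifier)
            if cfg.with_roles:
                if has_bait:
                    role = cv("bait", "MI:0496") if slot == 0 else cv("prey", "MI:0498")
                else:
                    role = cv("neutral component", "MI:0497")
            else:
                role = None
            features = (
                _make_features(interactor, rng) if rng.random() < cfg.p_feature else []
            )
            stoichiometry = None
            if rng.random() < cfg.p_stoichiometry:
                value = rng.randint(1, 3)
                stoichiometry = Stoichiometry(value, value)
            participants.append(
                Participant(
                    interactor=interactor,
                    experimental_role=role,
                    features=features,
                    stoichiometry=stoichiometry,
                )
            )

        detection = cv(*rng.choice(_DETECTION_POOL))
        itype = cv(*rng.choice(_TYPE_POOL))
        publication = Publication(
            pubmed_id=str(rng.randint(10_000_000, 39_999_999)),
            source=cv("intact", "MI:0469"),
        )
        experiment = Experiment(detection_method=detection, publication=publication)
        negative = rng.random() < cfg.p_negative
        annotations = (
            [Annotation(cv(_ANNOTATION_TOPIC), f"synthetic record {index + 1}")]
            if cfg.with_annotations
            else []
        )
        confidences = [(cv(_CONFIDENCE_TYPE), f"{rng.random():.3f}")]
        kwargs = dict(
            participants=participants,
            id=f"gen-{index + 1}",
            interaction_type=itype,
            experiment=experiment,
            confidences=confidences,
            is_negative=negative,
            annotations=annotations,
        )
        interaction: Interaction
        if arity == 2:
            interaction = BinaryInteraction(**kwargs)
        else:
            interaction = Interaction(**kwargs)
        entry.interactions.append(interaction)
        sidecar["interactions"].append(
            {
                "id": interaction.id,
                "arity": arity,
                "has_bait": has_bait,
                "participant_ids": [
                    p.interactor.preferred_id.identifier for p in participants
                ],
                "negative": negative,
            }
        )

    sidecar["n_distinct_interactors"] = len(used_accessions)
    sidecar["config"] = {
        **asdict(cfg),
        "arity_distribution": {str(k): v for k, v in cfg.arity_distribution.items()},
    }
    return EntrySet(entries=[entry], version="2.5"), sidecar


# ---------------------------------------------------------------------------
# Corruption injection
# ---------------------------------------------------------------------------

def _mitab_data_rows(lines: list[str]) -> list[int]:
    return [
        i
        for i, line in enumerate(lines)
        if line.strip() and not (i == 0 and line.startswith("#"))
    ]


def _corrupt_mitab(text: str, spec: dict[str, int], rng: random.Random):
    lines = text.splitlines()
    candidates = _mitab_data_rows(lines)
    total = sum(spec.values())
    if total > len(candidates):
        raise ConfigurationError(
            f"cannot inject {total} corruptions into {len(candidates)} data rows"
        )
    targets = rng.sample(candidates, total)
    ground_truth = []
    cursor = 0
    for kind, count in spec.items():
        for _ in range(count):
            row_index = targets[cursor]
            cursor += 1
            cells = lines[row_index].split("\t")
            if kind == "column-count":
                cells = cells[:-1]
            elif kind == "unbalanced-quote":
                cells[6] = '"' + cells[6]
            elif kind == "wrong-location-cv":
                cells[6] = 'psi-mi:"MI:0326"(protein)'
            elif kind == "unknown-cv":
                cells[6] = 'psi-mi:"MI:9999"(mystery method)'
            else:
                raise ConfigurationError(
                    f"corruption kind {kind!r} is not applicable to MITAB"
                )
            lines[row_index] = "\t".join(cells)
            ground_truth.append({"kind": kind, "line": row_index + 1})
    return "\n".join(lines) + "\n", ground_truth


def _corrupt_xml(text: str, spec: dict[str, int], rng: random.Random):
    root = etree.fromstring(text.encode("utf-8"))
    ns = etree.QName(root).namespace
    interactions = root.findall(f".//{{{ns}}}interaction")
    total = sum(spec.values())
    if total > len(interactions):
        raise ConfigurationError(
            f"cannot inject {total} corruptions into {len(interactions)} interactions"
        )
    targets = rng.sample(interactions, total)
    ground_truth = []
    cursor = 0

    def _set_cv(el, mi: str, name: str) -> None:
        short = el.find(f"{{{ns}}}names/{{{ns}}}shortLabel")
        if short is not None:
            short.text = name
        ref = el.find(f"{{{ns}}}xref/{{{ns}}}primaryRef")
        if ref is not None:
            ref.set("id", mi)

    for kind, count in spec.items():
        for _ in range(count):
            node = targets[cursor]
            cursor += 1
            label = node.find(f"{{{ns}}}names/{{{ns}}}shortLabel")
            locator = label.text if label is not None else node.get("id")
            if kind == "dangling-ref":
                ref = node.find(f".//{{{ns}}}interactorRef")
                if ref is None:
                    raise ConfigurationError(
                        "dangling-ref corruption needs a compact-style document"
                    )
                ref.text = "99999"
            elif kind in ("wrong-location-cv", "unknown-cv"):
                # expanded style: the inline experiment's detection method;
                # compact style: shared experiments would spread one corruption
                # over several interactions, so target the interaction's own
                # type element instead
                method = node.find(f".//{{{ns}}}interactionDetectionMethod")
                if method is None:
                    method = node.find(f"{{{ns}}}interactionType")
                if kind == "wrong-location-cv":
                    _set_cv(method, "MI:0326", "protein")
                else:
                    _set_cv(method, "MI:9999", "mystery method")
            else:
                raise ConfigurationError(
                    f"corruption kind {kind!r} is not applicable to PSI-MI XML"
                )
            ground_truth.append({"kind": kind, "interaction": locator})
    return (
        etree.tostring(root, pretty_print=True, xml_declaration=True, encoding="UTF-8").decode(),
        ground_truth,
    )


def corrupt(
    text: str, corruption_spec: dict[str, int], seed: int, fmt: str = "mitab"
) -> tuple[str, list[dict]]:
    """Inject corruptions into a serialized file produced by this library.

    `corruption_spec` maps kind -> count; each injection hits a distinct
    record so the validator must report each site exactly once. Returns the
    corrupted text and the ground-truth list of sites. Same seed, same
    sites. A kind inapplicable to the format raises
    :class:`ConfigurationError`.
    """
    for kind in corruption_spec:
        if kind not in CORRUPTION_KINDS:
            raise ConfigurationError(f"unknown corruption kind {kind!r}")
    rng = random.Random(seed)
    if not corruption_spec or all(v == 0 for v in corruption_spec.values()):
        return text, []
    if fmt == "mitab":
        return _corrupt_mitab(text, {k: v for k, v in corruption_spec.items() if v}, rng)
    if fmt == "psi-xml":
        return _corrupt_xml(text, {k: v for k, v in corruption_spec.items() if v}, rng)
    raise ConfigurationError(f"cannot corrupt format {fmt!r}")
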