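"""Spoke and matrix expansion of n-ary interactions.

Many downstream tools only operate on binary interactions, so an n-ary
evidence (a pull-down with one bait and several preys, a co-purified
complex) must be flattened:

* **spoke** — the bait is the hub; one (bait, prey) binary per non-bait
  participant: n - 1 binaries for arity n.
* **matrix** — every unordered pair of participants: n(n-1)/2 binaries.

Outputs carry the expansion method as a CV tag (``spoke expansion``
MI:1060 / ``matrix expansion`` MI:1061) so that a MITAB 2.7 writer can
record how the row was derived; a natively binary input passes through
untagged. All interaction-level fields (type, experiment, confidences,
parameters, xrefs, annotations, negativity) are inherited verbatim by every
output binary. Participants with stoichiometry > 1 occupy a single slot —
copies are not multiplied, matching what binary formats can express.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional

from .errors import AmbiguousHubError
from .model import (
    BinaryInteraction,
    Interaction,
    Participant,
    matrix_expansion_term,
    spoke_expansion_term,
)


@dataclass
class ExpansionReport:
    """Records fallback hub choices made during spoke expansion."""

    fallback_hubs: list[tuple[Optional[str], str]] = field(default_factory=list)

    def record_fallback(self, interaction_id: Optional[str], hub_id: str) -> None:
        self.fallback_hubs.append((interaction_id, hub_id))


def _make_binary(
    source: Interaction,
    a: Participant,
    b: Participant,
    expansion_term,
) -> BinaryInteraction:
    return BinaryInteraction(
        participants=[copy.deepcopy(a), copy.deepcopy(b)],
        id=source.id,
        interaction_type=copy.deepcopy(source.interaction_type),
        experiment=copy.deepcopy(source.experiment),
        confidences=copy.deepcopy(source.confidences),
        parameters=copy.deepcopy(source.parameters),
        is_negative=source.is_negative,
        xrefs=copy.deepcopy(source.xrefs),
        annotations=copy.deepcopy(source.annotations),
        checksums=list(source.checksums),
        complex_expansion=expansion_term,
    )


def _passthrough(interaction: Interaction) -> list[BinaryInteraction]:
    """Arity 1 -> self binary; arity 2 -> the pair, untagged (natively binary)."""
    ps = interaction.participants
    if len(ps) == 1:
        return [_make_binary(interaction, ps[0], ps[0], None)]
    return [_make_binary(interaction, ps[0], ps[1], None)]


def _participant_sort_key(p: Participant) -> str:
    return p.interactor.preferred_id.key()


def spoke_expand(
    interaction: Interaction,
    fallback: str = "error",
    report: Optional[ExpansionReport] = None,
) -> list[BinaryInteraction]:
    """Expand an n-ary interaction into (hub, prey) binaries.

    The hub is the unique participant with experimental role "bait". When
    there is no unique bait, `fallback` decides: ``"error"`` raises
    :class:`AmbiguousHubError`; ``"first_participant"`` picks the first
    participant under a deterministic preferred-id ordering and records the
    choice in `report`.
    """
    if fallback not in ("error", "first_participant"):
        raise ValueError(f"unknown fallback policy {fallback!r}")
    if interaction.arity() <= 2:
        return _passthrough(interaction)

    baits = [p for p in interaction.participants if p.is_bait()]
    if len(baits) == 1:
        hub = baits[0]
    elif fallback == "error":
        raise AmbiguousHubError(
            f"spoke expansion needs exactly one bait, found {len(baits)} "
            f"in interaction {interaction.id!r}"
        )
    else:
        hub = min(interaction.participants, key=_participant_sort_key)
        if report is not None:
            report.record_fallback(interaction.id, _participant_sort_key(hub))

    term = spoke_expansion_term()
    return [
        _make_binary(interaction, hub, p, copy.deepcopy(term))
        for p in interaction.participants
        if p is not hub
    ]


def matrix_expand(interaction: Interaction) -> list[BinaryInteraction]:
    """Expand an n-ary interaction into all n(n-1)/2 unordered pairs."""
    if interaction.arity() <= 2:
        return _passthrough(interaction)
    ps = interaction.participants
    term = matrix_expansion_term()
    out = []
    for i in range(len(ps)):
        for j in range(i + 1, len(ps)):
            out.append(_make_binary(interaction, ps[i], ps[j], copy.deepcopy(term)))
    return out


def expand(
    interaction: Interaction,
    method: str,
    fallback: str = "first_participant",
    report: Optional[ExpansionReport] = None,
) -> list[BinaryInteraction]:
    """Dispatch on method name: "spoke", "matrix", or "none".

    With "none", an n-ary input of arity > 2 is an error — binary targets
    cannot hold it.
    """
    if method == "spoke":
        return spoke_expand(interaction, fallback=fallback, report=report)
    if method == "matrix":
        return matrix_expand(interaction)
    if method == "none":
        if interaction.arity() > 2:
            raise AmbiguousHubError(
                f"interaction {interaction.id!r} has arity {interaction.arity()}; "
                "a binary-only target needs --expansion spoke or matrix"
            )
        if isinstance(interaction, BinaryInteraction):
            return [interaction]
        return _passthrough(interaction)
    raise ValueError(f"unknown expansion method {method!r}")
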