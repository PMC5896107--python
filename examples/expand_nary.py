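"""Spoke vs matrix expansion of a 4-participant pull-down.

An n-ary evidence (one bait pulling down three preys) cannot be written to
a binary format directly. Spoke expansion keeps the bait as the hub
(n - 1 = 3 binaries); matrix expansion enumerates every unordered pair
(n(n-1)/2 = 6 binaries). Each output is tagged with the expansion method so
downstream consumers know the rows are derived, not observed.
"""

from miexchange.expansion import matrix_expand, spoke_expand
from miexchange.model import Interaction, Interactor, Participant, Xref, cv

participants = [
    Participant(
        interactor=Interactor(
            preferred_id=Xref(cv("uniprotkb"), acc),
            interactor_type=cv("protein", "MI:0326"),
        ),
        experimental_role=cv("bait", "MI:0496") if acc == "P10636" else cv("prey", "MI:0498"),
    )
    for acc in ("P10636", "P63104", "P31946", "Q04917")
]
pulldown = Interaction(participants=participants, id="pulldown-1",
                       interaction_type=cv("physical association", "MI:0915"))

for name, binaries in [("spoke", spoke_expand(pulldown)), ("matrix", matrix_expand(pulldown))]:
    pairs = [
        (b.participant_a.interactor.preferred_id.identifier,
         b.participant_b.interactor.preferred_id.identifier)
        for b in binaries
    ]
    tag = binaries[0].complex_expansion.short_name
    print(f"{name}: {len(binaries)} binaries tagged '{tag}': {pairs}")
# spoke keeps the bait P10636 in every pair; matrix adds the prey-prey pairs.
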