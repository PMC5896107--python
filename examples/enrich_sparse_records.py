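"""Enrich a bare interactor and a bare CV term from file-backed fetchers.

The interactor starts as an identifier and nothing else; the fill-only
policy adds name, organism, sequence, aliases and cross-references from the
packaged reference table without ever touching a field that is already
set. The CV term starts as a name and gains its accession.
"""

from miexchange.enrich import (
    enrich_cvterm,
    enrich_interactor,
    packaged_cv_fetcher,
    packaged_fetcher,
)
from miexchange.model import Interactor, Xref, cv

interactor = Interactor(
    preferred_id=Xref(cv("uniprotkb"), "GEN0001"),
    interactor_type=cv("protein", "MI:0326"),
)
report = enrich_interactor(interactor, packaged_fetcher(), policy="fill_only")
print(f"fields filled: {sorted(f for _loc, f in report.fields_filled)}")
print(f"organism: taxid {interactor.organism.taxid} ({interactor.organism.scientific_name})")
print(f"sequence: {len(interactor.sequence)} residues")

again = enrich_interactor(interactor, packaged_fetcher(), policy="fill_only")
print(f"second pass fills: {len(again.fields_filled)} (enrichment is idempotent)")

term = cv("two hybrid")  # name only, no accession
enrich_cvterm(term, packaged_cv_fetcher())
print(f"CV term resolved: {term.short_name} -> {term.mi_identifier}")
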