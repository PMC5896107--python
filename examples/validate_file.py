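"""Validate a clean MITAB file, then a deliberately corrupted copy.

The validator layers a structural pass (can every row be parsed?) over a
CV-usage pass (does every controlled-vocabulary term exist in the ontology
and sit in an allowed slot?). The corruption injector returns the exact
sites it broke, so the findings can be checked against ground truth.
"""

import tempfile
from pathlib import Path

from miexchange import mitab
from miexchange.generate import GeneratorConfig, corrupt, generate_network
from miexchange.validate import check_file

entry_set, _ = generate_network(GeneratorConfig.for_dialect("mitab27", seed=8, n_interactions=10))
text = mitab.write_mitab(entry_set.interactions(), "2.7")

workdir = Path(tempfile.mkdtemp())
clean = workdir / "clean.tsv"
clean.write_text(text)
print(f"clean file findings: {len(check_file(clean))}")

bad_text, sites = corrupt(
    text, {"column-count": 1, "wrong-location-cv": 1, "unknown-cv": 1}, seed=3, fmt="mitab"
)
bad = workdir / "bad.tsv"
bad.write_text(bad_text)
report = check_file(bad)
print(f"injected {len(sites)} corruptions, validator found {len(report)} problems:")
print(report.to_text(), end="")
# one finding per injected site: a truncated row (syntax), an interactor-type
# accession in the detection-method slot (wrong-location), and a made-up
# accession (term-not-found).
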