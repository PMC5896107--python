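"""Export binaries as MI-JSON (for viewer clients) and HTML (for humans).

Both formats are write-only: they exist to be consumed, not round-tripped.
The MI-JSON document lists each distinct interactor once, then one object
per interaction referencing the interactors by id; the HTML document is a
single self-contained page.
"""

import json

from miexchange import htmlout, mijson
from miexchange.generate import GeneratorConfig, generate_network

entry_set, _ = generate_network(GeneratorConfig.for_dialect("mitab27", seed=6, n_interactions=4))
binaries = entry_set.interactions()

doc = json.loads(mijson.write_mijson(binaries))
kinds = [obj["object"] for obj in doc["data"]]
print(f"MI-JSON: {kinds.count('interactor')} interactor objects + "
      f"{kinds.count('interaction')} interaction objects (schema-checked on write)")

html = htmlout.write_html(binaries)
print(f"HTML: {len(html.splitlines())} lines, {html.count('<table>')} participant tables")

try:
    mijson.read_mijson_attempt("{}")
except Exception as exc:
    print(f"reading MI-JSON: {exc}")
# the support matrix makes these formats write-only; the read attempt
# is rejected with a capability error rather than silently misbehaving.
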