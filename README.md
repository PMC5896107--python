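# miexchange

A change-resilient interoperability library for molecular interaction
data, written for the people who move protein–protein interaction records
between tools: database maintainers exporting monthly releases, pipeline
developers ingesting curated evidence, and visualisation authors who need
viewer-ready JSON.

## The problem

Molecular interaction data ships in a family of formats maintained by the
Proteomics Standards Initiative's Molecular Interactions (PSI-MI)
workgroup: the full-fidelity **PSI-MI XML** (2.5 for experimental
evidences; 3.0 adding abstract interactions — curated complexes — and a
richer publication representation), the tab-delimited **MITAB** (2.5 with
15 columns, 2.6 with 36, 2.7 with 42; one binary interaction evidence per
row), and the viewer-oriented **MI-JSON**. Every tool that touches more
than one of these, or more than one version of one of them, otherwise ends
up with duplicated parsers and duplicated bugs.

`miexchange` puts a single format-agnostic data model in the middle. Every
reader populates it, every writer consumes it, so a conversion is always
*one read + one write* — never a chain of format-to-format translations —
and adding a dialect means adding one module, not N converters.

## What's in the box

| capability | module |
|---|---|
| abstract data model (`Interaction`, `Participant`, `Interactor`, `CvTerm`, ...) with a three-level semantic comparator | `miexchange.model` |
| MITAB 2.5 / 2.6 / 2.7 reader + writer, permissive-in / strict-out field grammar | `miexchange.mitab` |
| PSI-MI XML 2.5 / 3.0 reader + writer, compact and expanded reference styles | `miexchange.xmlio` |
| spoke / matrix expansion of n-ary interactions | `miexchange.expansion` |
| MI-JSON and HTML write-only exporters | `miexchange.mijson`, `miexchange.htmlout` |
| fetcher-backed enrichment (file-backed fetchers, fill-only / overwrite policies) | `miexchange.enrich` |
| structural + CV-usage validator over an OBO ontology | `miexchange.validate` |
| seeded synthetic network generator + corruption injector | `miexchange.generate` |
| conversion / validation / statistics CLI and the format registry | `miexchange.cli`, `miexchange.registry` |

Two ideas carry most of the weight:

**Expansion.** Many tools only operate on binary interactions, so an
n-ary evidence (a pull-down with one bait and several preys, a co-purified
complex) must be flattened. With participants $p_1 \dots p_n$ and a bait
$p_b$, *spoke* expansion emits the $n-1$ bait–prey pairs
$\{(p_b, p_i) : i \neq b\}$, while *matrix* expansion emits all
$\binom{n}{2} = n(n-1)/2$ unordered pairs. Every derived binary is tagged
with the expansion method (`spoke expansion` MI:1060 / `matrix expansion`
MI:1061) so consumers can tell derived rows from observed ones.

**Semantic equality.** File formats impose order; semantics do not.
`semantic_equals(a, b, stringency)` compares interactions as multisets at
three nested levels — `identity` (participant identifiers), `default`
(+ interaction type, negativity, roles), `exact` (+ features,
stoichiometry, confidences, annotations) — and is the oracle behind every
round-trip guarantee in the test suite.

The support matrix is enforced by a registry: MITAB 2.5/2.6/2.7 and
PSI-MI XML 2.5/3.0 read *and* write; MI-JSON and HTML write-only (a read
attempt is a capability error, not a parse failure).

## Worked example

Expand a four-participant pull-down (bait P10636) both ways
(`examples/expand_nary.py`):

```text
spoke: 3 binaries tagged 'spoke expansion': [('P10636', 'P63104'), ('P10636', 'P31946'), ('P10636', 'Q04917')]
matrix: 6 binaries tagged 'matrix expansion': [('P10636', 'P63104'), ('P10636', 'P31946'), ('P10636', 'Q04917'), ('P63104', 'P31946'), ('P63104', 'Q04917'), ('P31946', 'Q04917')]
```

Spoke keeps the bait in every pair ($n-1 = 3$ rows); matrix adds the
prey–prey pairs ($n(n-1)/2 = 6$ rows). Validate a clean file and a
deliberately corrupted copy (`examples/validate_file.py`):

```text
clean file findings: 0
injected 3 corruptions, validator found 3 problems:
ERROR   syntax           line 5: column-count: expected 42 columns for MITAB 2.7, found 41
ERROR   term-not-found   gen-3/experiment.detection_method: term 'MI:9999' is not in the ontology
ERROR   wrong-location   gen-9/experiment.detection_method: term MI:0326 (protein) is not a descendant of MI:0001 (interaction detection method)
```

Each injected corruption surfaces exactly once: a truncated row fails the
structural pass; a fabricated accession fails existence; a real accession
in the wrong slot (an interactor type where a detection method belongs)
fails the location rule, which requires descent from MI:0001 through the
ontology's `is_a` closure.

The same operations from the shell:

```bash
miexchange generate net.xml --dialect xml25 --seed 3 --sidecar truth.json
miexchange convert net.xml out.tsv --to mitab27 --expansion matrix
miexchange check out.tsv --json
miexchange stats net.xml
```

The other `examples/*.py` scripts cover format conversion, enrichment and
the viewer exports, each printing what it computes and why it matters.

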