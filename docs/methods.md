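# Methods

This note documents the design of `miexchange`: the data model and its
comparison semantics, the dialect mappings, the expansion and validation
procedures, what the synthetic generator does and does not emulate, and
the choices made where the design was genuinely open.

## The model and its assumptions

The central unit is the `Interaction`: one piece of interaction evidence
with N `Participant`s, each joining an `Interactor` (the molecule) to the
interaction with biological/experimental roles, sequence features,
stoichiometry and identification methods. Experimental context hangs off
an `Experiment` (detection method, host organism, `Publication`).
Everything is annotated through two atoms — `CvTerm` (a
controlled-vocabulary concept, usually with an `MI:NNNN` accession) and
`Xref` (database + identifier) — because that is the common denominator of
every dialect in the family.

Assumptions baked into the model:

* **Collections are ordered on disk, unordered in meaning.** Readers and
  writers preserve order (files diff cleanly); `semantic_equals` compares
  every collection as a multiset.
* **The library is a carrier, not a censor.** A CV term the ontology does
  not know is retained as a bare short name; unsupported XML 3.0
  constructs (cooperative effects, causal statements, variable parameters)
  are *reported*, never silently dropped.
* **Defaults are explicit terms, not nulls.** A participant always has a
  biological role (`unspecified role`, MI:0499) and an experiment always
  has a detection method (`unspecified method`, MI:0686), applied at
  construction; `apply_defaults` re-applies them idempotently for objects
  built by lenient readers.
* **Binary is a view, not a different thing.** `BinaryInteraction` is an
  `Interaction` restricted to two slots, carrying the `complex_expansion`
  tag exactly when it was derived by expansion. A self-interaction holds
  the same interactor in both slots (and MITAB 2.5's all-dashes column-B
  convention reads into that shape).

### Semantic equality

`semantic_equals(a, b, stringency)` hashes each interaction into a
signature and compares signatures. The three stringencies nest:

| level | compares |
|---|---|
| `identity` | multiset of participant interactor preferred ids |
| `default` | + interaction type, negativity, biological/experimental roles |
| `exact` | + stoichiometries, features (type, ranges, detection), confidences, annotations |

CV terms compare by accession when present, else by lower-cased short
name. Exact equality deliberately excludes organisms, aliases, xrefs,
publications and checksums: those are provenance and description, not the
interaction's semantic content, and several dialects cannot carry all of
them. The implication chain (exact ⇒ default ⇒ identity) is enforced by a
property test over ≥1000 generated pairs.

## Dialect mappings

**MITAB.** Column layouts follow the public 15/36/42-column lattice; the
version is auto-detected from the first data row's column count when not
declared. The field grammar (`db:identifier(free text)`, `|`-separated
values, `-` for empty) is *permissive-in, strict-out*: the reader accepts
quoted and bare sub-fields, the writer quotes any sub-field containing a
reserved character (`|():"` and the colon), an empty string, surrounding
whitespace, or a lone `-` that would be misread as the empty sentinel.
Writing a lower version truncates to its columns; the only lossy
truncation that warrants a diagnostic is the negative flag at 2.5 (no
column exists), which is dropped with a warning. Rows that fail to parse
become entries in a parse report and are skipped — row count in equals
records out plus error entries.

**PSI-MI XML.** Both reference styles are written and read: *compact*
(top-level experiment/interactor lists, numeric `*Ref` elements —
interactors deduplicated by preferred id) and *expanded* (inline
definitions). Writer ids are dense sequential integers per document.
Version deltas implemented: at 2.5 a `bibref` is a cross-reference *or*
an inline attribute list (when the model holds both, the cross-reference
wins on write, since identifiers are recoverable and prose is not); at
3.0 both are written and both read back into one `Publication`. Abstract
interactions (complexes) write only at 3.0; at 2.5 they raise a
capability error so the caller can downgrade explicitly. Stoichiometry is
a first-class element at 3.0 and a participant attribute at 2.5.

**MI-JSON / HTML.** Write-only by the support matrix, enforced in three
places: `FormatDescriptor` construction, the registry, and a
`read_mijson_attempt` that exists to raise. The MI-JSON field names are
this library's own versioned dialect; the packaged schema file
(`data/mijson-schema.json`) is the contract, the writer self-checks every
document against it, and the checker implements the subset of JSON Schema
the contract uses (type/required/properties/items/enum) plus the
referential invariants (unique interactors, resolvable references).

## Expansion

Spoke expansion requires a unique hub: the participant whose experimental
role is `bait` (matched case-insensitively by name or by MI:0496, so
fixtures need no ontology). With zero or several baits the caller chooses:
`error` (the default — ambiguity is data, not noise) or
`first_participant`, which picks the lexicographically smallest preferred
id (deterministic under participant reordering) and records the choice in
an expansion report. Arity 2 passes through untagged (natively binary);
arity 1 becomes a self-binary. Interaction-level fields are inherited
verbatim by every output binary; participants with stoichiometry > 1
occupy a single slot, matching what binary formats can express.

## Validation

Two passes. *Syntax* reuses the readers' parse reports (column counts,
malformed cells, dangling references, unsupported elements); the dialect
is established from the first decidable row so a corrupted first row is a
finding, not a dead stop. *CV usage* walks a rule table: each rule binds a
model slot to a required ancestor accession, and a term must exist in the
loaded OBO graph and lie in the transitive `is_a` closure under that
ancestor (self included). `part_of` and other relations are ignored — the
MI ontology organises the validated slots purely by `is_a`. Rules are
data (packaged YAML covering detection method, interaction type, both
roles and interactor type — a representative subset of the full catalogue,
swappable via `--rules`); a rule naming an unknown slot or ancestor is a
configuration error, not a finding. Findings are ordered by record then
rule, so reports are diffable.

## Enrichment

The fetcher contract is one function, `fetch(identifier) -> record | None`,
keeping enrichment policy independent of data source. Shipped fetchers
are file-backed — a TSV of 40 interactor records and the packaged OBO for
CV terms — preserving the architecture of web-service bridges while
staying offline. `fill_only` sets only absent scalar fields and records
disagreements as conflicts; `overwrite` replaces and records. List fields
merge set-wise under both policies. Invariants tested: enrichment never
removes information, never touches a present scalar under `fill_only`,
and a second pass at fixed fetcher + policy fills nothing. Canonical CV
spellings from the ontology count as fills, not conflicts: the ontology is
authoritative for names.

## The synthetic generator

The generator is the study material for every test. Defaults: 25
interactors, 12 interactions, arity distribution {2: 0.5, 3: 0.25,
4: 0.25} (binary-dominated, as curated interaction sets are), bait present
in 90% of interactions (most n-ary evidence comes from bait-based
pull-downs), features on 30% of participants, 5% negative evidences,
stoichiometry on 30% of participants. Organisms come from a five-entry
pool (human, mouse, yeast, E. coli, in vitro), sequences are uniform
random amino-acid strings of length 40–120, and every CV term is drawn
from the packaged ~60-term mini ontology, so generated files always
validate cleanly — which is precisely what makes injected corruptions
countable. Identical config + seed yields byte-identical serializations,
and a sidecar records every sampled choice so expected expansion counts
and statistics are computed by arithmetic, not by the code under test.

Because the MITAB lattice cannot hold every model field,
`GeneratorConfig.for_dialect` produces data expressible in the dialect
under test: `mitab25` drops roles, features, stoichiometry, annotations
and negativity and stays binary; `mitab26` restores roles, annotations
and negativity; `mitab27` restores features and stoichiometry; the XML
presets lift the binary restriction. Accession-less terms are used for
slots (feature types, confidence types, annotation topics) where not
every dialect carries accessions, so exact round trips hold everywhere.

What the generator does **not** emulate: realistic network topology
(no scale-free degree structure), real accessions or sequences,
multi-entry XML documents, inter-database identifier conflicts, or the
myriad hand-edited irregularities of files in the wild. Passing tests
therefore demonstrate correctness of the mappings and procedures on
well-formed and specifically-corrupted data, not robustness against every
malformation a decade of public archives can produce.

### Corruption injection

Five kinds: wrong column count, unbalanced quote (MITAB); dangling
numeric reference (XML); wrong-location CV accession and unknown CV
accession (both). Each injection targets a distinct record so ground
truth is exactly countable; the syntax kinds make a row unreadable (one
syntax finding, no CV findings), the CV kinds leave a row readable with
exactly one bad slot. Problem sizes in the acceptance checks — 200
networks of 5 interactions for round trips, 25-interaction networks for
conversion and validation, 100 interactors for enrichment — keep the
whole suite in seconds while exercising every code path several times.

## Numerical and edge-case choices

* Feature coordinates are 1-based, inclusive at both ends; indeterminate
  positions carry a status term (`undetermined`) and no coordinate; a
  MITAB feature whose only range is `?-?` reads back as a feature of
  unknown position (empty range list).
* Empty inputs are valid everywhere: empty MITAB stream → empty sequence
  and empty report; empty writer input → header-only file / empty-data
  MI-JSON / zero-interactions HTML notice.
* Reserved taxids −1…−5 (in vitro, chemical synthesis, unknown, in vivo,
  in silico) are accepted alongside positive NCBI taxids.
* A literal tab inside a model value would survive the cell-level grammar
  (quoted) but break row splitting; values are assumed tab-free, as in the
  published format.
* XML interactor deduplication in compact style keys on the preferred id;
  two same-id interactors differing elsewhere would collapse to the first
  definition.

## Known limitations

* XML 3.0 support covers the publication duality and abstract
  interactions only; cooperative effects, causal statements and variable
  parameters are rejected with explicit reports.
* MITAB checksums have interaction-level slots only; per-interactor
  checksum columns are written empty.
* The MI-JSON dialect is this library's own; consumers of other viewers'
  dialects may need a field mapping.
* The enricher ships no HTTP clients by design; live lookups require a
  user-supplied fetcher implementing the one-function contract.
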