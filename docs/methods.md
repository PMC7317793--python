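# Methods

This note records the modelling and engineering decisions behind the
toolkit: what the data model assumes, how the serializations encode it,
what the synthetic generator does and does not emulate, and the numerical
and dialect choices a maintainer would otherwise have to reverse-engineer.

## The data model and its assumptions

The model mirrors the MIAPPE 1.1 checklist: one record type per section
(investigation, study, person, data file, biological material, environment
parameter, experimental factor, event, observation unit, sample, observed
variable) plus shared value types — an ontology reference (label +
CURIE/IRI accession), a four-field WGS84 geolocation block (latitude,
longitude, altitude, coordinates uncertainty; decimal degrees and metres,
signs encoding hemisphere), and the trait/method/scale trio of an observed
variable.

Assumptions worth stating explicitly:

- **Identifier scope.** Identifiers are unique dataset-wide per section
  type. The checklist says "unique identifier" without a scope; the global
  reading is required for unambiguous cross-format conversion, where
  records are keyed by id alone. Records genuinely shared between studies
  (a field network's material and variable lists) may appear in several
  per-study lists provided every occurrence is identical; a differing
  record under the same id is a construction error naming both records.
- **Construction vs validation.** Constructors normalize (empty strings
  become absent) but never enforce checklist rules; `validate` does, so a
  defective dataset can always be represented, inspected and reported on.
  Absent and empty-string fields are deliberately indistinguishable.
- **Dates** are ISO 8601 at reduced precision (`YYYY`, `YYYY-MM`, full
  date, timestamp with optional zone), kept as the strings the user wrote.
  Field trials often record year-only dates; normalizing them would
  destroy information and break round-trips.
- **Factors vs environment.** A study may declare zero factors without
  warning ("may have one or more" is read as 0..n); environment parameter
  names must be unique within a study. Factor values assigned to
  observation units live in a per-unit map keyed by factor type and must
  come from the factor's declared value list.
- **Material identification is two-level and either level suffices.**
  Within-experiment identification (id + organism taxon) is mandatory;
  provenance (material source) and geolocation are optional, and no rule
  requires a material source when coordinates are present — the
  forest-tree case.
- **Events** reference observation units by id list; an empty list means
  the whole study. A repeated practice is a series of events sharing type
  and description and differing in date.
- Samples may derive from any observation unit, including plant-free ones;
  a collection date outside the study range is a warning, not an error,
  because storage and processing lags are plausible.

## Validation

Severity mapping is exactly MUST→ERROR, SHOULD→WARNING, unqualified→no
rule; the registry never invents requirements the checklist does not
state. Each of the 32 rules has a stable id (`CARD-*` cardinalities,
`REQ-*` required fields, `REF-*` reference resolution, `FMT-*` value
formats, `UNIQ-*` uniqueness, `WARN-*` soft checks). Reports carry one
issue per violated (rule, record) pair, sorted by (section, record id,
rule id, field), so a report is byte-identical across runs. Ontology-term
checks are syntactic only — CURIE (`PREFIX:ID`) or absolute-IRI shape —
because network term resolution would make validation nondeterministic and
unusable offline; whether a term really denotes a trait is out of scope.

The rule registry is exercised by a mutation harness (`synth.mutate`): for
every rule there is a mutator that introduces exactly that defect into a
generated dataset, and the suite asserts the report contains that rule and
no unrelated new errors. Mutators on study-shared records apply the defect
to every occurrence, since a shared record is one record.

## Serializations

All four carriers are driven by the same field registry so that coverage
is testable: a census of leaf model fields (derived from the dataclasses)
is compared against each writer's column map / routing table, and a field
added to the model without a mapping fails the suite.

**ISA-Tab.** Tab-delimited, UTF-8, Unix newlines. File scheme:
`i_investigation.txt`, `s_<slug>.txt`, `a_<slug>_<n>.txt` (one per data
file), `tdf_<slug>.txt`, `ev_<slug>.txt` (slugs derived from study ids;
collisions suffixed). MIAPPE-only fields travel as
`Comment[MIAPPE: <field name>]` rows/columns, making the reverse mapping
unambiguous. Conventions: ISA Source = biological material, ISA Sample =
observation unit, ISA Extract = MIAPPE sample; a "Growth" protocol carries
cultural practices (description) and environment parameters (names as
protocol parameters, values in a comment row); a "Phenotyping" protocol
always present; a "Sampling" protocol when samples exist; one protocol of
type "Event" per event type with occurrences in the events file (columns:
type, accession, description, date, semicolon-separated affected units).
Cells may not contain tabs, newlines or the `; ` list separator (the
latter only where lists are joined): such values are rejected on write
rather than quoted, because ISA-Tab quoting dialects in the wild are too
inconsistent to round-trip. Spatial-distribution pairs sit in a
`Comment` column on the Sample node as `key: value` lists. Two corners are
unrepresentable by construction: a study with samples but no data files
(samples are rows of assay files, each anchored to exactly one data file —
the writer refuses), and datasets that fail validation (both the ISA-Tab
and BrAPI writers refuse; the spreadsheet and RDF writers do not, so
defective datasets can still be exchanged for inspection).

**BrAPI.** Target shape is v1.3 (v2.0 is not targeted). Document sets are
directories with one JSON array per collection (trials, studies, contacts,
germplasm, observationunits, samples, variables, datalinks); DbIds equal
MIAPPE ids verbatim — no re-minting — which is what makes the mapping
reversible. Sections absent from BrAPI 1.3 (environment, event) and fields
without an established key travel under `additionalInfo` with `miappe:`
prefixes; each factor contributes one `{factor, modality}` treatment entry
per declared value. Because germplasm and variables are global collections
in BrAPI while MIAPPE attaches them per study, the study documents carry
their membership id lists under `additionalInfo` — without them the
per-study attachment of an unreferenced material would be lost. The scalar
key mapping is shipped as editable tables at the top of the module.

**Spreadsheet.** Eleven worksheets, header row = the shipped
human-readable field names, one record per row, cross-sheet references via
id columns. Lists join with `"; "`, pairs as `key: value`, the level
hierarchy with `" > "`; values containing the separators are rejected on
write. The same layout is written either as XLSX (all cells as text, so
nothing is coerced) or as a directory of per-sheet TSVs. Unknown sheets
are ignored on read; unknown extra columns are kept in a provenance
side-map; a missing Investigation/Study sheet or a header mismatch is an
error naming the sheet and column.

**RDF (PPEO-style).** One class per section plus Location, MaterialSource
and the Trait/Method/Scale grouping classes; camel-cased data and object
properties under a single toolkit namespace
(`https://w3id.org/miappe-toolkit/ppeo#`). The published ontology IRIs are
not hard-coded — they are not printed anywhere authoritative in a
machine-usable form here — so a later prefix remap can align the
vocabulary without touching the data. Instance IRIs are
`<base>/<section-slug>/<percent-encoded id>`; id-less records (persons,
environment parameters, factors, events, data files) get zero-padded
positional ids under their owner, which keeps output deterministic and
preserves list order through a round trip. The study's location is a node,
not bare literals, so the "exactly one location" restriction is
expressible on the graph. Literal typing: full dates as `xsd:date`,
timestamps as `xsd:dateTime`, reduced-precision dates as plain literals
(typing them would be false precision), coordinates as `xsd:decimal` with
the exact lexical form of the float. Constraint checking is a closed-world
instance-graph check (investigation ≥ 1 study, sample exactly 1
observation unit, study exactly 1 location) rather than OWL reasoning:
open-world semantics cannot flag a *missing* study. Turtle output is
byte-deterministic (triples inserted in sorted order); JSON-LD uses a
shipped context and parses back to the identical triple set.

Round-trip identity is defined modulo record order: a canonical form sorts
every record list by its natural key (ids; parameter names; event
type+date) while preserving genuinely ordered structures (the observation
unit level hierarchy). Provenance side-maps are excluded from comparison.

## The synthetic generator

The generator is the package's study-condition source: six archetypes
emulating the hard modelling cases — a multi-local multi-year field
network (3 locations × 2 extra years, 4 shared genotypes, 2 plots each,
hierarchy study > genotype > plot, a study-level weather-station unit, a
three-level nitrogen factor, sowing and repeated fertilizing events, leaf
samples), a forest survey (10 trees identified by coordinates only), a
glasshouse factorial (drought: rainfed/irrigated crossed over pots), a
thermal-time series (one variable on growing degree days, a repeated
irrigation event), a plant-free sensor unit, and a crossing population
(6 progeny sharing one parental cross as material source). Default counts
are deliberately small — every structural situation appears at least once
while a full scenario × 20-seed × 4-format sweep stays in seconds.

Generation is a pure function of (scenario, params, seed); names, sites
and coordinates come from fixed vocabularies and plausible European
agricultural bounds. Content realism is cosmetic: the generator emulates
**structure** (cardinalities, sharing, hierarchies, reference patterns),
not the statistics of real phenotypes — observation payloads are uniform
noise, there are no missing-data patterns, no misspelled ontology terms,
no encoding noise. Passing tests therefore demonstrate structural
correctness of the model, validator and converters, not robustness to the
textual mess of real submissions. Small TSV payloads are materialized on
request (`write_data_files`) so ISA-Tab data-file links resolve on disk;
they are never parsed.

## Problem sizes and tolerances

The acceptance checks run: all 32 rules through the mutation harness (one
field-network dataset), round trips over 6 scenarios × 20 seeds × 4
formats (480 cycles), cross-path conversion agreement over 6 scenarios,
validator agreement over 20 valid/broken datasets, and a 90-dataset
generator sweep. All comparisons are exact (canonical-form equality,
exact rule-id matching); there are no numeric tolerances anywhere — the
model carries strings and exactly round-tripped floats.

## Known limitations

- The checklist's normative per-field requirement levels live in the
  standard's external repository; fields the accompanying description does
  not qualify are treated as optional here, so the validator may be more
  lenient than the official configuration for those fields.
- The ISA-Tab dialect (file naming, comment-key syntax, trait-definition
  columns) is this toolkit's own deterministic dialect, designed to be
  unambiguous and reversible; archives produced by other tools are read
  only insofar as they follow the same conventions.
- BrAPI exchange is file-based; there is no HTTP client or server, no
  pagination, no authentication.
- Ontology references are checked for shape, never resolved; the RDF side
  ships an instance vocabulary, not the published ontology TBox, and does
  no OWL reasoning.
- Observation data values are opaque payloads throughout — the standard
  constrains metadata, not data.
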