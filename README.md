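# miappe

A toolkit for **MIAPPE 1.1** (Minimum Information About a Plant Phenotyping
Experiment) metadata: a typed data model for the checklist's eleven
sections, a rule-based validator, lossless readers and writers for the
standard's four serializations, converters between them, and a
deterministic generator of synthetic datasets covering the standard's hard
modelling cases.

## Who this is for

Plant phenotyping produces heterogeneous experiments — multi-year field
networks, automated glasshouses, forest-tree surveys, crossing populations,
sensor time series — whose datasets are only reusable if their metadata is
complete and machine-readable. MIAPPE 1.1 is the community checklist and
data model for that metadata. This package is for data managers and
bioinformaticians who need to **validate** datasets against the checklist,
**convert** them between the formats different repositories speak, or
**generate** realistic test fixtures without downloading anything.

## The data model in brief

A dataset is one *investigation* owning one or more *studies* (one
experiment each, with exactly one location). A study lists *data files*,
*biological materials* (identified two ways: within the experiment by an
ID plus taxon, or before it via a *material source*; forest trees may be
identified by latitude/longitude/altitude/uncertainty alone), constant
*environment* parameters, varied *experimental factors* with declared value
lists, dated *events*, hierarchical *observation units* (plant, pot, plot,
block or study level — a unit may contain no plant at all), *samples*
(each derived from exactly one observation unit) and *observed variables*,
which always decompose into the Crop Ontology trio **trait × method ×
scale**. MUST-level checklist rules validate as errors, SHOULD-level as
warnings.

Four serializations are supported and interconvertible:

| tag          | carrier                                             |
|--------------|-----------------------------------------------------|
| `isatab`     | ISA-Tab archive (`i_`/`s_`/`a_` files + trait-definition and events files) |
| `brapi`      | BrAPI v1.3-shaped JSON document set (one file per collection) |
| `xlsx` / `tsv-sheets` | spreadsheet template, one worksheet per section |
| `turtle` / `jsonld`   | RDF instantiating the PPEO class/property scheme |

## Worked example

```
$ miappe generate field_network trial/ --seed 7
generated field_network (seed 7) as isatab at trial/

$ miappe validate trial/
PASS: 0 error(s), 0 warning(s)

$ miappe convert trial/ trial_brapi/ --to brapi
wrote brapi to trial_brapi/

$ miappe rules | head -3
rule_id	severity	description
CARD-INV-STUDY	ERROR	An investigation must have one or more studies.
REQ-INV-ID	ERROR	The investigation must carry a non-empty unique identifier.
```

The first command writes a synthetic three-location wheat field network as
an ISA-Tab archive (investigation file, one study/assay/trait-definition
file set per location, plus small TSV observation payloads so every data
file link resolves). `validate` reads any supported format (auto-detected),
applies the full rule registry and exits 0 on PASS, 1 when errors are
present, 2 when the input cannot be read. The same library calls are
available in Python:

```python
from miappe import synth, formats
from miappe.validate import validate

dataset = synth.generate("forest_geo", seed=1, params={"trees": 10})
print(validate(dataset).verdict)            # PASS
formats.write_dataset(dataset, "oaks.ttl", "turtle")
```

which prints `PASS` — the forest scenario's trees are identified purely by
coordinates, with no material-source record, and still satisfy the
checklist.

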