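# modelevo

Structural diffing, change classification and evolution statistics for
versioned computational-biology models (SBML and CellML).

Given pairs or whole version histories of model files, `modelevo`

* parses and **canonicalizes** the XML (sorted attributes, stable
  namespace prefixes, normalized whitespace — cosmetic edits vanish;
  text inside `notes`/`annotation`/`documentation` is kept verbatim),
* computes a **typed edit script** (insert / delete / update / move, on
  element / attribute / text nodes) between consecutive versions, with
  *triggered* flags on operations implied by a subtree insert or delete,
  plus a classical LCS **line diff** baseline,
* **classifies** every operation with COMODI-style terms from three
  branches — Change, Target, XmlEntity — purely from the operation's
  path context,
* aggregates histories into three tables — `filestats` (per-version
  entity counts), `diffstats` (per-transition change counts),
  `repo-evolution` (per-repository time series) — and renders static
  figures,
* ships a **synthetic history generator** that plants known edit
  scripts, so the whole pipeline is verifiable offline against ground
  truth: a patch operator (`apply_delta`) round-trips every delta, and
  the differ recovers planted scripts exactly on id-stable documents.

## CLI

```bash
# compare two versions; exit status 0 = equal, 1 = different, 2 = error
modelevo diff v1/model.xml v2/model.xml                 # text report
modelevo diff v1/model.xml v2/model.xml --format json   # machine readable
modelevo diff v1/model.xml v2/model.xml --format xml-patch
modelevo diff v1/model.xml v2/model.xml --format comodi-csv

# generate a synthetic corpus with ground-truth ledgers
modelevo simulate corpus/ --seed 7 --models 10 --versions 4 --edits 5

# build the three tables (+ SVG figures) from a corpus directory
modelevo stats corpus/ out/ [--model-prefix M00] [--date-from 2005-01-01]
modelevo plot out/
```

A corpus directory follows the layout
`<root>/<repo>/<model_id>/<NNN>_<version_id>/model.xml` with a
`manifest.json` per model carrying version ids, ISO-8601 timestamps and
curation status (`modelevo simulate` writes exactly this layout, plus a
`ledger.json` with the planted operations).

## Library

```python
from modelevo import parse_model, diff, apply_delta, canonical_equal

a = parse_model(open("v1.xml", "rb").read(), model_id="M1", version_id="v1")
b = parse_model(open("v2.xml", "rb").read(), model_id="M1", version_id="v2")
delta = diff(a, b)
print(delta.summary)                      # op-type x entity-kind tallies
assert canonical_equal(apply_delta(a, delta), b)
```

Modules: `modelevo.model_io` (parsing, canonical form, entity counts),
`modelevo.diff_engine` (matching, edit scripts, line diff, patching),
`modelevo.classification` (COMODI-style terms), `modelevo.evolution`
(tables and summaries), `modelevo.synthetic` (seeded corpora with
planted ground truth), `modelevo.figures`, `modelevo.cli`.

## Notes on conventions

* "Nodes" in `filestats` counts **element** nodes only.
* SBML rule variants (`algebraicRule`, `assignmentRule`, `rateRule` and
  Level-1 dialects) all count as rules; `parameter` and `localParameter`
  both count as parameters.
* Entity counts are format-native: SBML rows have zero
  variables/components, CellML rows zero species/reactions/etc.
* Triggered operations are included in all summary counts; report
  renderers and `summarize` expose toggles to exclude them.
* Deltas are deterministic: identical inputs give byte-identical output.
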