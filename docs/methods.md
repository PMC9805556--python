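# Methods

## The linking model

`patlink` treats the gene–patent relationship as a two-hop relational
chain over public identifier systems:

```
gene symbol ──HGNC-style xref──▶ UniProt accession ──cross-ref──▶ target id
target id ──bioactivity evidence──▶ compound (modulator)
compound ──patent-chemistry xref──▶ SureChEMBL-style id ──occurrence──▶ patents
```

A **link** exists only for a fully mapped chain, and each link row carries
the complete provenance (gene, UniProt, target, compound, patent-chemistry
id, patent). The pipeline is a pure function of the backend snapshot and
the configuration; there is no randomness in the extraction itself.

Assumptions worth stating explicitly:

- *Identifier mapping is authoritative.* Symbol normalization is trim +
  uppercase only; aliases resolve through the backend's cross-reference
  table, never through fuzzy matching. A symbol with several target
  cross-references yields one record per (symbol, target) pair so
  paralogous targets are not silently dropped.
- *Validation = assay class.* A compound counts as an experimentally
  validated modulator if it has ≥ 1 evidence row whose single-letter assay
  class is in the allowed set (default `{B, F}`, binding/functional).
  Optional gates on recorded potency and on direct regulation
  (activation/inhibition actions) exist but default to off, because assay
  class is the operative criterion; the action and potency fields are
  carried so stricter configurations remain one flag away.
- *Patentability = patent-chemistry cross-reference.* A modulator can
  reach patents iff its compound record carries a SureChEMBL-style id;
  no other patentability notion is modelled.
- *Document identity = printed patent number.* Uniqueness is the triple
  (authority, serial, kind). Serial strings are compared verbatim
  (leading zeros significant) and two kind codes of one application are
  distinct documents. IPC and CPC codes share one namespace for
  filtering, since their section/class/subclass prefixes coincide.
- *Grant status is binary.* `granted` means kind letter `B` at an office
  that grants; offices in the configurable application-only set (default
  `{WO}`) never grant, so their documents always count as applications.

## Tunable parameters

| Parameter | Default | Meaning |
|---|---|---|
| `allowed_assay_types` | `{B, F}` | evidence classes accepted as validation |
| `require_potency` | off | demand a recorded negative-log-molar potency |
| `allowed_actions` | any | restrict to e.g. activation/inhibition |
| whitelist | `A61K, A61P, C07, C12, C40B` | IPC/CPC prefixes kept (section/class/subclass granularity) |
| `application_only` | `{WO}` | offices that publish but never grant |
| `prevalence_threshold` | 10 per 100 000, inclusive | disease selection cut-off; diseases with unknown prevalence are dropped |
| assignee keywords | INC/LTD/…/PHARMA vs UNIVERSITY/…/HOSPITAL | industry > academic > individual precedence, word-boundary match over all names |

The default whitelist is a deliberate generalization of the subclasses a
pharmaceutical landscape exhibits (C07D, C07K, C12Q, C07H, A61P, C12P,
C07F, C07C …): prefixes at class level (`C07`, `C12`) plus the
formulation/therapeutic classes `A61K`/`A61P` and `C40B`. It is visible
in every run manifest and overridable per run — there is no hidden code
list.

The assignee split is a declared keyword heuristic, not entity
resolution: corporate suffixes and pharma vocabulary beat academic
keywords, which beat the individual fallback. Mixed assignee lists
(inventor + company) therefore classify as industry.

## The fixture generator

The generator plants a relational snapshot (gene_xref, activity,
compound_xref, patent_occurrence) with independent attrition draws at
every hop. Defaults encode a rare-disease case-study shape: 56 input
genes with ~21 % resolving to activity-bearing targets, 1–78 modulators
per mapped gene (mean ≈ 39), ~30 % compound-to-patent-chemistry
mappability, 0–2 patents per mappable compound with 90 % of patents
carrying ≥ 1 whitelisted code (≈ ⅔ of mappable modulators patent-linked),
publication years 2000–2021, jurisdictions drawn US : EP : WO = 83 : 19 : 33,
and assignee categories ≈ 85 : 23 : 25. These values were fixed once, from
the funnel a published rare-disease landscape exhibits, and are the
package's standing test conditions.

Design choices that keep the generator honest:

- **One random stream per table**, seeded `seed + fixed offset`, so
  changing the patent dimension of a plan cannot perturb gene-mapping
  draws.
- **Serials drawn without replacement** within a fixture: an accidental
  patent-number collision would silently change dedup counts and break
  closed-form expectations.
- **WO documents only get A-kinds**, matching the application-only
  semantics the analytics assume.
- **Truth from tables, not intentions.** `truth.json` is computed by
  exhaustively joining the emitted tables with the stage filters; the
  test suite re-derives it with a second, independently written
  plain-Python join oracle (`tests/oracle.py`) that shares no code with
  either the generator or the pipeline.

What the fixtures do **not** emulate: real identifier formats beyond
shape, assay heterogeneity (units, duplicate measurements, conflicting
activities), patent families and cross-jurisdiction equivalents,
multi-gene pleiotropy of compounds (each planted compound serves one
gene), and free-text assignee noise. Passing tests therefore demonstrate
that the machinery recovers an arbitrary planted landscape exactly — they
do not certify recall against live databases, whose content changes
between snapshots.

## Numerical and procedural choices

- Problem sizes: unit fixtures use 4–20 genes; the oracle-equivalence
  sweep uses 20 fixtures of ≤ 50 genes; the emulation run uses the full
  56-gene default. The entire suite runs in a few seconds.
- Thresholding: prevalence comparison is `≥` (a disease at exactly the
  threshold is retained); unknown prevalence never passes any threshold.
- Tie-breaks: modulators sort by compound id, patents by canonical
  number, first occurrence wins for non-key fields during dedup; output
  tables are therefore order-independent of backend row order.
- Degenerate inputs: an empty gene list is a usage error; a gene list of
  only unmapped symbols is a *successful* run with empty outputs and a
  report explaining why; absence of any entity at any hop is recorded in
  `drops.tsv`, never raised.
- Dates: patents without a parseable publication date tally under the
  `"unknown"` year in global summaries and are omitted from per-gene
  timelines.
- Writes are atomic (temp file + rename) and the manifest contains no
  timestamps, so identical fixture + config reruns are byte-identical.

## Known limitations

- The live web-service path (querying ChEMBL/SureChEMBL over HTTP) is
  out of the tested surface; the four-query contract documents what such
  a client must satisfy, and the offline TSV/SQLite backends are the
  supported stores.
- Kind-code semantics beyond "B means granted outside application-only
  offices" (corrections, search reports, utility models) are not
  modelled.
- The parser requires all three number components; patent numbers
  printed without a kind code are rejected rather than guessed.
- Assignee classification is keyword-based and English-biased; per-code
  counts treat every subclass on a document equally with no primary-code
  notion.
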