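# patlink

Link genes of interest to patent documents through experimentally
validated chemical and biological modulators, and summarize the resulting
patent landscape.

Patent literature is a rich but under-used signal in drug discovery:
patenting activity around a target often precedes publications, and the
assignee mix reveals who is investing in it. `patlink` makes this signal
accessible for a plain list of gene symbols (or a disease–gene table with
epidemiological prevalence) by chaining public identifier systems in two
stages:

1. **Chemical extraction.** Each gene symbol is harmonized to a UniProt
   accession and a ChEMBL-style target identifier, and compounds with
   qualifying bioactivity evidence against the target are collected — by
   default evidence of assay class **B** (binding) or **F** (functional),
   the classes that demonstrate direct experimental validation. One
   modulator is emitted per distinct compound.
2. **Patent extraction.** Modulators that cross-reference into the
   patent-chemistry namespace (SureChEMBL-style identifiers) are resolved
   to the patent documents citing their structures. Documents are kept
   only if at least one IPC/CPC classification code matches a configurable
   whitelist (default `A61K, A61P, C07, C12, C40B` — drug formulations,
   therapeutic activity, organic chemistry, biochemistry, combinatorial
   libraries), and deduplicated by the full printed patent number
   `AUTHORITY-SERIAL-KIND` (e.g. `WO-2015123456-A1`: two-letter office
   code, 7–11 digit serial, grant-status kind code).

The output is a provenance-complete link table — one row per
gene → modulator → patent chain — plus landscape analytics over the
deduplicated patent set: jurisdictions, grant status (kind code `B*` at a
granting office; WIPO publishes but never grants), classification
subclasses (multi-label), publication years, per-gene timelines, and a
keyword-based assignee split into industry / academic / individual.

Because the real reference databases are large, versioned and remote, the
package ships an offline backend (four TSV tables or one SQLite file) and
a seeded fixture generator that plants a known gene–modulator–patent graph
with configurable attrition at every hop, together with ground-truth
counts computed by exhaustively joining the planted tables. Every pipeline
claim is testable against that planted truth and against independent
brute-force oracles.

## Worked example

Plant a fully forced fixture (5 genes × 3 modulators × 4 patents, every
mapping probability at 1) and run both stages plus the landscape:

```bash
patlink fixture --n-genes 5 --frac-gene-mapped 1 --modulators-per-gene 3,3 \
    --frac-evidence-allowed 1 --frac-compound-mapped 1 \
    --patents-per-compound 4,4 --frac-patent-whitelisted 1 \
    --seed 7 --out fx/
printf 'GENE0001\nGENE0002\nGENE0003\nGENE0004\nGENE0005\n' > genes.txt
patlink all --backend fx --genes genes.txt --out out/
```

which prints the funnel:

```
run complete: n_genes=5, n_genes_mapped=5, n_genes_with_modulators=5,
n_genes_with_patents=5, n_modulators_validated=15, n_modulators_mappable=15,
n_modulators_with_patents=15, n_patents_whitelisted_unique=60, n_links=60
landscape summary over 60 unique patents
```

All 15 planted modulators are recovered and the 60 planted patents are
unique (serials are drawn without replacement), matching the closed-form
product 5 × 3 × 4. `out/` then contains `modulators.tsv`, `links.tsv`,
`drops.tsv` (per-hop attrition log), `harmonization_report.tsv/json`,
`run_manifest.json` (resolved config, backend content hash, funnel
counts) and the landscape outputs `summary.json`, `summary.tsv`,
`timeline.tsv`. For this seed the summary reads:

```json
{"n_unique_patents": 60,
 "by_jurisdiction": {"EP": 11, "US": 36, "WO": 13},
 "by_grant_status": {"application": 50, "granted": 10},
 "by_assignee_category": {"academic": 9, "individual": 5, "industry": 46}}
```

Each partition sums to the 60 unique patents; the 13 WO documents are
necessarily applications. Classification tallies are multi-label (a
patent classified both `C07D` and `A61P` counts in both subclasses), so
their sum may exceed 60.

The same pipeline runs on any backend honouring the four-query contract
(`query_gene_xref`, `query_activities`, `query_compound_xref`,
`query_patents`); a directory of the four TSV tables or a SQLite file is
auto-detected by path. With `--disease-table` instead of `--genes`, the
input gene list is first selected from a disease–gene TSV by prevalence
(`--min-prevalence`, inclusive, default 10 cases per 100 000).

## Layout

- `src/patlink/model.py` — domain types, patent-number grammar,
  grant-status and classification semantics
- `src/patlink/backend.py` — backend contract, TSV/SQLite stores, fixture
  generator and planted-truth computation
- `src/patlink/harmonize.py` — symbol harmonization, prevalence selection
- `src/patlink/chemistry.py` — evidence filter, modulator extraction
- `src/patlink/patents.py` — class filter, patent retrieval, dedup, links
- `src/patlink/landscape.py` — landscape summaries and plots
- `src/patlink/pipeline.py`, `src/patlink/cli.py` — orchestration, CLI

See `docs/methods.md` for the method, parameter defaults and limitations.
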