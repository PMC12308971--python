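# Methods

## Problem setting

Manually curated marker-gene databases are precise but lag the literature.
`litatlas` builds the complementary resource automatically: it consumes
article-level named-entity annotations (gene and cell-type mentions already
normalised to concept identifiers by an upstream annotator), aggregates
them into a gene × cell-type relation table with per-relation evidence
counts, and ranks relations by a log-normalised co-occurrence score. The
package deliberately stops at the annotation boundary: running an NER
model, crawling PubMed, and live id-resolution services are out of scope;
their outputs are inputs here, and the resolver is an offline TSV catalog
behind a pluggable contract.

## Pipeline and data model

1. **Parsing** (`corpus_io`). PubTator flat text and line-delimited JSON
   records are parsed into `AnnotatedArticle` objects. Span offsets are
   0-based half-open over title + `"\n"` + abstract; neither input dialect
   fixes a convention, so one is fixed here and the synthetic generator
   emits it. Annotation-type → class mapping is a configurable table
   recognising `gene` and `cell_type`; everything else (cell lines,
   diseases, species) maps to `other` and is removed by catalog filtering,
   because only gene- and cell-type-resolved mentions feed the atlas.
   Duplicate PMIDs keep the first occurrence with a warning — deterministic
   ingestion beats silent last-writer-wins.

2. **Evidence** (`atlas_store`). Per article, each distinct (gene CUI, cell
   CUI) pair contributes one evidence row. The per-article weight is not
   pinned down by the co-occurrence literature, so it is a strategy knob:
   `min(gene mentions, cell mentions)` (default — bounds inflation from one
   hyper-mentioned entity), `product` (every mention pair), or `binary`
   (one per article). Evidence and a processed-article log live in a
   single-file SQLite store; re-ingestion of known PMIDs is skipped inside
   one transaction, which makes aggregation independent of batch order and
   makes incremental updates safe. `merge_incremental` adds per-pair counts
   from disjoint corpora and refuses to merge when PMID provenance overlaps.

3. **Scoring** (`scoring`). `score_raw = log10(c_pmid) · log10(c_total)`.
   Display rounding is round-half-to-even at 2 decimals and is purely
   presentational; ranking uses full precision, with ties broken by
   `c_pmid` descending then canonical name ascending so rankings are total
   and reproducible. The aggregated TF–IDF comparator defaults to
   `tf = c_total`, `idf = log10(D / c_pmid)` with log-tf and smoothed-idf
   variants selectable; it exists to document the qualitative contrast
   (TF–IDF falls, the relevance score rises, as document spread grows), not
   as a production scorer. Score normalisation (`none`/`max`/`minmax`)
   defaults to `none` for all ranking operations.

4. **Deployment filter.** Pairs need `c_pmid ≥ 3` distinct articles
   (default; configurable) and `c_total ≥ 1`. The three-article threshold
   trades recall for a lower false-positive rate in the deployed table.

5. **Queries and graphs** (`query_engine`). Query terms resolve through
   case-insensitive exact (or substring) name-index lookup; one result row
   per (resolved concept, counterpart) pair. Multi-marker annotation
   combines per-gene scores per cell type by `sum` (default — rewards both
   marker breadth and strength), `mean`, or matched-gene `count`; with one
   gene it reduces exactly to the single-gene query. Co-occurrence graphs
   are bipartite gene/cell with edge weight = relation score and node
   weight = max (or sum) of incident edge scores; "scaled by score" is
   ambiguous for nodes, so the rule is explicit and configurable. Export is
   lossless GraphML or node-link JSON; layout is a front-end concern.

6. **Ontology distance** (`ontology`). The metric is uniform-cost shortest
   path on the undirected view of the is_a DAG, which reproduces the
   parent/child = 1 and sibling = 2 semantics exactly. An alternative
   reading (paths constrained to go up to a common ancestor and back down)
   agrees on both of those canonical cases; the unrestricted metric was
   chosen as the simpler interpretation and is what `term_distance`
   implements. Only is_a edges participate; `part_of` and other relations
   are ignored, obsolete terms are dropped, and edges into dropped or
   undeclared terms are removed with a warning. Unreachable pairs return a
   marker (`None`), never a sentinel number — the evaluation layer decides
   policy (`exclude` by default, or a fixed penalty).

7. **Evaluation** (`evaluation`). Markers per cluster are the top n = 50
   genes by the one-vs-rest mean-expression ratio
   `(mean_in + ε) / (mean_rest + ε)`, ties alphabetical; ε defaults to
   1e-9, small enough to act only as a divide-by-zero guard. Per gene and
   database the top-1 ranked cell type's distance to the reference term is
   recorded; the combined distance is the minimum over matched databases,
   with a gene exclusive to one database keeping that database's distance.
   Genes are partitioned into atlas-only / both / curated-only / neither
   match categories, and per-cell-type summaries report mean ± sample
   standard deviation (n−1), flagging single-record cells as degenerate.
   Means over the per-database difference use only genes matched in both
   databases; combined-distance means use genes matched in at least one.
   Curated databases carry no counts, so their top-1 rank source is
   explicit: file order (default) or marker count.

## Synthetic data: what it emulates and what it does not

`synthetic_data` generates the whole input universe with known truth:

- **Corpus.** 400 articles, 20 genes, 5 cell types, each gene planted on
  one cell type round-robin. Each article focuses on one cell type
  (mentioned 1 + Poisson(1) times); planted genes of that cell type are
  mentioned Poisson(base_rate × multiplier) = Poisson(6) times, all other
  gene and cell mentions appear at a background noise rate of
  Poisson(0.02). These defaults give a clearly separated but not noise-free
  regime: background pairs do occasionally survive the three-article
  filter, with low scores. Counts are Poisson; the contract is on the
  means and determinism (byte-for-byte under a seed), not the count law.
- **Ontology.** Random rooted DAGs (each term draws parents among earlier
  terms, hence acyclic by construction), the fixed three-term
  anucleate-cell example, and a flat one-root ontology over the corpus's
  cell types for end-to-end evaluation.
- **Expression.** Cluster-mean tables with log-normal background and
  planted markers elevated by a multiplicative effect (default 10×), either
  free-standing or aligned with the corpus truth so literature and
  expression tell the same story.
- **Curated database.** A random 60%-coverage subset of the planted
  associations, emulating a precise but incomplete hand-curated resource.

What the generator does **not** emulate: real English text (abstracts are
token sequences), annotator error modes (no false or mis-normalised
mentions), realistic ontology topology or depth, correlated gene
expression, or species structure. Passing the recovery tests therefore
shows the pipeline's bookkeeping, ranking and evaluation machinery are
correct under the stated generative model — not that the score separates
signal from noise in real literature, where mention statistics are far
heavier-tailed.

## Numerical and design choices

- Rounding: round-half-to-even for all displayed scores (matches all five
  cells of the published worked example); full precision elsewhere.
- Tie-breaks: (score ↓, c_pmid ↓, name ↑) for query rankings;
  (combined score ↓, max c_pmid ↓, name ↑) for marker annotation; gene
  name ↑ for equal expression ratios.
- Ambiguous surface forms (one name, several concepts) are never silently
  resolved; they return an unmapped marker with the candidate set, because
  annotator-normalised ids are the primary keys and name lookup is only a
  fallback.
- Gene–gene co-mention edges exist in the underlying literature signal but
  the store schema is gene × cell; the graph layer is bipartite by default
  and a gene–gene extension would reuse the same evidence pipeline.
- Problem sizes in the test suite and acceptance script (hundreds of
  articles, 30–50-term ontologies, ~10⁴ evidence rows) were chosen as the
  smallest scales at which every code path — filtering, merging, ranking,
  all-pairs distances — is exercised with non-trivial collisions.

## Known limitations

- The score treats all mentions uniformly: no section provenance, no
  full-text vs abstract weighting, no negation or hedging detection.
- Name resolution is exact/substring, case-insensitive only — no fuzzy
  matching; misspelled query terms simply miss.
- The curated-database top-1 rule (file order) is an interpretation; with
  rich curated metadata a better rank source should be injected.
- Distances across disconnected ontology components are undefined and
  excluded by default, which can bias per-cell-type means when a database
  systematically hits terms outside the reference component.
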