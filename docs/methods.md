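# Methods

## Workflow model

`enzyminer` models literature biocuration as a five-stage funnel in which
each stage only narrows or annotates the output of the previous one:
corpus search → abstract screening → (external PDF collection) →
manuscript extraction → curation, with an evaluation harness alongside.
Stages communicate through flat files (TSV/RIS/JSONL) so that any stage
can be resumed, audited, or replaced; a run manifest records a config
snapshot, SHA-256 digests of every input and output, per-stage counts and
the backend identity.

The central design commitment is that the language model is an *abstract
gateway*. A request is a frozen value (system text, user text,
temperature, seed, token constraints, optional document attachment); a
backend maps requests to responses. The live backend wraps a commercial
chat-completion API and is inherently nondeterministic; the mock backend
is a pure function of the request text, so the complete pipeline is
exactly reproducible offline. All correctness claims made by the test
suite are claims about pipeline plumbing, metric arithmetic and curation
logic — *not* about any live model's extraction quality, which can only be
assessed by a live run graded with the same harness.

## Screening

Screening issues one stateless completion per paper. The prompt embeds
the enzyme family name in a templated question; the reply is forced to a
single token ("1"/"0") by `max_tokens=1` plus a hard logit bias on the two
corresponding token ids. Defaults are temperature 0.5 and seed 1, both
overridable. Two shipped templates span the observed strictness range:
`q1` asks whether the paper *directly tests* an activity, `q11` whether it
*likely describes* one. The mock backend honors exactly this distinction:
under strict wording it answers yes only for a planted assay sentence of
the queried family; under inclusive wording a family mention suffices.
This reproduces the real tradeoff — inclusive wording raises recall and
yes-rates at the cost of precision — as a monotone property the suite can
assert, without claiming the live model's specific numbers.

## Extraction and atomic splitting

Each manuscript is processed by two routes (PDF as an opaque attachment;
extracted text in the prompt), whose JSON payloads are merged by a third
completion. Merging is modeled as a de-duplicating union on
(enzyme, acceptors, donors, products); an unparseable payload falls back
to the parseable one with a warning. Every call is fresh-context: nothing
carries over between papers.

Extracted rows may pack several activities into one line. Splitting into
atomic entries (≤ 1 acceptor, donor, product) uses positional pairing when
acceptor and product counts agree — the i-th acceptor with the i-th
product, the donor paired positionally when counts agree and replicated
when single, reflecting how donors are typically reported once for a
substrate series. When acceptor and product counts disagree, no pairing
is trusted: every compound mention becomes its own atom flagged
`unpaired` for manual review, rather than fabricating a cross-product.
The conservation invariant is per-slot value conservation: acceptor and
product multisets are preserved exactly; donor values are preserved as a
set (replication is the stated pairing rule; values are never invented or
lost). Compound names are kept verbatim — including CoA-ester shorthand
like aiC4 or iC5 — because synonym resolution belongs to human grading,
not to the pipeline.

## Curation

Curation is append-only: extraction fields are never rewritten, each step
adds columns or flags, so every decision can be traced back to the raw
payload. Species names are normalized (parenthetical cultivar/strain
suffixes stripped, genus capitalized, epithet lower-cased) before lineage
lookup. Abbreviated genus names ("A. thaliana") resolve only when exactly
one genus in the table starts with that initial; with both *Escherichia*
and *Erwinia* present, "E. coli" deliberately stays unresolved rather than
guessed. Nontarget flagging uses per-family editable lexicons of
case-insensitive substring patterns; a name matching a known other-family
pattern and no target pattern is flagged, ambiguous names are left for
manual review. Accession harvesting classifies tokens with the official
UniProt accession pattern and GenBank nucleotide/protein patterns; UniProt
takes precedence, so no token is ever reported under both schemes.
UniProt mapping prefers ID-based matches; name-based matches additionally
require exact species agreement, and all hits are retained. Hallucination
flagging targets the empirically dominant mode: a biomedical species
(human, mouse, rat) asserted for a paper whose title and text never
mention it; known heterologous hosts (E. coli, yeast) instead get a
`heterologous_host` flag because their mention is real but the enzyme
belongs to the donor organism. Priority tiers are 1 (mapped accession),
2 (raw sequence ID), 3 (name only); the Minimally Curated Set keeps all
tiers but drops nontarget-family and nonplant entries.

## Evaluation

Undefined metrics (zero denominators) are reported as missing, never as
zero, so averages are not silently deflated; rounding happens only at
presentation. Reaction-level grading matches extracted entries to
comparison-dataset activities one-to-one per paper (maximum bipartite
matching over the ≥ 2-of-3 compound-agreement graph, computed with
scipy's sparse matching; the test suite checks it against an exhaustive
enumerator on small instances). Substrate-level grading intersects
per-slot multisets of normalized compound mentions. Recall denominators
are restricted to the papers actually evaluated. "Unknown correct"
entries are excluded from both sides of precision by default and appended
to the comparison dataset in the "(+)" re-grading mode. The curation-gap
estimate exposes its basis explicitly (unique mapped accessions, plus an
optional set of catalogued enzymes the workflow missed, which makes the
estimate a lower bound).

## Synthetic corpora

The generator is a pure function of a `CorpusSpec` (sizes, rates, seed).
It emulates: balanced positive/negative abstract sets across five enzyme
families; manuscripts whose activities appear as rigid, human-readable
assay sentences (a micro-grammar both the mock gateway and an independent
test parser can read); nontarget decoys written as other-family enzyme
names under the queried family, matching the dominant live error mode;
biomedical-species hallucination traps under plant-titled papers;
heterologous-host species mentions; and a split-donor layout that states
the donor in the methods section away from the acceptor/product
discussion. Category counts are exact (`round(rate · n)`), never
Bernoulli draws, so downstream flag fractions can be asserted as
equalities. Reference tables (lineage, ID-mapping) cover all planted
species and IDs plus distractors, with a planted mappable fraction
(default 0.58). PDFs are single-font, uncompressed text-layer documents
produced by the in-package writer and read back by the in-package
extractor.

What passing tests therefore show: the pipeline's plumbing, splitting,
curation rules and metrics are exactly correct on documents whose
structure is known. What they do not show: robustness to real PDF
typography, OCR noise, chemical-name synonymy, or the extraction quality
of any live model.

## Problem sizes and numerical choices

The default test/acceptance corpora use 100 positive papers (about 200
planted activities; 1–3 per paper), a 347-abstract screening analog
(173/174) and 10⁴-token fuzzing for accession patterns — sizes chosen so
the whole suite and the acceptance script each complete in seconds while
every rate assertion remains exact. Ties and degenerate inputs: a
single-year query window whose hit count exceeds the retrieval cap is
returned alone and flagged rather than split; records without abstracts
are retained with empty abstracts; an empty HQD slice yields undefined
(not zero) recall; an image-only PDF yields empty text with a warning and
is routed to the attachment-only path.

## Known limitations

No chemical-name normalization or structure resolution; no OCR; no live
UniProt/NCBI queries during tests; Zotero automation is out of scope (the
package emits RIS and consumes a populated storage folder); the live
backend's batch transport is modeled as serialized request/response files
only. The screening prompt texts are editable approximations of the
strict/inclusive wording families, not verbatim production prompts.
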