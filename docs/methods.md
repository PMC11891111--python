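# Methods

## Problem and model

A clinical note *T* yields a set of recognized entities, each a pair
(*e*, *l_e*) of surface text and context label. The goal is to map each
entity to the set *h* of concept unique identifiers (CUIs) that normalize
it against a controlled vocabulary. The pipeline realizes this as a
cost-aware cascade: cheap symbolic retrieval resolves the easy cases, and
the expensive LLM is consulted only when the symbolic evidence is genuinely
ambiguous.

### Background knowledge base

The BK aggregates vocabulary atoms (CUI, label, language, source, term
type, semantic types, definitions) into one entry per CUI. Labels are
compared after normalization — NFC, lowercase, accent folding (keeping
"ñ"), whitespace collapse — and each label's **linking score** is the
number of source records asserting it; the assumption is that a label
assigned independently by many source vocabularies is the concept's most
appropriate name. Raw label strings are preserved for display and prompts.

Each (CUI, label) pair becomes one index document with three fields:
`label` (the label's own tokens), `synonyms` (tokens of the concept's other
labels) and `definition` (tokens of all its definitions). Scoring is Okapi
BM25 with a lower-bound term (BM25+ style):

```
idf(t)      = ln(1 + (N - df_t + 0.5) / (df_t + 0.5))
score(q, d) = Σ_{t ∈ q, tf>0} idf(t) · (δ + tf(k1+1) / (tf + k1(1 − b + b·dl/avgdl)))
```

with defaults k1 = 1.2, b = 0.75, δ = 1.0, all configurable. Query tokens
are deduplicated; tokens absent from a document contribute nothing, so the
δ floor applies only to matched terms (a pure rank-preserving offset
otherwise). Each field is its own collection with its own document
frequencies and average length. The exact variant the approach was
originally tuned with is not published; this formulation was chosen because
it is standard and fully checkable against a closed-form oracle.

### Query types

Five query types trade precision against recall, and their hit sets are
nested by construction (`Exact ⊆ Basic_Fuzzy ⊆ Multi_match`,
`Multi_match_SPA ⊆ Multi_match`):

* **Exact** — normalized-label equality; ties broken by linking score then
  CUI, which makes the linking score the effective ranking signal.
* **Basic_Fuzzy** — per-token edit-distance matching on the label field;
  budget 1 for tokens of length ≤ 5, else 2 (the usual search-engine AUTO
  convention, since only "slight variations" are intended). A fuzzy-matched
  term's frequency is the sum over its expansion and its IDF the best
  (rarest) matched token, mirroring search-engine fuzzy scoring.
* **Multi_match / Multi_match_SPA** — fuzzy best-field retrieval over
  label/synonyms/definition (definition down-weighted ×0.5 so definition
  prose cannot outrank a label match); the SPA variant restricts to Spanish
  labels.
* **Multi_match_boosted** — Multi_match with a ×2.0 score boost for
  candidates whose label contains a cancer-lexicon token
  ({cáncer, cancer, carcinoma, tumor, neoplasia, maligno}, configurable).

Retrieval order is (score desc, linking score desc, CUI asc, label asc) —
a total order, so rankings are reproducible and oracle-checkable. How the
linking score should interact with BM25 rank is not formalized anywhere;
here BM25 is primary and the linking score breaks ties, and both values are
carried on every candidate so other policies can be layered on.

### Filtering and decision

Each candidate is scored against the mention with the Ratcliff–Obershelp
ratio s(a,b) = 2M/(|a|+|b|) on normalized strings (M = total matching-block
length; stdlib `difflib` with autojunk off, validated against an
independent quadratic implementation). Candidates with s ≥ θ_sim (default
0.96) form the *confident* set; "at or above" is deliberate so that θ = 1.0
still admits exact matches. Three scenarios follow:

* no candidates → **NO_CANDIDATE**: translate and retry;
* confident set covers exactly one CUI → **DIRECT_LINK**: no LLM call;
* otherwise → **AMBIGUOUS**: the confident set (or, when nothing cleared
  the threshold, the full retrieved set flagged *low-confidence*) goes to
  the LLM. The low-confidence pass-through may contain a single CUI; it is
  still sent to the LLM rather than trusted, because sub-threshold
  similarity is exactly the regime where surface matching misleads.

Grouping by CUI keeps the best label per concept (highest similarity, then
retrieval score).

### Disambiguation and translation

Prompts render the entity, its context label, and every candidate's CUI,
label, semantic group and definition, each exactly once; when a concept has
several definitions the NCI-sourced one is preferred (NCI is the
authoritative cancer source), then MSH, SNOMED CT, MDR, ICD-10-CM, then any
source alphabetically, then a placeholder. Three prompt styles exist
(zero-shot, few-shot with two synthetic exemplars, chain-of-thought); CoT
is the default. The prompt requests a machine-readable final line
(`ANSWER: <CUIs>` or `ANSWER: NONE` + `TRANSLATION: <English term>`), and
the parser additionally falls back to scanning free text for offered CUIs.
CUIs outside the offered set are always discarded. Defaults temperature 0
and max_tokens 512 favor determinism.

The pipeline is LLM-agnostic: any `complete(prompt) → response` object
works. Shipped clients are deterministic mocks — an oracle (answers from a
ground-truth map, translates from a fixture dictionary), an adversarial
client (always "NONE"), and a scripted replayer. Token accounting is a
whitespace count, a uniform proxy adequate for call-budget audits (not for
API billing).

### Orchestration

Linking is Spanish-first: round 0 searches the mention as written; if the
decision ends unresolved (no candidates, or the LLM finds all candidates
inadequate), the term is translated to English — reusing a translation the
LLM already volunteered, otherwise one dedicated translation call — and the
search repeats without a language pin. `max_translation_rounds` (default 1:
one Spanish pass + one English pass) bounds the loop, which the original
description leaves unbounded. If a translation round again yields several
CUIs, the same decision logic (including the LLM) applies to that round.
Per entity there are at most `1 + max_translation_rounds` retrieval passes,
at most one disambiguation call per AMBIGUOUS decision, and at most one
translation call per round.

Resolved entities are cached by (normalized surface, context label, config
hash) — linking is context-dependent but note-independent — so repeated
mentions cost no further LLM calls; the cache can persist to disk and is
invalidated by any config or index change through the hash. Per-entity
failures are isolated (logged, reported UNLINKED) so one bad mention cannot
abort a batch. Statuses are LINKED_DIRECT, LINKED_LLM,
LINKED_AFTER_TRANSLATION and UNLINKED; an UNLINKED result is an outcome,
not an error.

## Evaluation

Accuracy = |G ∩ R| / |G| (undefined for empty G, rejected), and
Accuracy@N applies the same after truncating the deduplicated ranked output
to N; it is non-decreasing in N. Predictions and gold are matched by exact
(normalized text, context) pairs; gold records never produced are scored 0
and listed, so silent drops are penalized; means are unweighted. The sweep
harness evaluates a config grid (query types, θ values, prompt styles) one
row per config, recording failures without aborting.

## Synthetic data

The generator emulates the structures the pipeline must handle, not
clinical prose:

* **Vocabulary** — bilingual 2–3-token surfaces from a seed oncology
  lexicon; duplicate label assertions across fake sources (exercising
  linking scores), synonyms at `synonym_rate`, per-concept definitions with
  an NCI-tagged subset, semantic types derived from the context label.
  Synthetic CUIs live in a reserved C9xxxxxx range.
* **Languages** — every concept has an English label and a Spanish one with
  probability `spa_share/eng_share` (defaults 0.4/0.6, so roughly a third
  of concepts are English-only); English-only concepts' Spanish aliases are
  exactly the translation-fallback cases and populate the fixture
  translation dictionary.
* **Homonyms** — `round(n_concepts · homonym_rate / 2)` surfaces are each
  shared by two CUIs with different context labels; only one reading is
  planted in notes, so gold stays single-valued while retrieval sees the
  ambiguity.
* **Notes** — template sentences with planted mentions (offsets recorded),
  optional one-character typos at `typo_rate` (guaranteed not to collide
  with any real surface), and occasional planted acronyms ("ca.", "Dx")
  exercising expansion. Gold, gazetteer lexicon and the mocks' truth map
  are emitted alongside.

All randomness flows from one seed; identical specs produce byte-identical
worlds. What passing tests on this data shows: the machinery (retrieval
ranking, thresholds, decision logic, translation loop, caching,
determinism) is correct. What it does not show: performance on real
clinical Spanish, whose spelling variation, negation and discourse
structure the templates do not model, nor behavior with a real
(hallucination-prone) LLM — the adversarial client bounds the damage case
but not intermediate ones.

## Sizes and numerical choices

Tests and the acceptance script use vocabularies of 40–60 concepts
(≤ ~100 index documents, where exhaustive-scoring oracles are exact) and
corpora of 200+ planted mentions, enough for stable statistics while
keeping the full suite under a minute. Degenerate inputs are pinned down
explicitly: empty vocabularies error at index build; empty candidate lists
decide NO_CANDIDATE; s("", "") = 1 by the identity convention; θ_sim and
rates are validated to [0, 1]. All orderings (labels, candidates, sweep
rows) carry documented total tie-breaks, so shuffled input re-aggregates
identically and reruns are byte-identical.

## Known limitations

* The gazetteer recognizer is exact-phrase (case/accent-insensitive,
  longest match); recall on real notes requires plugging in a trained NER
  model behind the same BIO interface.
* BM25 parameters and field weights are defensible defaults, not tuned
  values; the sweep harness exists precisely to re-tune them on licensed
  data (UMLS + a real benchmark + a hosted LLM), which this package does
  not ship.
* Retrieval is in-process and loads the whole index in memory — appropriate
  up to, say, hundreds of thousands of documents, not a full metathesaurus
  behind a search service.
* Translation quality is delegated entirely to the LLM client; the mock's
  dictionary makes it perfect in tests, which real translation is not.
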