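# clinlink

Neuro-symbolic entity linking for Spanish oncology clinical notes: recognized
mentions are normalized to **concept unique identifiers (CUIs)** of a medical
vocabulary (UMLS-style) by combining symbolic candidate retrieval with
LLM-based disambiguation.

Clinical narratives name the same concept many ways — abbreviations
("ca. de mama"), paraphrases ("mama parte derecha" for the vocabulary term
"mama derecha"), and homonyms ("boost" as a radiotherapy dose vs. other
senses) — and most vocabulary terms exist only in English while the notes
are Spanish. `clinlink` mimics how a clinician resolves a term:

1. **NER** — recognize mentions and their context labels (e.g. *Cancer
   location*, *Treatment name*) with a pluggable recognizer; a deterministic
   gazetteer is shipped, a transformer model can be dropped in.
2. **MEL** — query a background knowledge base (BK) built from the
   vocabulary: every (CUI, label) pair is a BM25-indexed document with
   fields *label* / *synonyms* / *definition*, and each label carries a
   **linking score** (how many source vocabularies assigned it). Five query
   types span exact matching to fuzzy multi-field retrieval with a
   cancer-lexicon boost. The top-*k* candidates are scored against the
   mention with the Ratcliff–Obershelp similarity
   *s*(a, b) = 2M/(|a|+|b|) and compared with a threshold θ_sim.
3. **Decision** — one confident CUI links directly (no LLM); several CUIs,
   or none above θ_sim, go to disambiguation.
4. **MED** — a chain-of-thought prompt lists each candidate's CUI, label,
   semantic group and definition (NCI definitions preferred); the LLM
   selects CUI(s) or declares the candidates inadequate and supplies an
   English translation, after which the search is retried (bounded rounds).

Evaluation uses Accuracy = |G ∩ R| / |G| and Accuracy@N over gold CUI sets
G, with sweep harnesses over query type, θ_sim and prompt style. Everything
is testable offline: a seeded synthetic generator emulates the vocabulary
(duplicate labels, synonyms, homonyms, definitions) and the note corpus,
and deterministic mock LLM clients (oracle / adversarial / scripted)
replace the hosted model.

## Worked example

```python
from clinlink import (
    PipelineConfig, QType, TermRecord, aggregate_concepts, build_index,
    ClinicalNote, gazetteer_recognizer, link_note, mock_llm,
)

records = [
    TermRecord(cui="C0007097", label="carcinoma", lang="SPA", source="SNOMEDCT"),
    TermRecord(cui="C0007097", label="carcinoma", lang="ENG", source="NCI"),
    TermRecord(cui="C9100001", label="ductal", lang="SPA", source="SNOMEDCT"),
    TermRecord(cui="C9100002", label="in situ", lang="SPA", source="SNOMEDCT"),
    TermRecord(cui="C9100003", label="right breast", lang="ENG", source="NCI"),
]
index = build_index(aggregate_concepts(records))

lexicon = {
    "carcinoma": "Cancer concept",
    "ductal": "Cancer type",
    "in situ": "Cancer expansion",
    "mama derecha": "Cancer location",
}
note = ClinicalNote(
    "n1", "Paciente diagnosticado con carcinoma ductal in situ en mama derecha"
)
llm = mock_llm("oracle", truth={}, translations={"mama derecha": "right breast"})
config = PipelineConfig(q_type=QType.EXACT)

for linked in link_note(note, index, config, gazetteer_recognizer(lexicon), llm):
    print(f"{linked.entity.surface!r:16} {linked.entity.label:17} "
          f"-> {set(linked.cuis)} [{linked.status.value}]")
```

prints

```
'carcinoma'      Cancer concept    -> {'C0007097'} [LINKED_DIRECT]
'ductal'         Cancer type       -> {'C9100001'} [LINKED_DIRECT]
'in situ'        Cancer expansion  -> {'C9100002'} [LINKED_DIRECT]
'mama derecha'   Cancer location   -> {'C9100003'} [LINKED_AFTER_TRANSLATION]
```

The first three mentions each have a unique confident vocabulary match and
link directly, with no LLM call. "mama derecha" exists only in English in
this toy vocabulary: the Spanish search finds nothing, the client translates
it to "right breast", and the English retry links it — the
translate-and-retry fallback in action.

The same flow is available from the shell:

```sh
clinlink synth --seed 5 --out data/                 # synthetic world
clinlink build-bk --simple-vocab data/vocab.jsonl --out bk/
clinlink link --input data/notes.jsonl --index bk/ --lexicon data/lexicon.json \
    --llm mock-oracle --gold data/gold.jsonl --translations data/translations.json \
    --out links.jsonl
clinlink eval --pred links.jsonl --gold data/gold.jsonl --at 1 --at 5 --at 15
```

Real UMLS releases are supported through `clinlink build-bk
--mrconso MRCONSO.RRF --mrsty MRSTY.RRF --mrdef MRDEF.RRF` (pipe-delimited
Rich Release Format; suppressed atoms dropped, languages filterable).

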