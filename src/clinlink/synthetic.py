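"""Deterministic synthetic vocabularies, notes, gold benchmarks and mock LLMs.

Everything the pipeline consumes — a multilingual vocabulary with duplicate
labels across sources, synonyms, homonyms, semantic types and multi-source
definitions; clinical-note-like texts with planted mentions; a gold
benchmark of (text, context, CUIs) records; and deterministic LLM clients —
is generated from a seeded spec, so every stage is testable with no
download and no network.

Synthetic CUIs use a reserved ``C9xxxxxx`` range to avoid collision with
real UMLS identifiers in mixed tests.  Surfaces are built from a small
bilingual oncology-flavored seed lexicon; no real patient-derived text
appears anywhere.
"""

from __future__ import annotations

import json
import random
import re
from dataclasses import dataclass, field
from pathlib import Path

from ._text import normalize
from .med import LLMResponse, count_tokens
from .ner import ClinicalNote
from .vocab import Definition, TermRecord

#: Context labels of the annotation scheme (benchmark label set).
DEFAULT_LABEL_SET = (
    "Cancer concept",
    "Cancer type",
    "Cancer subtype",
    "Cancer expansion",
    "Cancer location",
    "Surgery",
    "Treatment drug",
    "Treatment name",
)

_STY_BY_LABEL = {
    "Cancer concept": "Neoplastic Process",
    "Cancer type": "Neoplastic Process",
    "Cancer subtype": "Neoplastic Process",
    "Cancer expansion": "Neoplastic Process",
    "Cancer location": "Body Part, Organ, or Organ Component",
    "Surgery": "Therapeutic or Preventive Procedure",
    "Treatment drug": "Pharmacologic Substance",
    "Treatment name": "Therapeutic or Preventive Procedure",
}

#: Bilingual (Spanish, English) seed lexicon; concept surfaces are 2-3 token
#: combinations of these, so single expanded acronyms never collide with them.
_LEXICON: tuple[tuple[str, str], ...] = (
    ("cáncer", "cancer"), ("mama", "breast"), ("pulmón", "lung"),
    ("carcinoma", "carcinoma"), ("tumor", "tumor"), ("metástasis", "metastasis"),
    ("ductal", "ductal"), ("lobulillar", "lobular"), ("izquierda", "left"),
    ("derecha", "right"), ("quimioterapia", "chemotherapy"),
    ("radioterapia", "radiotherapy"), ("mastectomía", "mastectomy"),
    ("biopsia", "biopsy"), ("ganglio", "node"), ("axilar", "axillary"),
    ("maligno", "malignant"), ("benigno", "benign"), ("invasivo", "invasive"),
    ("cirugía", "surgery"), ("hormonal", "hormonal"), ("superior", "upper"),
    ("inferior", "lower"), ("cuadrante", "quadrant"), ("piel", "skin"),
    ("hígado", "liver"), ("hueso", "bone"), ("recidiva", "recurrence"),
    ("lesión", "lesion"), ("nódulo", "nodule"), ("quiste", "cyst"),
    ("adenopatía", "adenopathy"),
)

_SYNONYM_QUALIFIERS = ("zona", "región", "área", "proceso")
_SOURCES = ("SRC_A", "SRC_B", "SNOMEDCT", "MSH")

_NOTE_OPENINGS = (
    "Paciente en seguimiento oncológico.",
    "Revisión de evolución clínica.",
    "Valoración en consulta externa.",
)
_NOTE_OPENING_ACRONYM = "Dx de ca. confirmado en consulta."
_NOTE_CONNECTORS = ("Se observa", "Se indica", "Compatible con", "Control de")


@dataclass(frozen=True)
class SynthSpec:
    """Study conditions of the synthetic benchmark generator.

    Language proportions default to SPA 0.4 / ENG 0.6 (English labels
    dominate the vocabulary, as in real metathesauri); every concept gets an
    English label and a Spanish one with probability spa_share/eng_share, so
    some Spanish mentions can only be linked after translation.
    """

    seed: int = 0
    n_concepts: int = 50
    spa_share: float = 0.4
    eng_share: float = 0.6
    synonym_rate: float = 0.3
    homonym_rate: float = 0.1
    typo_rate: float = 0.05
    duplicate_label_rate: float = 0.5
    nci_definition_rate: float = 0.6
    acronym_rate: float = 0.2
    label_set: tuple[str, ...] = DEFAULT_LABEL_SET
    n_notes: int = 20
    mentions_per_note: int = 3

    def __post_init__(self) -> None:
        for name in ("spa_share", "eng_share", "synonym_rate", "homonym_rate",
                     "typo_rate", "duplicate_label_rate", "nci_definition_rate",
                     "acronym_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_concepts < 1:
            raise ValueError("n_concepts must be >= 1")

    @property
    def spa_coverage(self) -> float:
        """Probability that a concept carries a Spanish vocabulary label."""
        if self.eng_share <= 0:
            return 1.0
        return min(1.0, self.spa_share / self.eng_share)


@dataclass
class SynthConcept:
    cui: str
    spa_surface: str          # Spanish surface (vocabulary label or note-only alias)
    eng_surface: str
    context: str
    has_spa_label: bool       # False -> Spanish surface absent from the vocabulary
    homonym_partner: str | None = None
    plantable: bool = True


@dataclass
class SynthVocab:
    spec: SynthSpec
    records: list[TermRecord]
    concepts: list[SynthConcept]
    truth: dict[str, set[str]]            # normalized surface -> CUI set
    translations: dict[str, str]          # normalized SPA surface -> English label
    homonym_surfaces: list[str]           # normalized surfaces shared by 2 CUIs

    @property
    def n_cuis(self) -> int:
        return len({r.cui for r in self.records})


@dataclass(frozen=True)
class PlantedMention:
    note_id: str
    surface: str
    context: str
    start: int
    end: int
    cuis: frozenset[str]


@dataclass
class SynthCorpus:
    notes: list[ClinicalNote]
    gold: list[dict]                       # {text, context, cuis}
    lexicon: dict[str, str]                # gazetteer surface -> context label
    planted: list[PlantedMention]
    oracle_map: dict                       # (norm surface, context) -> CUI set
    translations: dict[str, str]


# ---------------------------------------------------------------------------
# Vocabulary generation
# ---------------------------------------------------------------------------

def _surface_pairs(rng: random.Random, n: int) -> list[tuple[str, str]]:
    """n unique bilingual surfaces as 2-3 token lexicon combinations."""
    pairs: list[tuple[str, str]] = []
    # one pool across languages: a Spanish surface must not collide with any
    # English surface either, or it would create an unplanned homonym
    seen: set[str] = set()
    m = len(_LEXICON)
    while len(pairs) < n:
        size = 2 if rng.random() < 0.8 else 3
        idxs = rng.sample(range(m), size)
        spa = " ".join(_LEXICON[i][0] for i in idxs)
        eng = " ".join(_LEXICON[i][1] for i in idxs)
        if normalize(spa) in seen or normalize(eng) in seen:
            continue
        seen.add(normalize(spa))
        seen.add(normalize(eng))
        pairs.append((spa, eng))
    return pairs


def gen_vocab(spec: SynthSpec) -> SynthVocab:
    """Generate vocabulary records plus the ground-truth surface map.

    Homonyms: ``round(n_concepts * homonym_rate / 2)`` surfaces are each
    shared by exactly two CUIs (so ``homonym_rate`` of the concepts sit on a
    shared surface); the two CUIs always carry different context labels and
    only the first of each pair is planted in notes.
    """
    rng = random.Random(spec.seed)
    pairs = _surface_pairs(rng, spec.n_concepts)
    concepts: list[SynthConcept] = []
    for i, (spa, eng) in enumerate(pairs):
        concepts.append(
            SynthConcept(
                cui=f"C9{100000 + i}",
                spa_surface=spa,
                eng_surface=eng,
                context=rng.choice(spec.label_set),
                has_spa_label=rng.random() < spec.spa_coverage,
            )
        )

    n_hom = int(round(spec.n_concepts * spec.homonym_rate / 2.0))
    homonym_surfaces: list[str] = []
    if n_hom:
        chosen = rng.sample(range(spec.n_concepts), 2 * n_hom)
        for a_idx, b_idx in zip(chosen[::2], chosen[1::2]):
            a, b = concepts[a_idx], concepts[b_idx]
            b.spa_surface = a.spa_surface
            a.has_spa_label = b.has_spa_label = True
            if b.context == a.context:
                b.context = next(l for l in spec.label_set if l != a.context)
            a.homonym_partner, b.homonym_partner = b.cui, a.cui
            b.plantable = False  # only one reading of the surface is planted
            homonym_surfaces.append(normalize(a.spa_surface))

    records: list[TermRecord] = []
    truth: dict[str, set[str]] = {}
    translations: dict[str, str] = {}

    def add_truth(surface: str, cui: str) -> None:
        truth.setdefault(normalize(surface), set()).add(cui)

    def emit(concept: SynthConcept, label: str, lang: str) -> None:
        n_copies = 1 + (1 if rng.random() < spec.duplicate_label_rate else 0)
        for source in rng.sample(_SOURCES, n_copies):
            records.append(
                TermRecord(
                    cui=concept.cui,
                    label=label,
                    lang=lang,
                    source=source,
                    stys=(_STY_BY_LABEL.get(concept.context, "Finding"),),
                    definitions=defs_by_cui[concept.cui],
                )
            )
        add_truth(label, concept.cui)

    defs_by_cui: dict[str, tuple[Definition, ...]] = {}
    for c in concepts:
        defs = [
            Definition(
                text=f"Synthetic definition of {c.eng_surface} in the {c.context.lower()} sense.",
                source="NCI" if rng.random() < spec.nci_definition_rate else "MSH",
            )
        ]
        if rng.random() < 0.3:
            defs.append(
                Definition(text=f"Alternate description of {c.eng_surface}.", source="SRC_A")
            )
        defs_by_cui[c.cui] = tuple(defs)

    for c in concepts:
        emit(c, c.eng_surface, "ENG")
        if c.has_spa_label:
            emit(c, c.spa_surface, "SPA")
            if rng.random() < spec.synonym_rate:
                qualifier = rng.choice(_SYNONYM_QUALIFIERS)
                emit(c, f"{qualifier} {c.spa_surface}", "SPA")
        else:
            add_truth(c.spa_surface, c.cui)  # note-only alias, not in vocabulary
        translations[normalize(c.spa_surface)] = c.eng_surface

    return SynthVocab(
        spec=spec,
        records=records,
        concepts=concepts,
        truth=truth,
        translations=translations,
        homonym_surfaces=homonym_surfaces,
    )


# ---------------------------------------------------------------------------
# Note / benchmark generation
# ---------------------------------------------------------------------------

def _typo(rng: random.Random, surface: str, forbidden: set[str]) -> str:
    """One-character edit that does not collide with any known surface."""
    letters = "abcdefghijklmnopqrstuvz"
    for _ in range(10):
        pos = rng.randrange(1, len(surface))
        if surface[pos] == " ":
            continue
        ch = rng.choice(letters)
        if ch == surface[pos]:
            continue
        mutated = surface[:pos] + ch + surface[pos + 1:]
        if normalize(mutated) not in forbidden:
            return mutated
    return surface


def gen_notes(vocab: SynthVocab, spec: SynthSpec | None = None) -> SynthCorpus:
    """Generate notes with planted mentions, the gold benchmark and lexicon.

    Each gold record keys a unique (text, context) pair; every gold CUI
    exists in the generated vocabulary truth.  Planted offsets slice the
    note text back to the mention surface.
    """
    spec = spec or vocab.spec
    rng = random.Random(spec.seed + 1)
    plantable = [c for c in vocab.concepts if c.plantable]
    known_surfaces = set(vocab.truth)

    notes: list[ClinicalNote] = []
    planted: list[PlantedMention] = []
    lexicon: dict[str, str] = {}
    gold: dict[tuple[str, str], dict] = {}
    oracle_map: dict = {}

    for note_i in range(spec.n_notes):
        note_id = f"note-{note_i:04d}"
        chosen = rng.sample(plantable, min(spec.mentions_per_note, len(plantable)))
        opening = (
            _NOTE_OPENING_ACRONYM
            if rng.random() < spec.acronym_rate
            else rng.choice(_NOTE_OPENINGS)
        )
        text = opening
        for c in chosen:
            surface = c.spa_surface
            if spec.typo_rate and rng.random() < spec.typo_rate:
                surface = _typo(rng, surface, known_surfaces)
            connector = rng.choice(_NOTE_CONNECTORS)
            text += f" {connector} "
            start = len(text)
            text += surface
            end = len(text)
            text += "."
            planted.append(
                PlantedMention(
                    note_id=note_id,
                    surface=surface,
                    context=c.context,
                    start=start,
                    end=end,
                    cuis=frozenset({c.cui}),
                )
            )
            lexicon[surface] = c.context
            key = (normalize(surface), c.context)
            gold[key] = {"text": surface, "context": c.context, "cuis": [c.cui]}
            oracle_map[key] = {c.cui}
            oracle_map.setdefault(normalize(surface), set()).add(c.cui)
        notes.append(ClinicalNote(note_id=note_id, text=text))

    return SynthCorpus(
        notes=notes,
        gold=list(gold.values()),
        lexicon=lexicon,
        planted=planted,
        oracle_map=oracle_map,
        translations=dict(vocab.translations),
    )


# ---------------------------------------------------------------------------
# Mock LLM clients
# ---------------------------------------------------------------------------

_PROMPT_CUI_RE = re.compile(r"CUI (C\d+)")


def _prompt_field(prompt: str, name: str) -> str:
    for line in prompt.splitlines():
        if line.startswith(f"{name}:"):
            return line[len(name) + 1:].strip()
    return ""


class _CountingClient:
    def __init__(self) -> None:
        self.calls = 0
        self.disambiguation_calls = 0
        self.translation_calls = 0
        self.prompt_tokens = 0
        self.completion_tokens = 0

    def _account(self, prompt: str, text: str) -> LLMResponse:
        self.calls += 1
        if prompt.startswith("TASK: translate"):
            self.translation_calls += 1
        else:
            self.disambiguation_calls += 1
        self.prompt_tokens += count_tokens(prompt)
        self.completion_tokens += count_tokens(text)
        return LLMResponse(text, count_tokens(prompt), count_tokens(text))


class OracleClient(_CountingClient):
    """Answers with the gold CUIs when offered; otherwise declares the
    candidates inadequate and supplies the fixture translation."""

    def __init__(self, truth: dict, translations: dict[str, str] | None = None):
        super().__init__()
        self.truth = truth
        self.translations = {normalize(k): v for k, v in (translations or {}).items()}

    def complete(self, prompt: str) -> LLMResponse:
        if prompt.startswith("TASK: translate"):
            term = _prompt_field(prompt, "TERM")
            eng = self.translations.get(normalize(term))
            return self._account(prompt, f"ANSWER: {eng}" if eng else "ANSWER: NONE")
        entity = _prompt_field(prompt, "ENTITY")
        context = _prompt_field(prompt, "CONTEXT")
        offered = set(_PROMPT_CUI_RE.findall(prompt))
        gold = self.truth.get((normalize(entity), context)) or self.truth.get(
            normalize(entity), set()
        )
        selected = sorted(set(gold) & offered)
        if selected:
            text = (
                "Comparing each candidate's definition and semantic group with the "
                f"context '{context}', the matching concept is clear.\n"
                "ANSWER: " + ", ".join(selected)
            )
        else:
            eng = self.translations.get(normalize(entity))
            text = "ANSWER: NONE" + (f"\nTRANSLATION: {eng}" if eng else "")
        return self._account(prompt, text)


class AdversarialClient(_CountingClient):
    """Always declares the candidates inadequate and refuses to translate."""

    def complete(self, prompt: str) -> LLMResponse:
        return self._account(prompt, "ANSWER: NONE")


class ScriptedMockClient(_CountingClient):
    """Replays canned responses; exhaustion is an error."""

    def __init__(self, responses: list[str]):
        super().__init__()
        self._responses = list(responses)
        self._i = 0

    def complete(self, prompt: str) -> LLMResponse:
        from .med import LLMTransportError

        if self._i >= len(self._responses):
            raise LLMTransportError("scripted responses exhausted")
        text = self._responses[self._i]
        self._i += 1
        return self._account(prompt, text)


def mock_llm(
    mode: str,
    truth: dict | None = None,
    translations: dict[str, str] | None = None,
    script: list[str] | str | Path | None = None,
):
    """Build a deterministic mock LLM client: oracle, adversarial or scripted."""
    if mode == "oracle":
        if truth is None:
            raise ValueError("oracle mode requires the ground-truth map")
        return OracleClient(truth, translations)
    if mode == "adversarial":
        return AdversarialClient()
    if mode == "scripted":
        if script is None:
            raise ValueError("scripted mode requires responses")
        if isinstance(script, (str, Path)):
            script = [
                l for l in Path(script).read_text(encoding="utf-8").splitlines() if l.strip()
            ]
        return ScriptedMockClient(script)
    raise ValueError(f"unknown mock mode {mode!r}")


# ---------------------------------------------------------------------------
# On-disk fixture export
# ---------------------------------------------------------------------------

def write_corpus(vocab: SynthVocab, corpus: SynthCorpus, out_dir: str | Path) -> None:
    """Write vocab.jsonl / notes.jsonl / gold.jsonl / lexicon.json /
    translations.json into a directory."""
    from .vocab import dump_simple_vocab

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dump_simple_vocab(vocab.records, out / "vocab.jsonl")
    with open(out / "notes.jsonl", "w", encoding="utf-8") as fh:
        for note in corpus.notes:
            fh.write(json.dumps({"note_id": note.note_id, "text": note.text},
                                ensure_ascii=False) + "\n")
    with open(out / "gold.jsonl", "w", encoding="utf-8") as fh:
        for rec in corpus.gold:
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")
    (out / "lexicon.json").write_text(
        json.dumps(corpus.lexicon, ensure_ascii=False, indent=2), encoding="utf-8"
    )
    (out / "translations.json").write_text(
        json.dumps(corpus.translations, ensure_ascii=False, indent=2), encoding="utf-8"
    )
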