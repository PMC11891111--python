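"""LLM-based medical entity disambiguation.

When candidate retrieval leaves more than one plausible concept (or only
low-confidence ones), a prompt is built over the candidates' CUIs, labels,
semantic groups and definitions and sent to a pluggable LLM client.  The
model either selects CUI(s) from the offered set, or declares the
candidates inadequate — optionally supplying an English translation of the
mention so the search can be retried.

The pipeline is LLM-agnostic: any object with
``complete(prompt) -> LLMResponse`` works.  Deterministic clients
(scripted replay here; oracle/adversarial mocks in :mod:`.synthetic`) make
the whole system testable offline.

Response contract: prompts instruct a machine-readable final section ::

    ANSWER: C0007097           (one or more CUIs, comma-separated)
    ANSWER: NONE
    TRANSLATION: right breast  (only after ANSWER: NONE, when translating)

The parser falls back to scanning the free text for offered CUIs, so a
model that reasons in prose but names the CUI is still understood.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

from ._text import normalize

logger = logging.getLogger(__name__)

_CUI_RE = re.compile(r"C\d+")

#: Definition-source priority: NCI (National Cancer Institute) first, as the
#: authoritative source for cancer concepts, then other major vocabularies.
DEF_SOURCE_PRIORITY = ("NCI", "MSH", "SNOMEDCT_US", "SNOMEDCT", "MDR", "ICD10CM")

NO_DEFINITION = "no definition available"


def select_definition(concept_entry) -> tuple[str, str | None]:
    """Pick one definition for a concept, preferring NCI-sourced text.

    Falls back through :data:`DEF_SOURCE_PRIORITY`, then any remaining source
    in alphabetical order, then a placeholder when the concept carries no
    definition at all.
    """
    defs = list(concept_entry.definitions)
    if not defs:
        return NO_DEFINITION, None
    for source in DEF_SOURCE_PRIORITY:
        hits = [d for d in defs if d.source == source]
        if hits:
            best = min(hits, key=lambda d: d.text)
            return best.text, best.source
    best = min(defs, key=lambda d: (d.source, d.text))
    return best.text, best.source


# ---------------------------------------------------------------------------
# Prompt construction
# ---------------------------------------------------------------------------

class PromptStyle(str, Enum):
    ZERO_SHOT = "zero_shot"
    FEW_SHOT = "few_shot"
    COT = "cot"


#: Two synthetic exemplars for few-shot prompting (configurable).
DEFAULT_EXEMPLARS = (
    "ENTITY: tumor maligno\nCONTEXT: Cancer concept\n"
    "CANDIDATE 1: CUI C9100001 | LABEL malignant tumor | GROUP Neoplastic Process | "
    "DEFINITION an abnormal malignant growth of tissue.\n"
    "ANSWER: C9100001",
    "ENTITY: zona dudosa\nCONTEXT: Cancer location\n"
    "CANDIDATE 1: CUI C9100002 | LABEL unrelated finding | GROUP Finding | "
    "DEFINITION a finding unrelated to the mention.\n"
    "ANSWER: NONE\nTRANSLATION: doubtful area",
)

_HEADER = (
    "TASK: disambiguate\n"
    "You are a clinical terminology expert. A medical entity was recognized in a "
    "Spanish oncology note and must be linked to the correct concept unique "
    "identifier(s) (CUIs) of a medical vocabulary.\n"
)

_COT_INSTRUCTIONS = (
    "Think step by step: compare the entity and its context with each candidate's "
    "label, semantic group and definition, and explain your reasoning. Then state "
    "whether a suitable CUI exists among the candidates. If one or more are "
    "suitable, finish with a line 'ANSWER: <comma-separated CUIs>'. If none is "
    "suitable, finish with 'ANSWER: NONE' followed by a line "
    "'TRANSLATION: <English translation of the entity>'.\n"
)

_PLAIN_INSTRUCTIONS = (
    "Reply with a line 'ANSWER: <comma-separated CUIs>' choosing among the "
    "candidates, or 'ANSWER: NONE' followed by "
    "'TRANSLATION: <English translation of the entity>' if none is suitable.\n"
)


@dataclass(frozen=True)
class PromptSpec:
    style: PromptStyle = PromptStyle.COT
    max_tokens: int = 512
    temperature: float = 0.0
    exemplars: tuple[str, ...] = DEFAULT_EXEMPLARS


def build_prompt(entity, candidates, prompt_spec: PromptSpec) -> str:
    """Render the disambiguation prompt; same inputs give identical bytes.

    Lists each candidate with CUI, label, semantic group and definition,
    plus the entity surface and its context label.
    """
    if not candidates:
        raise ValueError("build_prompt requires at least one candidate")
    lines = [_HEADER]
    if prompt_spec.style is PromptStyle.FEW_SHOT:
        for i, ex in enumerate(prompt_spec.exemplars, start=1):
            lines.append(f"EXAMPLE {i}:\n{ex}\n")
    lines.append(f"ENTITY: {entity.surface}")
    lines.append(f"CONTEXT: {entity.label}")
    for i, cand in enumerate(candidates, start=1):
        if not cand.cui:
            raise ValueError("candidate missing a CUI")
        definition = cand.definition or NO_DEFINITION
        group = cand.semantic_type or "unknown"
        lines.append(
            f"CANDIDATE {i}: CUI {cand.cui} | LABEL {cand.matched_label} | "
            f"GROUP {group} | DEFINITION {definition}"
        )
    if prompt_spec.style is PromptStyle.COT:
        lines.append(_COT_INSTRUCTIONS)
    else:
        lines.append(_PLAIN_INSTRUCTIONS)
    return "\n".join(lines)


def build_translation_prompt(term: str) -> str:
    return (
        "TASK: translate\n"
        f"TERM: {term}\n"
        "Translate the medical term above from Spanish into English. "
        "Reply with a line 'ANSWER: <English term>'.\n"
    )


def count_tokens(text: str) -> int:
    """Whitespace-token count used for prompt/response accounting."""
    return len(text.split())


# ---------------------------------------------------------------------------
# Clients
# ---------------------------------------------------------------------------

class LLMTransportError(RuntimeError):
    """A (possibly transient) client/transport failure."""


@dataclass
class LLMResponse:
    text: str
    prompt_tokens: int = 0
    completion_tokens: int = 0


class ScriptedClient:
    """Replays canned responses in order; raises when the script runs out."""

    def __init__(self, responses):
        if isinstance(responses, (str, Path)):
            responses = [
                json.loads(line)["response"] if line.lstrip().startswith("{") else line
                for line in Path(responses).read_text(encoding="utf-8").splitlines()
                if line.strip()
            ]
        self._responses = list(responses)
        self._i = 0
        self.calls = 0
        self.prompt_tokens = 0
        self.completion_tokens = 0

    def complete(self, prompt: str) -> LLMResponse:
        if self._i >= len(self._responses):
            raise LLMTransportError("scripted responses exhausted")
        text = self._responses[self._i]
        self._i += 1
        self.calls += 1
        self.prompt_tokens += count_tokens(prompt)
        self.completion_tokens += count_tokens(text)
        return LLMResponse(text, count_tokens(prompt), count_tokens(text))


# ---------------------------------------------------------------------------
# Response parsing & disambiguation
# ---------------------------------------------------------------------------

class Outcome(str, Enum):
    SELECTED = "SELECTED"
    INADEQUATE = "INADEQUATE"


@dataclass
class DisambiguationResult:
    outcome: Outcome
    selected_cuis: frozenset[str] = frozenset()
    translation: str | None = None
    rationale: str = ""
    prompt_tokens: int = 0
    completion_tokens: int = 0


def parse_response(raw: str, offered_cuis) -> DisambiguationResult:
    """Total parser for LLM replies.

    CUIs named outside the offered candidate set are discarded; a declared
    'ANSWER: NONE' with a 'TRANSLATION:' line yields INADEQUATE with the
    translation; anything unparseable yields INADEQUATE without one.
    """
    offered = set(offered_cuis)
    answer_line = None
    translation = None
    for line in raw.splitlines():
        stripped = line.strip()
        upper = stripped.upper()
        if upper.startswith("ANSWER:"):
            answer_line = stripped[len("ANSWER:"):].strip()
        elif upper.startswith("TRANSLATION:"):
            translation = stripped[len("TRANSLATION:"):].strip() or None

    if answer_line is not None:
        if answer_line.strip().upper().startswith("NONE"):
            return DisambiguationResult(
                Outcome.INADEQUATE, translation=translation, rationale=raw
            )
        cuis = frozenset(c for c in _CUI_RE.findall(answer_line) if c in offered)
        if cuis:
            return DisambiguationResult(Outcome.SELECTED, selected_cuis=cuis, rationale=raw)

    # fallback: scan the whole reply for offered CUIs
    cuis = frozenset(c for c in _CUI_RE.findall(raw) if c in offered)
    if cuis:
        return DisambiguationResult(Outcome.SELECTED, selected_cuis=cuis, rationale=raw)
    logger.debug("unparseable LLM response: %.120s", raw)
    return DisambiguationResult(Outcome.INADEQUATE, translation=translation, rationale=raw)


def disambiguate(
    llm_client,
    entity,
    candidates,
    prompt_spec: PromptSpec = PromptSpec(),
    max_retries: int = 3,
) -> DisambiguationResult:
    """One LLM call (plus bounded transport retries) to pick among candidates."""
    prompt = build_prompt(entity, candidates, prompt_spec)
    offered = [c.cui for c in candidates]
    last_exc: Exception | None = None
    for _ in range(max_retries):
        try:
            response = llm_client.complete(prompt)
        except LLMTransportError as exc:
            last_exc = exc
            continue
        result = parse_response(response.text, offered)
        result.prompt_tokens = response.prompt_tokens
        result.completion_tokens = response.completion_tokens
        return result
    logger.warning("LLM client failed after %d retries: %s", max_retries, last_exc)
    return DisambiguationResult(Outcome.INADEQUATE, rationale=f"client failure: {last_exc}")


class TranslationError(RuntimeError):
    """The client produced no usable translation."""


def translate(llm_client, term: str) -> str:
    """Ask the client for an English translation of a (Spanish) term."""
    if not term.strip():
        raise ValueError("cannot translate an empty term")
    try:
        response = llm_client.complete(build_translation_prompt(term))
    except LLMTransportError as exc:
        raise TranslationError(str(exc)) from exc
    for line in response.text.splitlines():
        stripped = line.strip()
        if stripped.upper().startswith("ANSWER:"):
            answer = stripped[len("ANSWER:"):].strip()
            if answer and answer.upper() != "NONE":
                return answer
            break
    raise TranslationError(f"no translation for {term!r}")


__all__ = [
    "DEF_SOURCE_PRIORITY",
    "DisambiguationResult",
    "LLMResponse",
    "LLMTransportError",
    "Outcome",
    "PromptSpec",
    "PromptStyle",
    "ScriptedClient",
    "TranslationError",
    "build_prompt",
    "build_translation_prompt",
    "count_tokens",
    "disambiguate",
    "parse_response",
    "select_definition",
    "translate",
]
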