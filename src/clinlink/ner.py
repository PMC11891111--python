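"""Clinical-note preprocessing and entity recognition.

The recognizer is pluggable: any callable mapping a token list to BIO tags
can drive :func:`recognize`.  A deterministic gazetteer recognizer is
shipped as the reference implementation; a transformer-based model can be
dropped in behind the same interface.

Preprocessing expands domain acronyms (e.g. "ca." -> "cáncer") before
recognition and keeps an offset map so every recognized span is reported on
the *original* note text.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from ._text import normalize

#: Shipped default acronym dictionary (stand-in, configurable): common
#: Spanish oncology short forms mapped to their full descriptions.
DEFAULT_ACRONYMS: dict[str, str] = {
    "ca.": "cáncer",
    "qt": "quimioterapia",
    "rt": "radioterapia",
    "dx": "diagnóstico",
    "tto": "tratamiento",
    "mtx": "metástasis",
    "iq": "intervención quirúrgica",
}

_SENT_SPLIT = re.compile(r"[.!?\n]+")
_WORD = re.compile(r"\S+")


class RecognizerError(RuntimeError):
    """Raised when the pluggable recognizer fails on a note."""

    def __init__(self, note_id: str, cause: Exception):
        super().__init__(f"recognizer failed on note {note_id!r}: {cause}")
        self.note_id = note_id


@dataclass(frozen=True)
class ClinicalNote:
    note_id: str
    text: str

    def __post_init__(self) -> None:
        if not self.text.strip():
            raise ValueError("ClinicalNote.text must be non-empty")


@dataclass(frozen=True)
class Entity:
    """A recognized mention with its context label and original-text span."""

    surface: str
    label: str
    start: int          # 0-based, half-open, on the original note text
    end: int
    sentence_index: int = 0


@dataclass(frozen=True)
class Token:
    text: str
    start: int  # offsets in the *expanded* text
    end: int


@dataclass
class PreprocessedNote:
    note: ClinicalNote
    expanded_text: str
    sentences: list[list[Token]]
    # segments (exp_start, exp_end, orig_start, orig_end), expansion-ordered
    offset_map: list[tuple[int, int, int, int]] = field(default_factory=list)

    def to_original_span(self, exp_start: int, exp_end: int) -> tuple[int, int]:
        """Map a half-open span in the expanded text back to the original."""

        def map_pos(pos: int, is_end: bool) -> int:
            for es, ee, os_, oe in self.offset_map:
                if es <= pos < ee or (is_end and pos == ee):
                    if ee - es == oe - os_:  # unchanged segment: exact mapping
                        return os_ + (pos - es)
                    # inside a replacement: snap to the replaced span's edges
                    return oe if is_end else os_
            return self.offset_map[-1][3] if self.offset_map else pos

        return map_pos(exp_start, False), map_pos(exp_end, True)


def _acronym_pattern(acronym_dict: dict[str, str]) -> re.Pattern:
    # longest first so "ca." wins over a hypothetical "ca"
    keys = sorted(acronym_dict, key=len, reverse=True)
    parts = [r"(?<!\w)" + re.escape(k) + (r"(?!\w)" if k[-1].isalnum() else "") for k in keys]
    return re.compile("|".join(parts), flags=re.IGNORECASE)


def preprocess(
    note: ClinicalNote, acronym_dict: dict[str, str] | None = None
) -> PreprocessedNote:
    """Expand acronyms, split into sentences and tokenize.

    Every acronym occurrence is replaced by its full description; an offset
    map relates positions in the expanded text to spans of the original, so
    recognized entities can be reported on the untouched note.
    """
    if acronym_dict is None:
        acronym_dict = DEFAULT_ACRONYMS
    text = note.text
    offset_map: list[tuple[int, int, int, int]] = []
    if acronym_dict:
        pattern = _acronym_pattern(acronym_dict)
        lower_map = {normalize(k): v for k, v in acronym_dict.items()}
        out: list[str] = []
        pos = 0
        exp_pos = 0
        for m in pattern.finditer(text):
            if m.start() > pos:
                seg = text[pos:m.start()]
                out.append(seg)
                offset_map.append((exp_pos, exp_pos + len(seg), pos, m.start()))
                exp_pos += len(seg)
            replacement = lower_map[normalize(m.group(0))]
            out.append(replacement)
            offset_map.append((exp_pos, exp_pos + len(replacement), m.start(), m.end()))
            exp_pos += len(replacement)
            pos = m.end()
        tail = text[pos:]
        out.append(tail)
        offset_map.append((exp_pos, exp_pos + len(tail), pos, len(text)))
        expanded = "".join(out)
    else:
        expanded = text
        offset_map.append((0, len(text), 0, len(text)))

    sentences: list[list[Token]] = []
    sent_start = 0
    boundaries = [m.end() for m in _SENT_SPLIT.finditer(expanded)] + [len(expanded)]
    for bound in boundaries:
        chunk = expanded[sent_start:bound]
        tokens = [
            Token(m.group(0), sent_start + m.start(), sent_start + m.end())
            for m in _WORD.finditer(chunk)
        ]
        if tokens:
            sentences.append(tokens)
        sent_start = bound

    return PreprocessedNote(
        note=note, expanded_text=expanded, sentences=sentences, offset_map=offset_map
    )


# ---------------------------------------------------------------------------
# Recognizers
# ---------------------------------------------------------------------------

def gazetteer_recognizer(lexicon: dict[str, str]):
    """Build a BIO recognizer from a surface -> context-label lexicon.

    Matching is case/accent-insensitive, longest-match, left-to-right;
    overlapping matches resolve longest-then-leftmost.  Trailing punctuation
    on tokens is ignored for matching.
    """
    if any(not normalize(k) for k in lexicon):
        raise ValueError("gazetteer surfaces must be non-empty")
    by_tokens: dict[tuple[str, ...], str] = {}
    for surface, label in lexicon.items():
        by_tokens[tuple(normalize(surface).split(" "))] = label
    max_len = max((len(k) for k in by_tokens), default=0)

    def recognizer(tokens: list[str]) -> list[str]:
        norm_toks = [normalize(re.sub(r"[.,;:!?]+$", "", t)) for t in tokens]
        tags = ["O"] * len(tokens)
        i = 0
        while i < len(tokens):
            matched = 0
            label = None
            for n in range(min(max_len, len(tokens) - i), 0, -1):
                cand = tuple(norm_toks[i:i + n])
                if cand in by_tokens:
                    matched, label = n, by_tokens[cand]
                    break
            if matched:
                tags[i] = f"B-{label}"
                for j in range(i + 1, i + matched):
                    tags[j] = f"I-{label}"
                i += matched
            else:
                i += 1
        return tags

    return recognizer


def recognize(
    note: ClinicalNote,
    recognizer,
    acronym_dict: dict[str, str] | None = None,
    label_set: set[str] | None = None,
) -> list[Entity]:
    """Run a BIO recognizer over the preprocessed note and emit entities.

    Contiguous B/I runs of one label are merged into a single entity; spans
    are mapped back to the original text and the surface is the original
    slice (ordered by span start).
    """
    pre = preprocess(note, acronym_dict)
    entities: list[Entity] = []
    for s_idx, tokens in enumerate(pre.sentences):
        try:
            tags = recognizer([t.text for t in tokens])
        except Exception as exc:  # recognizer contract violation
            raise RecognizerError(note.note_id, exc) from exc
        if len(tags) != len(tokens):
            raise RecognizerError(
                note.note_id, ValueError("recognizer returned wrong tag count")
            )
        i = 0
        while i < len(tags):
            if tags[i].startswith("B-"):
                label = tags[i][2:]
                j = i + 1
                while j < len(tags) and tags[j] == f"I-{label}":
                    j += 1
                exp_start, exp_end = tokens[i].start, tokens[j - 1].end
                # drop trailing punctuation from the span
                while exp_end > exp_start and pre.expanded_text[exp_end - 1] in ".,;:!?":
                    exp_end -= 1
                start, end = pre.to_original_span(exp_start, exp_end)
                if label_set is not None and label not in label_set:
                    raise RecognizerError(
                        note.note_id, ValueError(f"label {label!r} outside configured set")
                    )
                entities.append(
                    Entity(
                        surface=note.text[start:end],
                        label=label,
                        start=start,
                        end=end,
                        sentence_index=s_idx,
                    )
                )
                i = j
            else:
                i += 1
    entities.sort(key=lambda e: (e.start, e.end))
    return entities
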