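"""Shared text normalization used for matching across Spanish and English.

All cross-language matching (label equality, BM25 tokens, string similarity)
runs on the *normalized* form; raw surface strings are preserved everywhere
for display and tracing.
"""

from __future__ import annotations

import re
import unicodedata

_WS = re.compile(r"\s+")
_TOKEN = re.compile(r"[a-z0-9ñ]+")


def fold_accents(s: str) -> str:
    """Strip combining marks (NFD decomposition), keeping base characters.

    'ñ' is deliberately preserved: in Spanish it is a distinct letter, not an
    accented 'n', and folding it would conflate e.g. 'año'/'ano'.
    """
    out = []
    for ch in s:
        if ch == "ñ":
            out.append(ch)
            continue
        decomposed = unicodedata.normalize("NFD", ch)
        out.append("".join(c for c in decomposed if not unicodedata.combining(c)))
    return "".join(out)


def normalize(s: str) -> str:
    """NFC unicode, lowercase, accent-folded, whitespace-collapsed form."""
    s = unicodedata.normalize("NFC", s).lower()
    s = fold_accents(s)
    return _WS.sub(" ", s).strip()


def tokenize(s: str) -> list[str]:
    """Alphanumeric tokens of the normalized string."""
    return _TOKEN.findall(normalize(s))
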