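"""Medical entity linking: candidate retrieval, similarity filtering, decision.

For each recognized entity the configured query is run against the BK
index, the top-*k* candidates are annotated with a string similarity to the
mention, and a heuristic decides among three scenarios:

* no candidates at all          -> ``NO_CANDIDATE`` (translate & retry)
* one confident CUI             -> ``DIRECT_LINK``  (no LLM call)
* several CUIs / none confident -> ``AMBIGUOUS``    (LLM disambiguation)

"Confident" means string similarity >= theta_sim (default 0.96) between the
mention and the matched label.  When no candidate is confident the full
retrieved set is passed onward flagged as low-confidence, so the LLM can
still judge it — this is what lets the system recover mentions whose
vocabulary label differs slightly from the note's wording.

Query fuzziness levels (increasingly permissive):

* ``Exact``               — normalized-label equality only.
* ``Basic_Fuzzy``         — per-token edit-distance matching on the label
                            field (budget 1 for tokens of length <= 5, else 2).
* ``Multi_match_SPA``     — fuzzy best-field over label/synonyms/definition,
                            Spanish labels only.
* ``Multi_match``         — same, any language.
* ``Multi_match_boosted`` — Multi_match with cancer-lexicon labels boosted.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass, field, replace
from enum import Enum

import edlib

from ._text import normalize
from .med import select_definition
from .vocab import VocabIndex

#: Default cancer-related boost lexicon for Multi_match_boosted.
DEFAULT_BOOST_WORDS = ("cáncer", "cancer", "carcinoma", "tumor", "neoplasia", "maligno")
DEFAULT_BOOST_FACTOR = 2.0
DEFAULT_K = 15
#: Down-weight applied to the definition field in best-field scoring.
DEFINITION_FIELD_WEIGHT = 0.5


class QType(str, Enum):
    EXACT = "exact"
    BASIC_FUZZY = "basic_fuzzy"
    MULTI_MATCH_SPA = "multi_match_spa"
    MULTI_MATCH = "multi_match"
    MULTI_MATCH_BOOSTED = "multi_match_boosted"


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class Query:
    text: str                       # normalized mention
    q_type: QType
    k: int = DEFAULT_K
    lang: str = "any"               # SPA | ENG | any
    boost_words: tuple[str, ...] = ()
    boost_factor: float = DEFAULT_BOOST_FACTOR

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ConfigurationError("k must be >= 1")
        if self.boost_words and self.q_type is not QType.MULTI_MATCH_BOOSTED:
            raise ConfigurationError("boost_words only apply to Multi_match_boosted")


@dataclass
class Candidate:
    """A retrieved vocabulary term for one mention."""

    cui: str
    matched_label: str
    lang: str
    semantic_type: str
    linking_score: int
    retrieval_score: float
    similarity: float | None = None
    definition: str | None = None
    definition_source: str | None = None
    norm_label: str = ""


class Branch(str, Enum):
    NO_CANDIDATE = "NO_CANDIDATE"
    DIRECT_LINK = "DIRECT_LINK"
    AMBIGUOUS = "AMBIGUOUS"


@dataclass
class Decision:
    branch: Branch
    cui: str | None = None                      # DIRECT_LINK
    candidates: list[Candidate] = field(default_factory=list)  # AMBIGUOUS
    low_confidence: bool = False


def build_query(mention, config, lang_override: str | None = None) -> Query:
    """Build the retrieval query for a mention under a pipeline config.

    ``mention`` may be an Entity or a plain string.  Language constraint:
    SPA for Multi_match_SPA, any for Multi_match / Multi_match_boosted,
    as configured otherwise; ``lang_override`` (used for translation
    retries) wins over everything.
    """
    surface = getattr(mention, "surface", mention)
    q_type = QType(config.q_type) if not isinstance(config.q_type, QType) else config.q_type
    if q_type is QType.MULTI_MATCH_SPA:
        lang = "SPA"
    elif q_type in (QType.MULTI_MATCH, QType.MULTI_MATCH_BOOSTED):
        lang = "any"
    else:
        lang = getattr(config, "lang", "any")
    if lang_override is not None:
        lang = lang_override
    boost_words = ()
    boost_factor = DEFAULT_BOOST_FACTOR
    if q_type is QType.MULTI_MATCH_BOOSTED:
        boost_words = tuple(
            normalize(w) for w in getattr(config, "boost_words", DEFAULT_BOOST_WORDS)
        ) or DEFAULT_BOOST_WORDS
        boost_factor = getattr(config, "boost_factor", DEFAULT_BOOST_FACTOR)
    return Query(
        text=normalize(surface),
        q_type=q_type,
        k=getattr(config, "k", DEFAULT_K),
        lang=lang,
        boost_words=boost_words,
        boost_factor=boost_factor,
    )


# ---------------------------------------------------------------------------
# Retrieval
# ---------------------------------------------------------------------------

def fuzzy_budget(token: str) -> int:
    """Allowed edit distance per query token (1 up to length 5, else 2)."""
    return 1 if len(token) <= 5 else 2


def _fuzzy_expansion(
    query_tokens: list[str], vocabulary, budget=fuzzy_budget
) -> dict[str, set[str]]:
    """Map each query token to the index tokens within its edit budget."""
    expansion: dict[str, set[str]] = {}
    for tok in set(query_tokens):
        k = budget(tok)
        matches = set()
        for vtok in vocabulary:
            if abs(len(vtok) - len(tok)) > k:
                continue
            if vtok == tok or edlib.align(tok, vtok, mode="NW", task="distance", k=k)[
                "editDistance"
            ] != -1:
                matches.add(vtok)
        expansion[tok] = matches
    return expansion


def search(index: VocabIndex, query: Query) -> list[Candidate]:
    """Run the query against the BK index and return ranked candidates.

    Results are sorted by (retrieval score desc, linking score desc, CUI
    asc, label asc) and truncated to ``query.k``; an empty hit set is not an
    error.
    """
    tokens = query.text.split(" ") if query.text else []
    scored: list[tuple[float, Candidate]] = []

    if query.q_type is QType.EXACT:
        for doc in index.docs:
            if doc.norm_label != query.text:
                continue
            if query.lang != "any" and doc.lang != query.lang:
                continue
            score = index.bm25("label", tokens, doc.doc_id)
            scored.append((score, _candidate(index, doc, score)))
    elif query.q_type is QType.BASIC_FUZZY:
        expansion = _fuzzy_expansion(tokens, index.stats["label"].df.keys())
        for doc in index.docs:
            if query.lang != "any" and doc.lang != query.lang:
                continue
            score = index.bm25_fuzzy("label", tokens, doc.doc_id, expansion)
            if score > 0.0:
                scored.append((score, _candidate(index, doc, score)))
    else:  # Multi_match family: fuzzy best-field over label/synonyms/definition
        expansions = {
            f: _fuzzy_expansion(tokens, index.stats[f].df.keys())
            for f in ("label", "synonyms", "definition")
        }
        for doc in index.docs:
            if query.lang != "any" and doc.lang != query.lang:
                continue
            score = max(
                index.bm25_fuzzy("label", tokens, doc.doc_id, expansions["label"]),
                index.bm25_fuzzy("synonyms", tokens, doc.doc_id, expansions["synonyms"]),
                DEFINITION_FIELD_WEIGHT
                * index.bm25_fuzzy("definition", tokens, doc.doc_id, expansions["definition"]),
            )
            if score <= 0.0:
                continue
            if query.q_type is QType.MULTI_MATCH_BOOSTED and query.boost_words:
                label_tokens = set(doc.norm_label.split(" "))
                if label_tokens & set(query.boost_words):
                    score *= query.boost_factor
            scored.append((score, _candidate(index, doc, score)))

    scored.sort(key=lambda sc: (-sc[0], -sc[1].linking_score, sc[1].cui, sc[1].norm_label))
    return [c for _, c in scored[: query.k]]


def _candidate(index: VocabIndex, doc, score: float) -> Candidate:
    entry = index.concepts[doc.cui]
    definition, def_source = select_definition(entry)
    return Candidate(
        cui=doc.cui,
        matched_label=doc.label,
        lang=doc.lang,
        semantic_type=", ".join(entry.semantic_types),
        linking_score=doc.linking_score,
        retrieval_score=score,
        definition=definition,
        definition_source=def_source,
        norm_label=doc.norm_label,
    )


# ---------------------------------------------------------------------------
# Similarity & filtering
# ---------------------------------------------------------------------------

def similarity(a: str, b: str) -> float:
    """Ratcliff–Obershelp matching ratio 2M/(|a|+|b|) on normalized strings.

    M is the total length of the matching blocks of the longest-matching-
    block recursion; the value lies in [0, 1], equals 1 for identical
    strings and 0 when no characters match.
    """
    na, nb = normalize(a), normalize(b)
    if not na and not nb:
        return 1.0
    return difflib.SequenceMatcher(a=na, b=nb, autojunk=False).ratio()


@dataclass
class FilteredCandidates:
    """Similarity-annotated candidates grouped by CUI.

    ``confident`` holds candidates at or above theta_sim; ``pool`` is the
    per-CUI best-label view the decision works on — the confident set when
    non-empty, else the full retrieved set flagged ``low_confidence``.
    """

    mention: str
    theta_sim: float
    all: list[Candidate]
    confident: list[Candidate]
    pool: list[Candidate]
    low_confidence: bool


def _group_by_cui(candidates: list[Candidate]) -> list[Candidate]:
    best: dict[str, Candidate] = {}
    for c in candidates:
        cur = best.get(c.cui)
        key = (-(c.similarity or 0.0), -c.retrieval_score, c.norm_label)
        if cur is None or key < (-(cur.similarity or 0.0), -cur.retrieval_score, cur.norm_label):
            best[c.cui] = c
    return sorted(
        best.values(),
        key=lambda c: (-(c.similarity or 0.0), -c.retrieval_score, -c.linking_score, c.cui),
    )


def filter_candidates(
    candidates: list[Candidate], mention: str, theta_sim: float
) -> FilteredCandidates:
    """Annotate candidates with similarity to the mention and split by theta.

    Candidates with similarity >= theta_sim form the confident set; when it
    is empty the full retrieved set is passed onward flagged low-confidence.
    Grouping by CUI keeps the best label (highest similarity, then retrieval
    score) per concept.
    """
    if not 0.0 <= theta_sim <= 1.0:
        raise ConfigurationError("theta_sim must lie in [0, 1]")
    annotated = [replace(c, similarity=similarity(mention, c.matched_label)) for c in candidates]
    confident = _group_by_cui([c for c in annotated if c.similarity >= theta_sim])
    low_confidence = not confident and bool(annotated)
    pool = confident if confident else _group_by_cui(annotated)
    return FilteredCandidates(
        mention=mention,
        theta_sim=theta_sim,
        all=annotated,
        confident=confident,
        pool=pool,
        low_confidence=low_confidence,
    )


def decide(filtered: FilteredCandidates) -> Decision:
    """Resolve the three linking scenarios.

    No candidates -> NO_CANDIDATE; confident candidates covering exactly one
    CUI -> DIRECT_LINK (no LLM); otherwise AMBIGUOUS with the surviving pool
    (the confident set, or the whole low-confidence set when nothing cleared
    the threshold).
    """
    if not filtered.all:
        return Decision(branch=Branch.NO_CANDIDATE)
    confident_cuis = {c.cui for c in filtered.confident}
    if len(confident_cuis) == 1:
        return Decision(branch=Branch.DIRECT_LINK, cui=next(iter(confident_cuis)),
                        candidates=filtered.confident)
    return Decision(
        branch=Branch.AMBIGUOUS,
        candidates=filtered.pool,
        low_confidence=filtered.low_confidence,
    )
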