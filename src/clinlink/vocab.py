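"""Background knowledge base: vocabulary parsing, concept aggregation, indexing.

The background knowledge (BK) is built from a medical vocabulary — UMLS Rich
Release Format files or an equivalent simple fixture format — and holds, per
concept (CUI), every label with its *linking score* (the number of source
vocabularies that assigned that label), semantic types, and definitions from
all sources.  A BM25 inverted index over (CUI, label) documents with fields
``label`` / ``synonyms`` / ``definition`` supports ranked candidate retrieval.

BM25 variant
------------
Okapi BM25 with a lower-bound term (BM25+ style)::

    idf(t)        = ln(1 + (N - df_t + 0.5) / (df_t + 0.5))
    score(q, d)   = sum over distinct query tokens t present in d of
                    idf(t) * (delta + tf * (k1 + 1) / (tf + k1 * (1 - b + b * dl / avgdl)))

with defaults ``k1 = 1.2``, ``b = 0.75``, ``delta = 1.0``.  Each field
(label, synonyms, definition) is scored as its own collection with its own
document frequencies and average length.  Tokens absent from the document
contribute nothing; duplicate query tokens are deduplicated.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path

from ._text import normalize, tokenize

logger = logging.getLogger(__name__)

INDEX_FORMAT_VERSION = 1

#: Languages recognized in vocabulary sources; anything else maps to "other".
KNOWN_LANGS = ("SPA", "ENG")

# Column offsets in UMLS RRF files (pipe-delimited, no header).
_MRCONSO_CUI, _MRCONSO_LAT, _MRCONSO_SAB, _MRCONSO_TTY, _MRCONSO_STR, _MRCONSO_SUPPRESS = (
    0, 1, 11, 12, 14, 16,
)
_MRCONSO_MIN_COLS = 17
_MRSTY_STY = 3
_MRDEF_SAB, _MRDEF_DEF = 4, 5


class VocabularyError(ValueError):
    """Unusable vocabulary input (empty file, empty concept table, ...)."""


@dataclass(frozen=True)
class Definition:
    text: str
    source: str


@dataclass(frozen=True)
class TermRecord:
    """One vocabulary atom: a (concept, label) assertion from one source."""

    cui: str
    label: str
    lang: str = "SPA"
    source: str = "UNKNOWN"
    tty: str | None = None
    stys: tuple[str, ...] = ()
    definitions: tuple[Definition, ...] = ()

    def __post_init__(self) -> None:
        if not self.cui:
            raise ValueError("TermRecord.cui must be non-empty")
        if not normalize(self.label):
            raise ValueError("TermRecord.label must be non-empty after normalization")
        if self.lang not in KNOWN_LANGS:
            object.__setattr__(self, "lang", "other")


@dataclass(frozen=True)
class LabelEntry:
    """A concept label with its linking score.

    The linking score counts how many source records (i.e. how many
    vocabulary assignments) carry this label, compared after normalization;
    labels with high linking scores are assumed to be the most appropriate
    names for the concept.
    """

    label: str          # display form (lexicographically smallest raw variant)
    norm: str           # normalized form used for matching
    lang: str
    linking_score: int


@dataclass
class ConceptEntry:
    """Everything the BK knows about one CUI."""

    cui: str
    labels: list[LabelEntry]
    semantic_types: list[str]
    definitions: list[Definition]

    @property
    def synonyms(self) -> list[str]:
        return [lab.label for lab in self.labels]


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def _read_rrf_rows(path: str | Path, min_cols: int) -> list[list[str]]:
    rows: list[list[str]] = []
    skipped = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("|")
            if cols and cols[-1] == "":  # trailing pipe
                cols = cols[:-1]
            if len(cols) < min_cols:
                skipped += 1
                logger.warning("%s:%d malformed row (%d columns) skipped", path, lineno, len(cols))
                continue
            rows.append(cols)
    if skipped:
        logger.warning("%s: %d malformed rows skipped", path, skipped)
    return rows


def parse_rrf(
    mrconso_path: str | Path,
    mrsty_path: str | Path | None = None,
    mrdef_path: str | Path | None = None,
    lang_filter: tuple[str, ...] | None = ("SPA", "ENG"),
    keep_suppressed: bool = False,
) -> list[TermRecord]:
    """Parse UMLS RRF files into term records.

    One record per MRCONSO row passing the language filter, joined with the
    semantic types (MRSTY) and definitions (MRDEF) of its CUI.  Suppressed
    atoms (SUPPRESS != 'N') are dropped unless ``keep_suppressed``.
    """
    conso = _read_rrf_rows(mrconso_path, _MRCONSO_MIN_COLS)
    if not conso:
        raise VocabularyError(f"{mrconso_path}: no usable MRCONSO rows")

    stys: dict[str, list[str]] = defaultdict(list)
    if mrsty_path is not None:
        for cols in _read_rrf_rows(mrsty_path, _MRSTY_STY + 1):
            if cols[_MRSTY_STY] not in stys[cols[0]]:
                stys[cols[0]].append(cols[_MRSTY_STY])

    defs: dict[str, list[Definition]] = defaultdict(list)
    if mrdef_path is not None:
        for cols in _read_rrf_rows(mrdef_path, _MRDEF_DEF + 1):
            d = Definition(text=cols[_MRDEF_DEF], source=cols[_MRDEF_SAB])
            if d not in defs[cols[0]]:
                defs[cols[0]].append(d)

    records: list[TermRecord] = []
    for cols in conso:
        cui, lat = cols[_MRCONSO_CUI], cols[_MRCONSO_LAT]
        if lang_filter is not None and lat not in lang_filter:
            continue
        if not keep_suppressed and cols[_MRCONSO_SUPPRESS] != "N":
            continue
        label = cols[_MRCONSO_STR]
        if not normalize(label):
            continue
        records.append(
            TermRecord(
                cui=cui,
                label=label,
                lang=lat,
                source=cols[_MRCONSO_SAB],
                tty=cols[_MRCONSO_TTY] or None,
                stys=tuple(stys.get(cui, ())),
                definitions=tuple(defs.get(cui, ())),
            )
        )
    return records


def load_simple_vocab(path: str | Path) -> list[TermRecord]:
    """Load the JSON-lines fixture vocabulary.

    Each line is an object with fields cui, label, lang, source and optional
    sty, definition, def_source — same semantics as :func:`parse_rrf` output.
    Records missing a mandatory field are rejected with a logged reason.
    """
    records: list[TermRecord] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                logger.warning("%s:%d rejected: invalid JSON (%s)", path, lineno, exc)
                continue
            missing = [k for k in ("cui", "label") if not obj.get(k)]
            if missing:
                logger.warning("%s:%d rejected: missing %s", path, lineno, missing)
                continue
            definitions: tuple[Definition, ...] = ()
            if obj.get("definition"):
                definitions = (Definition(obj["definition"], obj.get("def_source", "UNKNOWN")),)
            records.append(
                TermRecord(
                    cui=obj["cui"],
                    label=obj["label"],
                    lang=obj.get("lang", "SPA"),
                    source=obj.get("source", "UNKNOWN"),
                    tty=obj.get("tty"),
                    stys=(obj["sty"],) if obj.get("sty") else (),
                    definitions=definitions,
                )
            )
    return records


def dump_simple_vocab(records: list[TermRecord], path: str | Path) -> None:
    """Write term records in the JSON-lines fixture format."""
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            obj = {
                "cui": r.cui,
                "label": r.label,
                "lang": r.lang,
                "source": r.source,
            }
            if r.stys:
                obj["sty"] = r.stys[0]
            if r.definitions:
                obj["definition"] = r.definitions[0].text
                obj["def_source"] = r.definitions[0].source
            fh.write(json.dumps(obj, ensure_ascii=False) + "\n")


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def aggregate_concepts(records: list[TermRecord]) -> dict[str, ConceptEntry]:
    """Group term records into one entry per CUI with ranked labels.

    Labels are compared after normalization (lowercase, accent-folded,
    whitespace-collapsed); the linking score of a label is the number of
    input records whose normalized label equals it.  Labels are ranked by
    descending linking score, ties broken lexicographically on the
    normalized form, so re-aggregation of shuffled input is identical.
    """
    by_cui: dict[str, list[TermRecord]] = defaultdict(list)
    for r in records:
        by_cui[r.cui].append(r)

    table: dict[str, ConceptEntry] = {}
    for cui in sorted(by_cui):
        group = by_cui[cui]
        by_norm: dict[str, list[TermRecord]] = defaultdict(list)
        for r in group:
            by_norm[normalize(r.label)].append(r)
        labels = []
        for norm, rs in by_norm.items():
            display = min(r.label for r in rs)
            lang_counts = Counter(r.lang for r in rs)
            best = max(lang_counts.values())
            lang = min(l for l, c in lang_counts.items() if c == best)
            labels.append(LabelEntry(label=display, norm=norm, lang=lang, linking_score=len(rs)))
        labels.sort(key=lambda e: (-e.linking_score, e.norm))
        semantic_types = sorted({sty for r in group for sty in r.stys})
        definitions = sorted(
            {d for r in group for d in r.definitions}, key=lambda d: (d.source, d.text)
        )
        table[cui] = ConceptEntry(
            cui=cui, labels=labels, semantic_types=semantic_types, definitions=definitions
        )
    return table


# ---------------------------------------------------------------------------
# BM25 index
# ---------------------------------------------------------------------------

FIELDS = ("label", "synonyms", "definition")


@dataclass
class IndexDoc:
    """One indexed (CUI, label) pair with its searchable fields."""

    doc_id: int
    cui: str
    label: str
    norm_label: str
    lang: str
    linking_score: int
    tokens: dict[str, list[str]]  # field -> token list


@dataclass
class _FieldStats:
    df: dict[str, int] = field(default_factory=dict)
    doc_tf: list[Counter] = field(default_factory=list)
    doc_len: list[int] = field(default_factory=list)
    avgdl: float = 0.0


class VocabIndex:
    """In-process BM25 index over the concept table.

    One document per retained (CUI, label) pair; fields ``label`` (the
    label's own tokens), ``synonyms`` (tokens of the concept's other
    labels), and ``definition`` (tokens of all the concept's definitions).
    """

    def __init__(
        self,
        concept_table: dict[str, ConceptEntry],
        k1: float = 1.2,
        b: float = 0.75,
        delta: float = 1.0,
    ) -> None:
        if not concept_table:
            raise VocabularyError("cannot index an empty concept table")
        self.k1, self.b, self.delta = k1, b, delta
        self.concepts = concept_table
        self.docs: list[IndexDoc] = []
        self.label_to_cuis: dict[str, set[str]] = defaultdict(set)

        for cui in sorted(concept_table):
            entry = concept_table[cui]
            def_tokens = [t for d in entry.definitions for t in tokenize(d.text)]
            norm_all = [lab.norm for lab in entry.labels]
            for lab in entry.labels:
                syn_tokens = [
                    t for other in norm_all if other != lab.norm for t in other.split(" ")
                ]
                self.docs.append(
                    IndexDoc(
                        doc_id=len(self.docs),
                        cui=cui,
                        label=lab.label,
                        norm_label=lab.norm,
                        lang=lab.lang,
                        linking_score=lab.linking_score,
                        tokens={
                            "label": lab.norm.split(" "),
                            "synonyms": syn_tokens,
                            "definition": def_tokens,
                        },
                    )
                )
                self.label_to_cuis[lab.norm].add(cui)

        self.n_docs = len(self.docs)
        self.stats: dict[str, _FieldStats] = {}
        for f in FIELDS:
            st = _FieldStats()
            for doc in self.docs:
                tf = Counter(doc.tokens[f])
                st.doc_tf.append(tf)
                st.doc_len.append(sum(tf.values()))
                for tok in tf:
                    st.df[tok] = st.df.get(tok, 0) + 1
            st.avgdl = (sum(st.doc_len) / self.n_docs) if self.n_docs else 0.0
            self.stats[f] = st

    # -- scoring ------------------------------------------------------------

    def idf(self, field_name: str, token: str) -> float:
        df = self.stats[field_name].df.get(token, 0)
        return math.log(1.0 + (self.n_docs - df + 0.5) / (df + 0.5))

    def bm25(self, field_name: str, query_tokens: list[str], doc_id: int) -> float:
        """BM25+ score of a document field for (deduplicated) query tokens."""
        st = self.stats[field_name]
        tf_map = st.doc_tf[doc_id]
        dl = st.doc_len[doc_id]
        if dl == 0 or st.avgdl == 0:
            return 0.0
        score = 0.0
        for tok in sorted(set(query_tokens)):
            tf = tf_map.get(tok, 0)
            if tf == 0:
                continue
            denom = tf + self.k1 * (1.0 - self.b + self.b * dl / st.avgdl)
            score += self.idf(field_name, tok) * (self.delta + tf * (self.k1 + 1.0) / denom)
        return score

    def bm25_fuzzy(
        self, field_name: str, query_tokens: list[str], doc_id: int,
        match_map: dict[str, set[str]],
    ) -> float:
        """BM25+ where each query token stands for a set of index tokens.

        ``match_map`` maps a query token to the index-vocabulary tokens it is
        allowed to match (its fuzzy expansion); the term frequency is the sum
        over matched tokens and the IDF is taken from the best (rarest)
        matched token, mirroring how search engines score fuzzy-expanded
        terms.
        """
        st = self.stats[field_name]
        tf_map = st.doc_tf[doc_id]
        dl = st.doc_len[doc_id]
        if dl == 0 or st.avgdl == 0:
            return 0.0
        score = 0.0
        for tok in sorted(set(query_tokens)):
            matched = match_map.get(tok, set())
            tf = sum(tf_map.get(m, 0) for m in matched)
            if tf == 0:
                continue
            idf = max(self.idf(field_name, m) for m in matched if tf_map.get(m, 0))
            denom = tf + self.k1 * (1.0 - self.b + self.b * dl / st.avgdl)
            score += idf * (self.delta + tf * (self.k1 + 1.0) / denom)
        return score

    # -- persistence --------------------------------------------------------

    def _payload(self) -> dict:
        return {
            "concepts": [
                {
                    "cui": e.cui,
                    "labels": [
                        [lab.label, lab.norm, lab.lang, lab.linking_score] for lab in e.labels
                    ],
                    "semantic_types": e.semantic_types,
                    "definitions": [[d.text, d.source] for d in e.definitions],
                }
                for _, e in sorted(self.concepts.items())
            ],
        }

    def build_hash(self) -> str:
        blob = json.dumps(self._payload(), sort_keys=True, ensure_ascii=False)
        return hashlib.sha256(blob.encode("utf-8")).hexdigest()[:16]

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest = {
            "format_version": INDEX_FORMAT_VERSION,
            "bm25": {"k1": self.k1, "b": self.b, "delta": self.delta},
            "n_docs": self.n_docs,
            "build_hash": self.build_hash(),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2), encoding="utf-8")
        (out / "concepts.json").write_text(
            json.dumps(self._payload(), ensure_ascii=False), encoding="utf-8"
        )

    @classmethod
    def load(cls, in_dir: str | Path) -> "VocabIndex":
        in_dir = Path(in_dir)
        manifest = json.loads((in_dir / "manifest.json").read_text(encoding="utf-8"))
        if manifest.get("format_version") != INDEX_FORMAT_VERSION:
            raise VocabularyError(
                f"index format version {manifest.get('format_version')} not supported"
            )
        payload = json.loads((in_dir / "concepts.json").read_text(encoding="utf-8"))
        table: dict[str, ConceptEntry] = {}
        for c in payload["concepts"]:
            table[c["cui"]] = ConceptEntry(
                cui=c["cui"],
                labels=[
                    LabelEntry(label=l, norm=n, lang=g, linking_score=s)
                    for l, n, g, s in c["labels"]
                ],
                semantic_types=list(c["semantic_types"]),
                definitions=[Definition(t, s) for t, s in c["definitions"]],
            )
        bm = manifest["bm25"]
        idx = cls(table, k1=bm["k1"], b=bm["b"], delta=bm["delta"])
        if idx.build_hash() != manifest["build_hash"]:
            raise VocabularyError("index build hash mismatch on load")
        return idx


def build_index(
    concept_table: dict[str, ConceptEntry],
    k1: float = 1.2,
    b: float = 0.75,
    delta: float = 1.0,
) -> VocabIndex:
    """Build the searchable BK index from an aggregated concept table."""
    return VocabIndex(concept_table, k1=k1, b=b, delta=delta)
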