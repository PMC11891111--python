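"""Independent reference implementations used as test oracles.

These deliberately share no code with the package: similarity via the
classic quadratic Ratcliff–Obershelp recursion, edit distance via the full
Levenshtein DP, and retrieval via exhaustive scoring of every document with
the documented BM25+ formula.
"""

from __future__ import annotations

import math
from collections import Counter

from clinlink._text import normalize


# ---------------------------------------------------------------------------
# Ratcliff–Obershelp
# ---------------------------------------------------------------------------

def _longest_match(a: str, b: str) -> tuple[int, int, int]:
    """Longest common substring (earliest in a, then in b) by brute force."""
    best = (0, 0, 0)  # (length, i, j)
    for i in range(len(a)):
        for j in range(len(b)):
            k = 0
            while i + k < len(a) and j + k < len(b) and a[i + k] == b[j + k]:
                k += 1
            if k > best[0]:
                best = (k, i, j)
    return best


def _matching_chars(a: str, b: str) -> int:
    k, i, j = _longest_match(a, b)
    if k == 0:
        return 0
    return k + _matching_chars(a[:i], b[:j]) + _matching_chars(a[i + k:], b[j + k:])


def ratcliff_obershelp(a: str, b: str) -> float:
    """2M/(|a|+|b|) on normalized strings, by direct recursion."""
    na, nb = normalize(a), normalize(b)
    if not na and not nb:
        return 1.0
    return 2.0 * _matching_chars(na, nb) / (len(na) + len(nb))


# ---------------------------------------------------------------------------
# Levenshtein
# ---------------------------------------------------------------------------

def levenshtein(a: str, b: str) -> int:
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        for j, cb in enumerate(b, start=1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


# ---------------------------------------------------------------------------
# Exhaustive retrieval oracle
# ---------------------------------------------------------------------------

def _budget(token: str) -> int:
    return 1 if len(token) <= 5 else 2


def _bm25_plus(query_tokens, docs_tokens, doc_id, expansion, k1, b, delta):
    """BM25+ with fuzzy expansion, statistics recomputed from scratch."""
    n = len(docs_tokens)
    tfs = [Counter(toks) for toks in docs_tokens]
    df: Counter = Counter()
    for tf in tfs:
        df.update(tf.keys())
    lengths = [sum(tf.values()) for tf in tfs]
    avgdl = sum(lengths) / n if n else 0.0
    dl = lengths[doc_id]
    if dl == 0 or avgdl == 0:
        return 0.0

    def idf(tok):
        return math.log(1.0 + (n - df[tok] + 0.5) / (df[tok] + 0.5))

    score = 0.0
    for tok in sorted(set(query_tokens)):
        matched = expansion.get(tok, {tok})
        tf = sum(tfs[doc_id].get(m, 0) for m in matched)
        if tf == 0:
            continue
        best_idf = max(idf(m) for m in matched if tfs[doc_id].get(m, 0))
        denom = tf + k1 * (1.0 - b + b * dl / avgdl)
        score += best_idf * (delta + tf * (k1 + 1.0) / denom)
    return score


def exhaustive_search(index, query):
    """Score every document with the documented rules; return ranked CUI/
    label/score triples truncated to k.  Mirrors the retrieval contract,
    implemented from scratch."""
    tokens = query.text.split(" ") if query.text else []
    q_type = query.q_type.value

    def expansion_for(field):
        vocab = set()
        for doc in index.docs:
            vocab.update(doc.tokens[field])
        exp = {}
        for tok in set(tokens):
            k = _budget(tok)
            exp[tok] = {v for v in vocab if levenshtein(tok, v) <= k}
        return exp

    field_docs = {
        f: [doc.tokens[f] for doc in index.docs] for f in ("label", "synonyms", "definition")
    }
    results = []
    exp_label = expansion_for("label")
    exp_syn = expansion_for("synonyms")
    exp_def = expansion_for("definition")
    for doc in index.docs:
        if query.lang != "any" and doc.lang != query.lang:
            continue
        if q_type == "exact":
            if doc.norm_label != query.text:
                continue
            exp_id = {t: {t} for t in tokens}
            score = _bm25_plus(tokens, field_docs["label"], doc.doc_id, exp_id,
                               index.k1, index.b, index.delta)
        elif q_type == "basic_fuzzy":
            score = _bm25_plus(tokens, field_docs["label"], doc.doc_id, exp_label,
                               index.k1, index.b, index.delta)
            if score <= 0.0:
                continue
        else:
            score = max(
                _bm25_plus(tokens, field_docs["label"], doc.doc_id, exp_label,
                           index.k1, index.b, index.delta),
                _bm25_plus(tokens, field_docs["synonyms"], doc.doc_id, exp_syn,
                           index.k1, index.b, index.delta),
                0.5 * _bm25_plus(tokens, field_docs["definition"], doc.doc_id, exp_def,
                                 index.k1, index.b, index.delta),
            )
            if score <= 0.0:
                continue
            if q_type == "multi_match_boosted" and query.boost_words:
                if set(doc.norm_label.split(" ")) & set(query.boost_words):
                    score *= query.boost_factor
        results.append((score, doc))
    results.sort(key=lambda sd: (-sd[0], -sd[1].linking_score, sd[1].cui, sd[1].norm_label))
    return [(d.cui, d.norm_label, s) for s, d in results[: query.k]]
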