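"""Candidate retrieval, similarity filtering and the three-way decision."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clinlink import (
    Branch,
    PipelineConfig,
    QType,
    aggregate_concepts,
    build_index,
    build_query,
    decide,
    filter_candidates,
    search,
    similarity,
)
from clinlink.mel import ConfigurationError
from clinlink.vocab import TermRecord

from helpers import exhaustive_search, ratcliff_obershelp


@pytest.fixture(scope="module")
def tiny_index():
    records = [
        TermRecord(cui="C0007097", label="carcinoma", lang="ENG", source="NCI"),
        TermRecord(cui="C0007097", label="carcinoma", lang="SPA", source="SNOMEDCT"),
        TermRecord(cui="C0006141", label="mama derecha", lang="SPA", source="SNOMEDCT"),
        TermRecord(cui="C0006141", label="right breast", lang="ENG", source="NCI"),
        TermRecord(cui="C1", label="boost", lang="ENG", source="NCI"),
        TermRecord(cui="C2", label="boost", lang="ENG", source="MSH"),
    ]
    return build_index(aggregate_concepts(records))


class TestBuildQuery:
    def test_exact_query_language_defaults(self):
        q = build_query("carcinoma", PipelineConfig(q_type=QType.EXACT))
        assert q.text == "carcinoma" and q.lang == "any" and not q.boost_words

    def test_spa_variant_pins_language(self):
        q = build_query("carcinoma", PipelineConfig(q_type=QType.MULTI_MATCH_SPA))
        assert q.lang == "SPA"

    def test_boosted_carries_boost_settings(self):
        cfg = PipelineConfig(q_type=QType.MULTI_MATCH_BOOSTED,
                             boost_words=("cáncer", "carcinoma"))
        q = build_query("carcinoma de mama", cfg)
        assert "carcinoma" in q.boost_words and q.boost_factor == 2.0

    def test_unknown_q_type_is_configuration_error(self):
        with pytest.raises((ValueError, ConfigurationError)):
            PipelineConfig(q_type="semantic_match")


class TestSearch:
    def test_exact_self_retrieval(self, tiny_index):
        hits = search(tiny_index, build_query("carcinoma", PipelineConfig(q_type=QType.EXACT)))
        assert hits[0].cui == "C0007097" and hits[0].matched_label == "carcinoma"

    def test_exact_excludes_near_misses(self, tiny_index):
        hits = search(tiny_index, build_query("carcinom", PipelineConfig(q_type=QType.EXACT)))
        assert hits == []

    def test_basic_fuzzy_tolerates_one_typo(self, tiny_index):
        q = build_query("mama derechas", PipelineConfig(q_type=QType.BASIC_FUZZY))
        assert any(c.cui == "C0006141" for c in search(tiny_index, q))

    def test_boosted_label_scores_higher(self, tiny_index):
        cfg = PipelineConfig(q_type=QType.MULTI_MATCH_BOOSTED)
        boosted = search(tiny_index, build_query("carcinoma", cfg))
        plain = search(tiny_index, build_query("carcinoma", PipelineConfig(q_type=QType.MULTI_MATCH)))
        b = {c.cui: c.retrieval_score for c in boosted}
        p = {c.cui: c.retrieval_score for c in plain}
        assert b["C0007097"] == pytest.approx(2.0 * p["C0007097"])

    @pytest.mark.parametrize("q_type", list(QType))
    def test_rankings_equal_exhaustive_oracle(self, synth_world, q_type):
        _, vocab, _, index = synth_world
        assert index.n_docs <= 100
        rng = random.Random(21)
        surfaces = sorted(vocab.truth)
        cfg = PipelineConfig(q_type=q_type)
        for _ in range(10):
            q = build_query(rng.choice(surfaces), cfg)
            got = [(c.cui, c.norm_label) for c in search(index, q)]
            want = [(cui, lab) for cui, lab, _ in exhaustive_search(index, q)]
            assert got == want

    def test_recall_monotonicity_across_fuzziness(self, synth_world):
        _, vocab, _, index = synth_world
        rng = random.Random(6)
        surfaces = sorted(vocab.truth)
        big_k = index.n_docs + 1
        for _ in range(20):
            text = rng.choice(surfaces)

            def hits(q_type):
                q = build_query(text, PipelineConfig(q_type=q_type, k=big_k))
                return {c.cui for c in search(index, q)}

            assert hits(QType.EXACT) <= hits(QType.BASIC_FUZZY) <= hits(QType.MULTI_MATCH)
            assert hits(QType.MULTI_MATCH_SPA) <= hits(QType.MULTI_MATCH)

    def test_hit_count_non_decreasing_in_k(self, synth_world):
        _, vocab, _, index = synth_world
        text = sorted(vocab.truth)[0]
        sizes = [
            len(search(index, build_query(text, PipelineConfig(q_type=QType.MULTI_MATCH, k=k))))
            for k in (1, 3, 10, 50)
        ]
        assert sizes == sorted(sizes)


class TestSimilarity:
    @pytest.mark.parametrize(
        ("a", "b", "expected"),
        [
            ("mama derecha", "mama derecha", 1.0),
            ("abc", "xyz", 0.0),
            ("mama derecha", "mama parte derecha", 0.8),
        ],
    )
    def test_known_values(self, a, b, expected):
        assert similarity(a, b) == pytest.approx(expected)

    @given(st.text(max_size=25), st.text(max_size=25))
    @settings(max_examples=200, derandomize=True)
    def test_bounds_and_identity(self, a, b):
        s = similarity(a, b)
        assert 0.0 <= s <= 1.0
        assert similarity(a, a) == 1.0

    def test_equals_reference_recursion_on_random_pairs(self):
        rng = random.Random(3)
        words = ["mama", "derecha", "parte", "cáncer", "tumor", "piel", "izq"]
        for _ in range(200):
            a = " ".join(rng.choices(words, k=rng.randint(1, 4)))
            b = " ".join(rng.choices(words, k=rng.randint(1, 4)))
            assert similarity(a, b) == pytest.approx(ratcliff_obershelp(a, b))


class TestFilterAndDecide:
    def _candidates(self, index, mention, q_type=QType.MULTI_MATCH):
        return search(index, build_query(mention, PipelineConfig(q_type=q_type)))

    def test_theta_zero_everything_confident(self, tiny_index):
        cands = self._candidates(tiny_index, "carcinoma")
        f = filter_candidates(cands, "carcinoma", 0.0)
        assert {c.cui for c in f.confident} == {c.cui for c in cands}

    def test_theta_one_exact_only(self, tiny_index):
        cands = self._candidates(tiny_index, "mama derecha")
        f = filter_candidates(cands, "mama derecha", 1.0)
        assert all(c.similarity == 1.0 for c in f.confident)
        assert {c.cui for c in f.confident} == {"C0006141"}

    def test_survivors_match_direct_recomputation(self, synth_world):
        _, vocab, _, index = synth_world
        mention = sorted(vocab.truth)[5]
        cands = self._candidates(index, mention)
        f = filter_candidates(cands, mention, 0.96)
        expected = {c.cui for c in cands if ratcliff_obershelp(mention, c.matched_label) >= 0.96}
        assert {c.cui for c in f.confident} == expected

    def test_survivors_non_increasing_in_theta(self, tiny_index):
        cands = self._candidates(tiny_index, "mama derecha")
        sizes = [
            len(filter_candidates(cands, "mama derecha", t).confident)
            for t in (0.0, 0.5, 0.9, 1.0)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_theta_out_of_range_rejected(self, tiny_index):
        with pytest.raises(ConfigurationError):
            filter_candidates([], "x", 1.5)

    def test_no_candidates_branch(self):
        f = filter_candidates([], "mama", 0.96)
        assert decide(f).branch is Branch.NO_CANDIDATE

    def test_single_confident_cui_is_direct_link(self, tiny_index):
        cands = self._candidates(tiny_index, "mama derecha")
        d = decide(filter_candidates(cands, "mama derecha", 0.96))
        assert d.branch is Branch.DIRECT_LINK and d.cui == "C0006141"

    def test_homonym_two_cuis_is_ambiguous(self, tiny_index):
        cands = self._candidates(tiny_index, "boost", q_type=QType.EXACT)
        d = decide(filter_candidates(cands, "boost", 0.96))
        assert d.branch is Branch.AMBIGUOUS
        assert {c.cui for c in d.candidates} == {"C1", "C2"}

    def test_all_below_threshold_goes_to_llm_flagged(self, tiny_index):
        # no candidate reaches theta: the full set passes on, low-confidence
        cands = self._candidates(tiny_index, "mama parte derecha")
        f = filter_candidates(cands, "mama parte derecha", 0.96)
        assert not f.confident and f.low_confidence
        d = decide(f)
        assert d.branch is Branch.AMBIGUOUS and d.low_confidence
        assert len(d.candidates) >= 1
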