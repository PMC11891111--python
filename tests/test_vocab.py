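"""Background-knowledge construction: parsing, aggregation, BM25 indexing."""

import random
from collections import Counter, defaultdict

import pytest

from clinlink import aggregate_concepts, build_index, load_simple_vocab, parse_rrf
from clinlink._text import normalize
from clinlink.vocab import TermRecord, VocabularyError

from helpers import _bm25_plus


def _write_rrf(path, rows, n_cols):
    with open(path, "w", encoding="utf-8") as fh:
        for row in rows:
            cols = [""] * n_cols
            for i, v in row.items():
                cols[i] = v
            fh.write("|".join(cols) + "|\n")


def _conso_row(cui, lat, sab, string, suppress="N"):
    return {0: cui, 1: lat, 11: sab, 12: "PT", 14: string, 16: suppress}


class TestParseRRF:
    def test_suppressed_rows_dropped(self, tmp_path):
        p = tmp_path / "MRCONSO.RRF"
        _write_rrf(p, [
            _conso_row("C0007097", "ENG", "NCI", "carcinoma"),
            _conso_row("C0007097", "SPA", "SNOMEDCT", "carcinoma"),
            _conso_row("C0007097", "ENG", "MSH", "old term", suppress="O"),
        ], 18)
        records = parse_rrf(p)
        assert len(records) == 2
        assert all(r.cui == "C0007097" and r.label == "carcinoma" for r in records)

    def test_carcinoma_concept_row(self, tmp_path):
        p = tmp_path / "MRCONSO.RRF"
        _write_rrf(p, [_conso_row("C0007097", "ENG", "NCI", "carcinoma")], 18)
        (rec,) = parse_rrf(p)
        assert (rec.cui, rec.label, rec.lang, rec.source) == (
            "C0007097", "carcinoma", "ENG", "NCI"
        )

    def test_join_matches_bruteforce_oracle(self, tmp_path):
        rng = random.Random(5)
        cuis = [f"C{1000 + i}" for i in range(20)]
        conso = [
            _conso_row(rng.choice(cuis), rng.choice(["SPA", "ENG"]),
                       rng.choice(["NCI", "MSH"]), f"label {i}")
            for i in range(100)
        ]
        sty_rows = [{0: c, 3: f"Type {i % 3}"} for i, c in enumerate(cuis) if i % 2 == 0]
        def_rows = [{0: c, 4: "NCI", 5: f"def of {c}"} for c in cuis if rng.random() < 0.5]
        _write_rrf(tmp_path / "MRCONSO.RRF", conso, 18)
        _write_rrf(tmp_path / "MRSTY.RRF", sty_rows, 6)
        _write_rrf(tmp_path / "MRDEF.RRF", def_rows, 8)

        records = parse_rrf(tmp_path / "MRCONSO.RRF", tmp_path / "MRSTY.RRF",
                            tmp_path / "MRDEF.RRF")
        # independent join oracle over the raw row dicts
        stys = defaultdict(list)
        for r in sty_rows:
            stys[r[0]].append(r[3])
        defs = defaultdict(list)
        for r in def_rows:
            defs[r[0]].append((r[5], r[4]))
        assert len(records) == len(conso)
        for rec, row in zip(records, conso):
            assert rec.cui == row[0] and rec.label == row[14]
            assert list(rec.stys) == stys.get(rec.cui, [])
            assert [(d.text, d.source) for d in rec.definitions] == defs.get(rec.cui, [])

    def test_malformed_row_skipped_and_empty_file_errors(self, tmp_path):
        p = tmp_path / "MRCONSO.RRF"
        with open(p, "w") as fh:
            fh.write("C1|ENG|bad row\n")
            fh.write("|".join(_row_cols(_conso_row("C2", "ENG", "NCI", "kept"))) + "|\n")
        assert [r.cui for r in parse_rrf(p)] == ["C2"]
        empty = tmp_path / "empty.RRF"
        empty.write_text("")
        with pytest.raises(VocabularyError):
            parse_rrf(empty)


def _row_cols(row, n_cols=18):
    cols = [""] * n_cols
    for i, v in row.items():
        cols[i] = v
    return cols


class TestSimpleVocab:
    def test_identity_read(self, tmp_path):
        p = tmp_path / "vocab.jsonl"
        p.write_text(
            '{"cui": "C0006142", "label": "cáncer de mama", "lang": "SPA", '
            '"source": "SNOMEDCT", "sty": "Neoplastic Process", '
            '"definition": "d", "def_source": "NCI"}\n'
        )
        (rec,) = load_simple_vocab(p)
        assert rec.cui == "C0006142"
        assert rec.label == "cáncer de mama"
        assert rec.lang == "SPA"
        assert rec.stys == ("Neoplastic Process",)
        assert rec.definitions[0].source == "NCI"

    def test_empty_file_is_empty_list(self, tmp_path):
        p = tmp_path / "vocab.jsonl"
        p.write_text("")
        assert load_simple_vocab(p) == []

    def test_missing_mandatory_field_rejected(self, tmp_path):
        p = tmp_path / "vocab.jsonl"
        p.write_text('{"label": "orphan"}\n{"cui": "C1", "label": "ok"}\n')
        assert [r.cui for r in load_simple_vocab(p)] == ["C1"]


class TestAggregation:
    def test_linking_scores_match_bruteforce_count(self):
        rng = random.Random(9)
        labels = ["carcinoma", "Carcinoma", "tumor maligno", "breast  cancer"]
        records = [
            TermRecord(cui=f"C{rng.randint(1, 3)}", label=rng.choice(labels),
                       lang="ENG", source=f"S{i}")
            for i in range(60)
        ]
        table = aggregate_concepts(records)
        expected = Counter((r.cui, normalize(r.label)) for r in records)
        for cui, entry in table.items():
            for lab in entry.labels:
                assert lab.linking_score == expected[(cui, lab.norm)]
            # conservation: scores within a CUI sum to the record count
            assert sum(l.linking_score for l in entry.labels) == sum(
                1 for r in records if r.cui == cui
            )
            # ranking is by descending score with deterministic tie-break
            scores = [l.linking_score for l in entry.labels]
            assert scores == sorted(scores, reverse=True)

    def test_shuffled_input_aggregates_identically(self):
        rng = random.Random(2)
        records = [
            TermRecord(cui=f"C{i % 5}", label=f"label {i % 7}", lang="ENG", source=f"S{i}")
            for i in range(40)
        ]
        shuffled = records[:]
        rng.shuffle(shuffled)
        assert aggregate_concepts(records) == aggregate_concepts(shuffled)

    def test_single_record(self):
        table = aggregate_concepts([TermRecord(cui="C1", label="solo", source="A")])
        assert table["C1"].labels[0].linking_score == 1

    def test_homonym_label_kept_in_both_concepts(self):
        # one surface, two CUIs: both concepts keep it, no cross-CUI merging
        records = [
            TermRecord(cui="C1", label="boost", lang="ENG", source="A"),
            TermRecord(cui="C2", label="boost", lang="ENG", source="B"),
        ]
        table = aggregate_concepts(records)
        assert table["C1"].labels[0].norm == "boost"
        assert table["C2"].labels[0].norm == "boost"


class TestIndex:
    def test_self_retrieval_single_concept(self):
        from clinlink import PipelineConfig, QType, build_query, search

        table = aggregate_concepts([TermRecord(cui="C1", label="mama derecha", lang="SPA")])
        index = build_index(table)
        assert index.n_docs >= 1
        hits = search(index, build_query("mama derecha", PipelineConfig(q_type=QType.EXACT)))
        assert hits[0].cui == "C1"

    def test_empty_table_errors(self):
        with pytest.raises(VocabularyError):
            build_index({})

    def test_document_count_equals_retained_pairs(self, synth_world):
        _, vocab, _, index = synth_world
        n_pairs = sum(len(e.labels) for e in index.concepts.values())
        assert index.n_docs == n_pairs
        assert all(doc.cui in index.concepts for doc in index.docs)

    def test_bm25_matches_closed_form(self, synth_world):
        # field score of any (query, doc) equals the formula evaluated from scratch
        _, vocab, _, index = synth_world
        rng = random.Random(4)
        docs_tokens = [doc.tokens["label"] for doc in index.docs]
        for _ in range(25):
            doc = rng.choice(index.docs)
            query = rng.sample(doc.tokens["label"], k=min(2, len(doc.tokens["label"])))
            query += ["unseen_token"]
            expected = _bm25_plus(
                query, docs_tokens, doc.doc_id, {t: {t} for t in query},
                index.k1, index.b, index.delta,
            )
            assert index.bm25("label", query, doc.doc_id) == pytest.approx(expected)

    def test_serialization_roundtrip_scores(self, synth_world, tmp_path):
        from clinlink import PipelineConfig, QType, build_query, search
        from clinlink.vocab import VocabIndex

        _, vocab, corpus, index = synth_world
        index.save(tmp_path / "bk")
        reloaded = VocabIndex.load(tmp_path / "bk")
        assert reloaded.build_hash() == index.build_hash()
        rng = random.Random(8)
        surfaces = sorted(vocab.truth)
        config = PipelineConfig(q_type=QType.MULTI_MATCH)
        for _ in range(20):
            q = build_query(rng.choice(surfaces), config)
            a = [(c.cui, c.retrieval_score) for c in search(index, q)]
            b = [(c.cui, c.retrieval_score) for c in search(reloaded, q)]
            assert a == b
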