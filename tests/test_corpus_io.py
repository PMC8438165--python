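"""Corpus dialect round-trips, inventory validation, and pre-processing."""

import json
from collections import Counter

import pytest

from epenthesis_lab.corpus import (
    Corpus,
    CorpusFormatError,
    Phrase,
    WordToken,
    apply_deletion,
    collapse_palatalization,
    corpus_from_streams,
    phone_streams,
    read_corpus,
    read_inventory,
    write_corpus,
)
from epenthesis_lab.phones import default_inventory, parse_label


def _corpus(*phrase_specs):
    return corpus_from_streams(
        (f"p{i}", [("w", "Noun", list(phones))])
        for i, phones in enumerate(phrase_specs)
    )


class TestRoundTrip:
    def test_read_then_write_is_byte_identical(self, toy_corpus, tmp_path):
        f1 = tmp_path / "a.jsonl"
        f2 = tmp_path / "b.jsonl"
        write_corpus(toy_corpus, f1)
        write_corpus(read_corpus(f1), f2)
        assert f1.read_bytes() == f2.read_bytes()

    def test_write_then_read_preserves_structure(self, toy_corpus, tmp_path):
        f = tmp_path / "c.jsonl"
        write_corpus(toy_corpus, f)
        back = read_corpus(f)
        assert back.phrases == toy_corpus.phrases

    def test_single_phrase_identity(self, tmp_path):
        f = tmp_path / "one.jsonl"
        f.write_text(
            json.dumps({"phrase_id": "p0",
                        "words": [{"orth_id": "w", "pos": "Noun",
                                   "phones": ["k", "a", "t"]}]}) + "\n"
        )
        c = read_corpus(f)
        assert len(c) == 1
        assert len(c.phrases[0].words) == 1
        assert c.phrases[0].words[0].phones == ("k", "a", "t")


class TestValidation:
    def test_unknown_label_names_label_and_line(self, tmp_path):
        f = tmp_path / "bad.jsonl"
        f.write_text(
            json.dumps({"phrase_id": "p0",
                        "words": [{"orth_id": "w", "pos": "N",
                                   "phones": ["k", "qq"]}]}) + "\n"
        )
        with pytest.raises(CorpusFormatError, match=r"line 1.*'qq'"):
            read_corpus(f)

    def test_missing_field_names_line(self, tmp_path):
        f = tmp_path / "bad.jsonl"
        f.write_text('{"phrase_id": "p0"}\n')
        with pytest.raises(CorpusFormatError, match="line 1"):
            read_corpus(f)

    def test_vowel_with_palatalized_flag_rejected(self, tmp_path):
        f = tmp_path / "inv.json"
        f.write_text(json.dumps({
            "a": {"kind": "vowel", "quality": "a", "voicing": "voiced",
                  "length": "short", "palatalized": True},
        }))
        with pytest.raises(CorpusFormatError, match="'a'"):
            read_inventory(f)

    def test_inventory_round_trip(self, tmp_path):
        from epenthesis_lab.corpus import write_inventory

        f = tmp_path / "inv.json"
        inv = default_inventory()
        write_inventory(inv, f)
        assert read_inventory(f) == inv

    def test_boundary_inside_phrase_rejected(self):
        with pytest.raises(CorpusFormatError, match="boundary"):
            _corpus(["k", "#", "a"])


class TestCollapsePalatalization:
    def test_phonetic_variants_merge_onto_phonological_label(self):
        c = _corpus(["sh~", "i"], ["sh", "a"])
        merged = collapse_palatalization(c)
        assert merged.phrases[0].words[0].phones == ("sh", "i")
        assert merged.phrases[1].words[0].phones == ("sh", "a")
        assert "sh~" not in merged.inventory

    def test_no_phonetic_phones_is_identity(self, toy_corpus):
        c = _corpus(["k", "a"])
        assert collapse_palatalization(c).phrases == c.phrases

    def test_merged_frequency_is_sum_of_variants(self):
        # 10 phrases: 6 with the phonetic variant, 4 with the phonological one
        phrases = [["sh~", "i", "t", "a"]] * 6 + [["sh", "a", "t", "a"]] * 4
        c = _corpus(*phrases)
        before = Counter(c.iter_phones())
        assert before["sh~"] == 6 and before["sh"] == 4
        after = Counter(collapse_palatalization(c).iter_phones())
        assert after["sh"] == 10
        assert sum(after.values()) == sum(before.values())  # count conserved

    def test_missing_counterpart_is_an_error(self):
        c = _corpus(["sh~", "i"])
        del c.inventory["sh"]
        with pytest.raises(ValueError, match="counterpart"):
            collapse_palatalization(c)


class TestApplyDeletion:
    def test_rate_zero_is_identity(self):
        c = _corpus(["s", "u0", "t", "a"])
        assert apply_deletion(c, 0.0, seed=1).phrases == c.phrases

    def test_rate_one_removes_all_devoiced(self):
        c = _corpus(["s", "u0", "t", "i0", "k", "a"])
        out = apply_deletion(c, 1.0, seed=1)
        inv = out.inventory
        assert not any(inv[lab].is_devoiced_vowel for lab in out.iter_phones())
        assert out.phrases[0].words[0].phones == ("s", "t", "k", "a")

    def test_only_devoiced_vowels_touched(self, small_synth):
        corpus, _truth, _cfg = small_synth
        out = apply_deletion(corpus, 0.5, seed=9)
        before = Counter(corpus.iter_phones())
        after = Counter(out.iter_phones())
        for lab, n in before.items():
            if not corpus.inventory[lab].is_devoiced_vowel:
                assert after[lab] == n, lab
            else:
                assert after[lab] <= n

    def test_determinism(self, small_synth):
        corpus, _truth, _cfg = small_synth
        a = apply_deletion(corpus, 0.3, seed=5)
        b = apply_deletion(corpus, 0.3, seed=5)
        assert a.phrases == b.phrases

    def test_long_devoiced_switch(self):
        c = _corpus(["s", "u0:", "t", "u0"])
        out = apply_deletion(c, 1.0, seed=1, include_long=False)
        assert out.phrases[0].words[0].phones == ("s", "u0:", "t")

    def test_rate_out_of_range(self):
        c = _corpus(["k", "a"])
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            apply_deletion(c, 1.5, seed=1)


class TestPhoneStreams:
    def test_words_concatenate_with_phrase_edge_boundaries(self):
        c = corpus_from_streams(
            [("p0", [("w1", "N", ["k", "a"]), ("w2", "N", ["t", "a"])])]
        )
        assert phone_streams(c, with_boundaries=True) == [["#", "k", "a", "t", "a", "#"]]
        assert phone_streams(c, with_boundaries=False) == [["k", "a", "t", "a"]]

    def test_one_stream_per_phrase(self, small_synth):
        corpus, _truth, _cfg = small_synth
        assert len(phone_streams(corpus)) == len(corpus)

    def test_empty_corpus_gives_empty_result(self):
        assert phone_streams(Corpus(())) == []


def test_phone_attribute_parsing():
    v = parse_label("u0:")
    assert (v.kind, v.quality, v.voicing, v.length) == ("vowel", "u", "devoiced", "long")
    c = parse_label("ky~")
    assert (c.kind, c.palatalized, c.palatalization_source) == ("consonant", True, "phonetic")
    n = parse_label("N")
    assert n.kind == "placeless-coda"
    with pytest.raises(ValueError):
        parse_label("x7")


def test_vowel_subinventory_has_twenty_members():
    inv = default_inventory()
    vowels = [p for p in inv.values() if p.kind == "vowel"]
    assert len(vowels) == 20
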