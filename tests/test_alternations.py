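"""Edit-operation extraction, weighting, contextualization and surprisal."""

import math

import pytest
from hypothesis import given, strategies as st

from epenthesis_lab.alternations import (
    collect_operations,
    contextualize,
    diff_ops,
    op_surprisal,
    operations_frame,
    zero_to_vowel_report,
)
from epenthesis_lab.lexicon import LexicalEntry, LexicalKey, Lexicon, build_lexicon

from .oracles import apply_edit_script

seq = st.lists(st.sampled_from(["k", "t", "a", "u", "u0", "sh", "i0"]),
               min_size=0, max_size=8)


def _sigs(ops):
    return [(o.kind, o.from_seg, o.to_seg) for o in ops]


class TestDiffOps:
    def test_vowel_zero_alternation_surfaces_as_insert(self):
        ops = diff_ops(["sh", "i0", "t", "a"], ["sh", "t", "a"])
        assert _sigs(ops) == [("equal", "sh", "sh"), ("insert", None, "i0"),
                              ("equal", "t", "t"), ("equal", "a", "a")]

    def test_voicing_alternation_surfaces_as_replace(self):
        ops = diff_ops(["sh", "i0", "t", "a"], ["sh", "i", "t", "a"])
        assert _sigs(ops) == [("equal", "sh", "sh"), ("replace", "i", "i0"),
                              ("equal", "t", "t"), ("equal", "a", "a")]

    def test_self_comparison_is_all_equal(self):
        ops = diff_ops(["a", "k", "a"], ["a", "k", "a"])
        assert all(o.kind == "equal" for o in ops)

    def test_extra_alternate_segment_is_delete(self):
        ops = diff_ops(["k", "a"], ["k", "u0", "a"])
        assert ("delete", "u0", None) in _sigs(ops)

    def test_empty_baseline_rejected(self):
        with pytest.raises(ValueError):
            diff_ops([], ["k"])

    @given(seq.filter(bool), seq)
    def test_ops_rebuild_baseline_from_alternate(self, baseline, alternate):
        ops = diff_ops(baseline, alternate)
        assert apply_edit_script(ops, alternate) == baseline


class TestContextualize:
    def test_insert_context_is_preceding_baseline_segment(self):
        base = ["sh", "i0", "t", "a"]
        ops = contextualize(diff_ops(base, ["sh", "t", "a"]), base)
        ins = [o for o in ops if o.kind == "insert"][0]
        assert ins.context == "sh"

    def test_word_initial_context_is_boundary(self):
        base = ["k", "a"]
        ops = contextualize(diff_ops(base, ["t", "a"]), base)
        assert ops[0].context == "#"

    def test_hand_walked_contexts(self):
        base = ["a", "k", "a"]
        ops = contextualize(diff_ops(base, base), base)
        assert [o.context for o in ops] == ["#", "a", "k"]


class TestCollectOperations:
    def _did_only_lexicon(self):
        lex = Lexicon()
        key = LexicalKey("shita1", "Verb")
        lex.entries[key] = LexicalEntry(key, {("sh", "i0", "t", "a"): 7,
                                              ("sh", "t", "a"): 2,
                                              ("sh", "i", "t", "a"): 1})
        return lex

    def test_worked_example_weights(self):
        table = collect_operations(self._did_only_lexicon())
        sh = table.stats["sh"]
        assert sh[("insert", "", "i0")] == 2.0  # from the deleted form, x2
        assert sh[("replace", "i", "i0")] == 1.0  # from the voiced form, x1
        # equal ops after sh: t from the x2 form is aligned after the insert
        assert sh[("equal", "i0", "i0")] == 7.0  # self-comparison of the baseline

    def test_self_comparison_weight_equals_token_count(self):
        lex = Lexicon()
        key = LexicalKey("aru", "Verb")
        lex.entries[key] = LexicalEntry(key, {("a", "r", "u"): 10})
        table = collect_operations(lex)
        assert table.stats["#"][("equal", "a", "a")] == 10.0
        assert table.stats["a"][("equal", "r", "r")] == 10.0
        assert table.stats["r"][("equal", "u", "u")] == 10.0

    def test_total_weight_hand_computed(self):
        # 'did' alone: self 4 ops x7 + deleted-form 4 ops x2 + voiced-form 4 ops x1
        table = collect_operations(self._did_only_lexicon())
        total = sum(w for ctx in table.stats.values() for w in ctx.values())
        assert total == 4 * 7 + 4 * 2 + 4 * 1

    def test_tied_forms_processed_in_both_directions_at_half_weight(self):
        lex = Lexicon()
        key = LexicalKey("w", "Noun")
        lex.entries[key] = LexicalEntry(key, {("k", "u0", "t", "a"): 3,
                                              ("k", "t", "a"): 3})
        table = collect_operations(lex)
        # primary baseline is the lexicographically smaller tied form (k,t,a);
        # the tied alternate is compared in both directions at half weight
        assert table.stats["k"][("insert", "", "u0")] == 1.5
        assert table.stats["k"][("delete", "u0", "")] == 1.5
        total = sum(w for ctx in table.stats.values() for w in ctx.values())
        # self x3 (3 ops) + each direction 1.5 x (4 ops)
        assert total == 9 + 6 + 6

    def test_self_identical_lexicon_yields_only_equal_signatures(self):
        lex = Lexicon()
        for i, form in enumerate([("k", "a"), ("t", "u")]):
            key = LexicalKey(f"w{i}", "Noun")
            lex.entries[key] = LexicalEntry(key, {form: 5})
        table = collect_operations(lex)
        kinds = {sig[0] for ctx in table.stats.values() for sig in ctx}
        assert kinds == {"equal"}


class TestOpSurprisal:
    def _table(self):
        lex = Lexicon()
        key = LexicalKey("w", "Noun")
        # context k total weight 10: insert i0 weight 2, equal weight 8
        lex.entries[key] = LexicalEntry(key, {("k", "i0", "a"): 8, ("k", "a"): 2})
        return collect_operations(lex)

    def test_hand_arithmetic(self):
        table = self._table()
        # after k: equal i0 (8) + insert i0 (2) = total 10
        assert math.isclose(op_surprisal(table, "k", ("insert", "", "i0")),
                            -math.log2(0.2))

    def test_single_signature_is_zero_bits(self):
        table = self._table()
        # context i0 only ever sees equal a -> a (weight 8)
        assert op_surprisal(table, "i0", ("equal", "a", "a")) == 0.0

    def test_unobserved_signature_is_infinite(self):
        table = self._table()
        assert math.isinf(op_surprisal(table, "k", ("insert", "", "u0")))

    def test_unknown_context_is_an_error(self):
        with pytest.raises(KeyError):
            op_surprisal(self._table(), "zz", ("equal", "a", "a"))


class TestZeroToVowelReport:
    def _lexicon(self, weights: dict[str, int]):
        lex = Lexicon()
        for i, (vowel, count) in enumerate(weights.items()):
            key = LexicalKey(f"w{i}", "Noun")
            lex.entries[key] = LexicalEntry(
                key, {("p", vowel, "t", "o"): count + 1, ("p", "t", "o"): count}
            )
        return lex

    def test_ranked_ascending_by_surprisal(self):
        table = collect_operations(self._lexicon({"u": 8, "u0": 5, "i": 1}))
        frame = zero_to_vowel_report(table, k=3, contexts=["p"])
        assert list(frame.loc[0, ["vowel_1", "vowel_2", "vowel_3"]]) == ["u", "u0", "i"]

    def test_context_without_inserts_gets_dash_row(self):
        lex = Lexicon()
        key = LexicalKey("w", "Noun")
        lex.entries[key] = LexicalEntry(key, {("g", "a"): 5})
        table = collect_operations(lex)
        frame = zero_to_vowel_report(table, k=3, contexts=["g"])
        assert list(frame.loc[0, ["vowel_1", "bits_1"]]) == ["-", "-"]

    def test_equal_weights_tie_lexicographic_and_equal_bits(self):
        table = collect_operations(self._lexicon({"a": 4, "u": 4}))
        frame = zero_to_vowel_report(table, k=3, contexts=["p"])
        assert list(frame.loc[0, ["vowel_1", "vowel_2"]]) == ["a", "u"]
        assert frame.loc[0, "bits_1"] == frame.loc[0, "bits_2"]


def test_equal_bias_when_most_tokens_do_not_alternate(toy_corpus):
    table = collect_operations(build_lexicon(toy_corpus))
    eq = sum(w for ctx in table.stats.values()
             for sig, w in ctx.items() if sig[0] == "equal")
    ne = sum(w for ctx in table.stats.values()
             for sig, w in ctx.items() if sig[0] != "equal")
    assert eq > ne
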