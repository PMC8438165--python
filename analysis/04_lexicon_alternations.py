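#!/usr/bin/env python
"""Lexical alternation learning: ∅→vowel operations per consonant context.

Builds the (orthography, category)-keyed surface lexicon, extracts
frequency-weighted edit operations between each entry's baseline form and
its alternates, and ranks nothing-to-vowel insertions by operation
surprisal per context.  The headline check: after every voiceless
consonant, the cheapest insertion is the planted devoiced/deleted vowel of
that context, and deletion operations are never the cheapest anywhere —
the learner acquires a keep-equal bias plus targeted vowel recovery.
"""

from pathlib import Path

from epenthesis_lab.alternations import (
    collect_operations,
    operations_frame,
    zero_to_vowel_report,
)
from epenthesis_lab.corpus import read_corpus
from epenthesis_lab.lexicon import build_lexicon, lexicon_frame, variation_summary

OUT = Path("results/analysis")


def main() -> None:
    corpus = read_corpus(OUT / "corpus.jsonl")
    lexicon = build_lexicon(corpus)
    summary = variation_summary(lexicon)
    print(f"lexicon: {summary.n_entries} unique words, "
          f"{summary.n_multiform} with more than one surface form "
          f"({lexicon.n_skipped} tokens emptied by deletion were skipped)")
    lexicon_frame(lexicon).to_csv(OUT / "lexicon.tsv", sep="\t", index=False)

    table = collect_operations(lexicon)
    operations_frame(table).to_csv(OUT / "operations.tsv", sep="\t", index=False)
    inv = corpus.inventory
    contexts = sorted(c for c in table.contexts()
                      if c in inv and inv[c].is_consonant)
    frame = zero_to_vowel_report(table, k=3, contexts=contexts)
    frame.to_csv(OUT / "zero_to_vowel.tsv", sep="\t", index=False)
    print("\nThree lowest-surprisal ∅→vowel insertions per context (bits):")
    print(frame.to_string(index=False))

    eq = sum(w for ctx in table.stats.values()
             for sig, w in ctx.items() if sig[0] == "equal")
    ne = sum(w for ctx in table.stats.values()
             for sig, w in ctx.items() if sig[0] != "equal")
    print(f"\nkeep-equal bias: equal weight {eq:.0f} vs non-equal {ne:.0f} "
          f"({eq / (eq + ne):.1%} equal)")


if __name__ == "__main__":
    main()
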