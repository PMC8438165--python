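#!/usr/bin/env python
"""Sublexical predictability: vowel surprisal per consonant context.

For each consonant, ranks all twenty surface vowels (voiced/devoiced ×
short/long) by conditional surprisal -log2 Pr(v|C), with no a-priori
restriction of the candidate set.  Also prints a surprisal-smoothing
example: the direct transition across a deletion-created cluster versus
the path through an epenthesized vowel.
"""

from pathlib import Path

from epenthesis_lab.corpus import phone_streams, read_corpus
from epenthesis_lab.surprisal import (
    candidate_frame,
    smoothing_report,
    successor_distribution,
    surprisal_frame,
)

OUT = Path("results/analysis")


def main() -> None:
    corpus = read_corpus(OUT / "corpus.jsonl")
    dist = successor_distribution(phone_streams(corpus, with_boundaries=True))
    inv = corpus.inventory
    contexts = sorted(c for c in dist.contexts()
                      if c in inv and inv[c].is_consonant)
    surprisal_frame(dist).to_csv(OUT / "surprisal.tsv", sep="\t", index=False)
    frame = candidate_frame(dist, contexts, k=3)
    frame.to_csv(OUT / "candidates.tsv", sep="\t", index=False)
    print("Three lowest-surprisal vowels per consonant context (bits):")
    print(frame.to_string(index=False))

    # pick the most frequent deletion-created cluster for the smoothing demo
    best = None
    for c1 in contexts:
        for c2, n in dist.counts[c1].items():
            if c2 in inv and inv[c2].is_consonant:
                if best is None or n > best[2]:
                    best = (c1, c2, n)
    if best:
        c1, c2, _n = best
        # epenthesize the lowest-surprisal short high vowel for this context
        highs = [v for v in ("u", "u0", "i", "i0") if v in dist.counts[c1]]
        v = min(highs, key=lambda v: -dist.pr(c1, v))
        rep = smoothing_report(dist, c1, c2, v)
        print(f"\nSmoothing example — most frequent surface cluster [{c1} {c2}]:")
        print(f"  direct   s({c2}|{c1}) = {rep.direct:.3f} bits")
        print(f"  insert   s({v}|{c1}) = {rep.insert_step:.3f} bits")
        print(f"  continue s({c2}|{v}) = {rep.continue_step:.3f} bits")
        print(f"  path sum {rep.path_sum:.3f} bits; "
              f"smoothing {'achieved' if rep.smoothed else 'not achieved'}")


if __name__ == "__main__":
    main()
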