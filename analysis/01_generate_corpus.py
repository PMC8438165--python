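#!/usr/bin/env python
"""Generate the study corpus: ~10^5 words of Japanese-like speech.

Draws the default synthetic corpus — strictly CV word types, planted
per-consonant vowel distributions, high-vowel devoicing between voiceless
consonants at 0.85, deletion of devoiced vowels at 0.10 — and writes the
pre-processed corpus plus a ground-truth summary for the later stages.
"""

import json
from pathlib import Path

from epenthesis_lab.corpus import write_corpus
from epenthesis_lab.synthesis import SyntheticConfig, generate_corpus

OUT = Path("results/analysis")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SyntheticConfig()  # the default study conditions, seed included
    corpus, truth = generate_corpus(cfg)
    write_corpus(corpus, OUT / "corpus.jsonl")
    summary = {
        "seed": cfg.seed,
        "n_phrases": len(corpus),
        "n_words": corpus.n_words(),
        "n_phones": corpus.n_phones(),
        "n_devoiced_pre_deletion": truth.n_devoiced_pre,
        "n_deleted": truth.n_deleted,
        "n_cc_types_from_deletion": len(truth.cc_types_from_deletion),
        "planted_mode": truth.planted_mode,
        "deleted_per_context": {
            f"{c} {v}": n
            for (c, v), n in sorted(truth.deleted_per_context.items())
        },
    }
    (OUT / "ground_truth.json").write_text(json.dumps(summary, indent=1) + "\n")
    print(f"corpus: {summary['n_phrases']} phrases, {summary['n_words']} words, "
          f"{summary['n_phones']} phones")
    print(f"devoiced vowels before deletion: {summary['n_devoiced_pre_deletion']}")
    print(f"deleted: {summary['n_deleted']} "
          f"({summary['n_deleted'] / summary['n_devoiced_pre_deletion']:.3f} "
          f"of devoiced; configured rate {cfg.deletion_rate})")
    print(f"consonant-cluster biphone types created by deletion: "
          f"{summary['n_cc_types_from_deletion']}")
    print(f"wrote {OUT / 'corpus.jsonl'} and {OUT / 'ground_truth.json'}")


if __name__ == "__main__":
    main()
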