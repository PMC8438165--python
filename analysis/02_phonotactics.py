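#!/usr/bin/env python
"""Phonotactic learning: biphone O/E ratios and induced constraints.

Counts biphones over the unsegmented phrase streams of the study corpus
(boundaries at phrase edges only), computes observed/expected ratios, and
induces markedness (O/E < 0.75) and Contiguity (O/E > 1.25) constraints.
The headline check: every consonant cluster — all of which were created by
vowel deletion — comes out underrepresented and receives a markedness
constraint, while the strongest Contiguity constraints are all CV.
"""

from pathlib import Path

from epenthesis_lab.corpus import phone_streams, read_corpus
from epenthesis_lab.phonotactics import (
    Thresholds,
    biphone_frame,
    constraint_report,
    count_biphones,
    induce_constraints,
)

OUT = Path("results/analysis")


def main() -> None:
    corpus = read_corpus(OUT / "corpus.jsonl")
    streams = phone_streams(corpus, with_boundaries=True)
    table = count_biphones(streams)
    constraints = induce_constraints(table, Thresholds())
    frame = biphone_frame(table)
    frame.to_csv(OUT / "biphones.tsv", sep="\t", index=False)

    inv = corpus.inventory
    cc = frame[[inv[x].is_consonant and inv[y].is_consonant
                for x, y in zip(frame.x, frame.y)]]
    marked = {c.biphone for c in constraints if c.kind == "markedness"}
    print(f"{len(frame)} biphone types, {len(constraints)} constraints "
          f"({len(marked)} markedness)")
    print(f"consonant-cluster types: {len(cc)}; "
          f"underrepresented (O/E < 0.75): {(cc.OE < 0.75).sum()}; "
          f"with markedness constraint: "
          f"{sum((x, y) in marked for x, y in zip(cc.x, cc.y))}")
    rep = constraint_report(constraints, k=5)
    print("\nFive strongest Contiguity constraints (keep biphone intact):")
    print(rep.contiguity.to_string(index=False))
    print("\nFive strongest markedness constraints (flag for repair):")
    print(rep.markedness.to_string(index=False))
    rep.contiguity.to_csv(OUT / "top_contiguity.tsv", sep="\t", index=False)
    rep.markedness.to_csv(OUT / "top_markedness.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
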