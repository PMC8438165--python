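# epenthesis-lab

Computational models of **illusory vowel epenthesis** — the phenomenon in
which listeners report hearing a vowel inside a consonant cluster that is
phonotactically illegal in their native language, even when no vowel is in
the signal (Japanese listeners hearing [ebzo] as [ebuzo]). The package is
aimed at computational psycholinguists and phonologists who want to test,
on phone-level annotated speech corpora, how far three kinds of learnable
knowledge go toward predicting the identity of the illusory vowel:

1. **Phonotactic constraint induction.** Over unsegmented intonational
   phrases, every adjacent segment pair (biphone) *xy* gets an
   observed/expected ratio

   &nbsp;&nbsp;&nbsp;&nbsp;O/E(*xy*) = Pr(*xy*) / (ΣPr(*xY*) · ΣPr(*Xy*)),

   the joint probability over the product of the biphone-position
   marginals. Markedness constraints (repair *xy*) are induced for
   O/E < 0.75, Contiguity constraints (keep *xy* intact) for O/E > 1.25,
   with strength E(*xy*). In a CV-dominant language with high-vowel
   devoicing/deletion, every surface consonant cluster comes out
   underrepresented.
2. **Conditional vowel surprisal.** For each consonant context C₁ and each
   of the 20 surface vowels v (5 qualities × voiced/devoiced × short/long,
   kept distinct — no assumption of underlying categories),
   s(v | C₁) = −log₂ Pr(v | C₁) bits, computed over *all* successors with
   no a-priori restriction of the candidate set. The lowest-surprisal
   vowel per context is the phonotactically predicted epenthetic vowel,
   and epenthesis itself can be read as smoothing a surprisal peak:
   s(v|C₁) + s(C₂|v) vs. the direct s(C₂|C₁).
3. **Alternation learning.** A surface lexicon keyed by meaning proxies
   (orthography id + syntactic category) records every lexeme's surface
   forms with token counts. Each alternate form is aligned to the lexeme's
   most frequent (baseline) form by longest-contiguous-matching-block
   alignment; the per-segment equal/replace/delete/insert operations,
   weighted by token frequency and conditioned on the preceding segment,
   give operation surprisal −log₂ Pr(y→z | C₁). Vowel–zero alternations
   (∅→v inserts) after each consonant are the lexically predicted
   epenthetic vowels.

Because the speech corpus this design targets is access-restricted, the
package ships a **synthetic corpus generator** (`epenthesis_lab.synthesis`)
that emulates its structure — strictly CV word types, planted
per-consonant vowel distributions with [i]-biased palatalized consonants,
high-vowel devoicing between voiceless consonants, probabilistic deletion
of devoiced vowels, homophony across distinct lexemes — with full ground
truth, so every stage of the pipeline is tested by parameter recovery.
See `docs/methods.md` for the model details and design choices.

## Worked example

```python
from epenthesis_lab import (SyntheticConfig, generate_corpus, phone_streams,
                            count_biphones, oe_ratio, induce_constraints,
                            build_lexicon, collect_operations,
                            successor_distribution, rank_vowel_candidates,
                            smoothing_report)
from epenthesis_lab.alternations import op_surprisal

corpus, truth = generate_corpus(SyntheticConfig())   # ~10^5 words, deletion 0.10
streams = phone_streams(corpus, with_boundaries=True)

table = count_biphones(streams)
print(oe_ratio(table, "k", "u"), oe_ratio(table, "k", "t"))
dist = successor_distribution(streams)
print(rank_vowel_candidates(dist, "sh", 3))
print(smoothing_report(dist, "k", "t", "u"))
ops = collect_operations(build_lexicon(corpus))
print(op_surprisal(ops, "k", ("insert", "", "u0")))
```

prints (formatted):

```
O/E(k,u) = 2.14   O/E(k,t) = 0.0792
(k,t) gets a markedness constraint: True
after [k]: u:1.806  u0:2.084  a:3.025
after [sh]: i:1.614  i0:1.793  o:3.214
s(t|k) = 7.957  s(u|k)+s(t|u) = 1.806+3.788 = 5.594  smoothed: True
insert-u0-after-k surprisal: 5.647 bits
```

Reading: [ku] is overrepresented (O/E ≫ 1.25) and the deletion-created
cluster [kt] heavily underrepresented, so the learner flags [kt] for
repair. Among vowels, [u] is cheapest after [k] and [i] after palatalized
[ʃ] — the context-dependence that a single default epenthetic vowel cannot
capture. Epenthesizing [u] inside [kt] lowers the total surprisal of the
transition (5.59 < 7.96 bits), and in the lexicon the cheapest
nothing-to-vowel insertion after [k] is the devoiced [u], i.e. exactly the
vowel the planted devoicing/deletion process removes there.

The numbered drivers under `analysis/` run the same stages as a narrative
(generate → phonotactics → surprisal → lexicon/alternations), printing the
ranked tables and writing TSVs under `results/analysis/`:

```bash
python analysis/01_generate_corpus.py
python analysis/02_phonotactics.py
python analysis/03_surprisal.py
python analysis/04_lexicon_alternations.py
```

There is also a CLI, `epenthesis-lab`, with subcommands `generate`,
`phonotactics`, `surprisal`, `smoothing`, `lexicon`, `alternations`, and
`run` (full pipeline from a YAML config with a reproducibility manifest).

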