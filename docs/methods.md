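# Methods

This package implements three learnable accounts of illusory vowel
epenthesis — the percept of a vowel inside a phonotactically illegal
consonant cluster — as a reproducible pipeline over phone-level annotated
speech corpora, together with a synthetic corpus generator that provides
ground truth for every stage. The target language profile is Japanese: a
strongly CV language whose productive high-vowel devoicing (and frequent
outright deletion) creates surface consonant clusters, so that a learner is
exposed to clusters yet perceptually repairs them.

## Corpus model and pre-processing

A corpus is an ordered list of intonational phrases; each phrase is an
ordered list of word tokens carrying an orthography identifier, a syntactic
category, and a surface phone sequence. Segments use ASCII labels
(documented in `epenthesis_lab.phones`): 20 surface vowels (5 qualities ×
voiced/devoiced × short/long, e.g. `u`, `u0`, `u:`, `u0:`), consonants with
a palatalized subset, the placeless codas `N`/`Q`, and the boundary `#`
that only ever marks phrase edges. Long vowels are single segments —
length is a vowel attribute, not a second timing slot. `N` and `Q` are
kept verbatim: their surface place is fully predictable from the following
segment, and they are never candidates for deletion or palatalization
collapse.

Two pre-processing transforms are applied once, before any counting, so the
phrase-level and lexical analyses see identical surface forms:

1. **Palatalization collapse.** Transcriptions distinguish phonologically
   palatalized consonants from "phonetically" palatalized ones — a purely
   coarticulatory annotation occurring only before [i, iː]. A learner
   without a lexicon has no access to that underlying difference, so the
   phonetic variants are relabeled onto their phonological counterparts
   (`sh~` → `sh`). Total phone count is conserved.
2. **Devoiced-vowel deletion.** Each devoiced vowel token is independently
   deleted with probability 0.10, leaving no placeholder, reflecting
   evidence that devoiced vowels often lack any acoustic or articulatory
   trace. The 0.10 rate is a deliberately conservative default; 0.30 is
   the documented sensitivity alternative and the rate is a parameter
   everywhere. The pseudorandom stream visits devoiced tokens in corpus
   order under a fixed seed, so the transform is a pure function of
   (corpus, rate, seed). Whether long devoiced vowels are eligible is a
   switch (default: yes — the same rate for all devoiced vowels, since no
   independent estimate distinguishes them). Word tokens emptied by
   deletion are kept in the corpus but skipped by the lexicon builder with
   a logged warning; a zero-length surface form is not a lexical object.

## Phonotactic learning (biphone O/E)

Over unsegmented phrase streams (words concatenated; `#` only at phrase
edges) we count adjacent ordered pairs and compute each biphone's
observed/expected ratio

    O/E(xy) = Pr(xy) / ( ΣPr(xY) · ΣPr(Xy) ),

the joint biphone probability over the product of the two *biphone-position
marginals* — not unigram frequencies. O/E = 1 means a pair occurs exactly
as often as independent combination of first- and second-position
distributions predicts. Markedness constraints ("repair this biphone") are
induced for O/E strictly below 0.75 and Contiguity constraints ("keep it
intact") strictly above 1.25 — deliberately aggressive thresholds relative
to the 0.5/2.0 of earlier segmentation work; values exactly at a threshold
induce nothing. A constraint's strength is the biphone's expected
probability E(xy), and reports rank by strength (ties broken
lexicographically). Only biphones observed in the input induce constraints
by default; unobserved pairs with positive marginals have O/E = 0 and can
be included via a switch. No smoothing of zero counts anywhere.

Boundary symbols participate in counting, and the boundary is the
intonational-phrase edge: at this stage speech is unsegmented, so a
word-level boundary is unavailable in principle. A word-boundary mode can
be had by streaming words instead of phrases, but is not the default.

## Conditional surprisal

From the same streams, each context segment C1 gets a successor
distribution over ALL successors (vowels, consonants, codas, boundary),
and surprisal is s(v|C1) = −log2 Pr(v|C1) in bits. Ranking
epenthetic-vowel candidates is a *filtered view* of that distribution,
deliberately not renormalized over vowels: restricting the candidate set a
priori (e.g. to short high vowels) is precisely the assumption under test,
and keeping devoiced vowels distinct from their voiced counterparts is what
separates surface phonotactic knowledge from learned allophony. A successor
unobserved in an observed context has infinite surprisal and is always
reported as an absent cell ("–"), never as a finite number — there are no
pseudo-counts.

The smoothing comparison for a cluster C1C2 and candidate vowel v reports
s(C2|C1), s(v|C1), s(C2|v) and the path sum s(v|C1)+s(C2|v), plus a flag
for path sum < direct. Both components and the sum are returned; the
report does not commit to a single scalar, since the additive reading is
one interpretation among others.

## Lexicon and alternation learning

The lexicon proxies meaning by the pair (orthography id, syntactic
category): homophones with different orthography or category never merge,
and each entry maps each distinct surface phone sequence to a token count.
No underlying forms are inferred.

Alternations are mined per entry against the **baseline** — the most
frequent surface form. Alternate forms are aligned to the baseline with
the longest-contiguous-matching-block recursion (Ratcliff–Obershelp, via
`difflib.SequenceMatcher` with `autojunk=False`; ties between equal-length
blocks resolve to the earliest position). Block operations are decomposed
into per-segment equal/replace/delete/insert operations oriented so that
applying them to the *alternate* rebuilds the *baseline*: a vowel present
in the baseline but absent in the alternate is a ∅→v insert, which is the
shape vowel deletion leaves behind. Multi-segment replace blocks pair
segments positionally, overhang becoming inserts or deletes, since the
operation statistics are defined over single segments.

Weighting and contextualization:

* each alternate's operations are multiplied by the alternate's token
  count; the baseline is compared against itself at its own count, and
  non-alternating words likewise — this is what produces the keep-equal
  bias of a mostly non-alternating lexicon;
* an alternate tied with the baseline in frequency is compared in both
  directions, each direction at half the form count, so no sort order is
  privileged and total weight mass is conserved (the combination rule for
  the two runs is this package's choice). When several forms tie at the
  maximum the lexicographically smallest serves as primary baseline;
* each operation's context is the immediately preceding baseline segment,
  or a word boundary for word-initial sites (a word boundary even
  phrase-medially, following the stated rule). For inserts the preceding
  aligned segment is shared by both forms, so reading the context off the
  baseline only matters in adjacent-edit corner cases.

Per context the accumulated weights define a distribution over operation
signatures, and the operation surprisal is −log2 of a signature's weight
share. Self-comparison (equal) operations are part of the denominator: the
keep-equal bias is a claim about exactly this distribution, and a switch
(`include_self=False`) exposes the alternative. Unobserved signatures are
absent, never finite.

## Synthetic corpus generator

The restricted corpus the pipeline is designed around cannot be shipped, so
the generator emulates the structural properties the analyses rely on, with
full ground truth. Word types have fixed, strictly CV underlying forms —
fixed once per type so that devoicing/deletion create genuine surface
alternations of the same lexeme rather than per-token resamplings. Vowel
qualities are drawn per mora from planted per-consonant distributions
(palatalized consonants 0.70 [i]-biased; coronal stops prefer mid vowels,
0.50; other voiceless consonants 0.60 [u]; voiced 0.45 [u]); length is
drawn at 0.08. Devoicing applies per token to short [i, u] after a
voiceless consonant when the next segment is voiceless or the vowel is
phrase-final (so C# alternation contexts exist, as with the devoiced
copula), at rate 0.85 — high-vowel devoicing in the emulated environment
is close to categorical. Deletion then runs through the very same
`apply_deletion` transform used for real corpora at rate 0.10, and the
ground truth records deletion sites by diffing pre- and post-deletion
streams (unambiguous because vowels are never adjacent in CV forms).
Homophony is planted at rate 0.05 across distinct (orthography, category)
keys. Everything derives from a single seed via spawned seed sequences.

**Default sizes and the frequency law.** The default corpus is 25,000
phrases (~10^5 word tokens) over 5,000 word types with token frequencies
∝ rank^−0.3. These sizes are a power calculation, set in advance of the
recovery tests: recovering a planted modal vowel for a consonant context
compares an empirical mode against a runner-up whose gap, after devoicing
splits the modal vowel's mass into voiced and devoiced variants, is roughly
0.15–0.3 in probability; the number of *independent* vowel draws behind a
context's token distribution is governed by the effective sample size of
the frequency weights (≈(Σw)²/Σw²), not by token count. A textbook Zipf
exponent near 1 concentrates the token mass in a handful of types and
leaves a rare consonant's distribution resting on a few dozen effective
draws — the planted mode is then not identifiable at any corpus size. The
flattened exponent trades surface realism of the frequency law for
identifiability of the planted phonotactics while still yielding a long
tail of low-frequency words and ~40% multi-form entries. Consequences to
keep in mind when reading the recovery results against real corpora: real
lexicons are more skewed, and real conditional vowel distributions are not
iid draws per lexical slot, so passing recovery here demonstrates
correctness of the analyses, not that a real corpus of this size would
determine its modes equally sharply.

Two further consequences of the design are worth stating. First, the
planted Pr(v|C) governs the vowel slots of word-*type* forms; token-level
conditional frequencies are intentionally reweighted by word frequency and
by devoicing, so distributional checks against the planted values are run
over the type forms, where the binomial model actually holds. Second, the
vowel that "alternates with zero" after a voiceless consonant is a vowel
*quality*: depending on which surface form is a lexeme's baseline, the
learned insert is either the devoiced or the voiced variant of that
quality, and recovery of the planted deleted vowel is therefore assessed at
the quality level.

What the generator does not emulate: phonetic detail (duration, F0,
spectra), pitch accent, loanword strata, morphology, non-high-vowel
devoicing, and any dependence of deletion rate on vowel height or speech
rate.

## Pipeline, outputs, determinism

`run_all` drives source → preprocess → phonotactics → surprisal → lexicon →
alternations from one config on one pre-processed corpus, writing UTF-8
TSVs and a manifest with a config hash (output directory excluded), the
seed, and per-stage row counts; identical configs produce bit-identical
bundles. Corpora with fewer than 100 phrases (configurable) skip the
phrase-level stages, flagged as degenerate in the manifest: phrase-level
biphone statistics on a handful of phrases are noise, while the lexical
stages remain well-defined (the bundled toy lexicon exercises this path).
A stage failure aborts the run, removes partial outputs, and names the
stage. The `epenthesis-lab` CLI mirrors each stage and the full run; exit
codes are 0/1/2 for ok/config error/stage error.

## Numerical choices and degenerate inputs

* Probabilities are plain ratios of integer counts; surprisal uses
  `math.log2`. No smoothing, no pseudo-counts anywhere.
* All rankings break ties lexicographically (labels, then biphones), so
  reports are deterministic across platforms.
* O/E is undefined (an error) when a positional marginal is zero; an
  unobserved biphone with positive marginals has O/E = 0.
* Unknown contexts raise; observed contexts with unobserved successors or
  signatures yield infinity internally and dashes in reports.
* Deletion rate 0 and 1 are exact no-op/saturation bounds; empty corpora
  yield empty stream lists; a corpus whose every stream is shorter than
  two phones is a counting error, not a silent zero.
* Analytic biphone tables (`BiphoneTable.from_probabilities`) accept
  directly specified joint and marginal probabilities for worked examples;
  they carry no counts and are not validated for joint/marginal
  consistency.

## Problem sizes used by the test suite

The exhaustive oracle sweep compares O/E and conditional surprisal against
brute-force enumeration on every stream of length 2–8 over a four-symbol
alphabet (~87k streams) plus 20,000 seeded random streams of lengths 9–12;
the independence limit uses one million i.i.d. phones; edit-script
reconstruction uses 10,000 random form pairs; parameter recovery runs on
the default ~10^5-word corpus. These sizes make the checks sharp (3σ
margins or better) while keeping the whole suite fast on a single CPU.

## Known limitations

* The alternation learner reads contexts off the baseline; for pathological
  adjacent edits the "preceding segment" of an insert can differ between
  baseline and alternate. Real vowel-zero alternations do not hit this.
* The boundary-mode ambiguity (phrase-level vs word-level C# statistics) is
  resolved in favor of phrase edges; word-level counting is available but
  produces different C# tallies by construction.
* Constraint induction treats each biphone independently; there is no
  feature-based generalization across contexts (e.g. pooling palatalized
  consonants), so contexts with no observed alternation stay dash rows.
* The generator's devoicing is categorical in eligibility (flanking
  voicelessness) and binary per token; gradient devoicing and
  speaker/rate effects are out of scope.
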