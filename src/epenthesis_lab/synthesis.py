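"""Synthetic generator for Japanese-like phone-annotated speech corpora.

The restricted corpus this pipeline is designed around cannot be shipped,
so every pipeline stage is exercised on generated corpora with known ground
truth.  The generator emulates the structural properties the analyses rely
on:

* strictly CV-structured word types (with a phonemic length contrast), so
  all surface consonant clusters are created by vowel deletion;
* per-consonant planted vowel distributions, with palatalized consonants
  biased toward [i];
* productive high-vowel devoicing: a short [i] or [u] flanked by voiceless
  consonants (or phrase-final after a voiceless consonant, as in the
  devoiced copula) is devoiced with a configurable probability;
* probabilistic deletion of devoiced vowels (the same pre-processing
  transform the pipeline applies to real transcriptions), leaving no trace;
* homophony across distinct (orthography, category) lexemes, and per-lexeme
  surface variation: a word type's underlying form is fixed once, so
  devoicing/deletion create genuine surface alternations of the same
  lexeme rather than independent per-token resamplings.

Everything is reproducible from (config, seed) alone.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .corpus import Corpus, Phrase, WordToken, apply_deletion
from .phones import (
    VOICELESS_CONSONANTS,
    default_inventory,
    vowel_label,
    vowel_quality,
)

GENERATOR_PALATALIZED = ("sh", "ch", "jh", "C", "ky", "py", "gy", "by")
GENERATOR_PLAIN_VOICELESS = ("p", "t", "k", "ts", "s", "h", "F")
GENERATOR_PLAIN_VOICED = ("b", "d", "g", "z", "m", "n", "r", "w", "y")
GENERATOR_CONSONANTS = (
    GENERATOR_PLAIN_VOICELESS + GENERATOR_PLAIN_VOICED + GENERATOR_PALATALIZED
)

#: rough corpus-frequency weights for onset consonants (unnormalized)
DEFAULT_CONSONANT_WEIGHTS = {
    "t": 10.0, "k": 10.0, "s": 8.0, "n": 8.0, "m": 6.0, "r": 6.0,
    "d": 5.0, "g": 5.0, "b": 4.0, "h": 4.0, "sh": 4.0, "ts": 3.0,
    "w": 3.0, "y": 3.0, "z": 3.0, "p": 2.0, "ch": 2.0, "jh": 2.0,
    "F": 2.0, "C": 2.0, "ky": 1.0, "gy": 1.0, "py": 0.8, "by": 0.8,
}

HIGH_VOWELS = ("i", "u")


def default_vowel_distributions() -> dict[str, dict[str, float]]:
    """Planted Pr(vowel quality | consonant) for the default setting.

    Palatalized consonants are strongly [i]-biased; coronal stops prefer
    mid vowels (so not every context has a high-vowel mode); everything
    else is [u]-dominant, more strongly so when voiceless.
    """
    dists: dict[str, dict[str, float]] = {}
    for c in GENERATOR_CONSONANTS:
        if c in GENERATOR_PALATALIZED:
            dists[c] = {"i": 0.70, "a": 0.10, "o": 0.10, "u": 0.05, "e": 0.05}
        elif c == "t":
            dists[c] = {"o": 0.50, "u": 0.20, "a": 0.12, "i": 0.10, "e": 0.08}
        elif c == "d":
            dists[c] = {"e": 0.50, "u": 0.20, "a": 0.12, "i": 0.10, "o": 0.08}
        elif c in VOICELESS_CONSONANTS:
            dists[c] = {"u": 0.60, "a": 0.12, "o": 0.10, "i": 0.10, "e": 0.08}
        else:
            dists[c] = {"u": 0.45, "a": 0.18, "e": 0.14, "o": 0.13, "i": 0.10}
    return dists


@dataclass
class SyntheticConfig:
    """Generator settings; the defaults are the study conditions.

    ``devoicing_rate`` is the probability that an eligible short high vowel
    (flanked by voiceless consonants, or phrase-final after one) is
    devoiced; ``deletion_rate`` the probability a devoiced vowel is then
    deleted (0.10 by default, with 0.30 as the documented sensitivity
    alternative).
    """

    seed: int = 20210831
    n_word_types: int = 5000
    n_phrases: int = 25_000
    word_length_distribution: dict[int, float] = field(
        default_factory=lambda: {1: 0.15, 2: 0.40, 3: 0.30, 4: 0.15}
    )
    words_per_phrase_distribution: dict[int, float] = field(
        default_factory=lambda: {2: 0.15, 3: 0.25, 4: 0.30, 5: 0.20, 6: 0.10}
    )
    consonant_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONSONANT_WEIGHTS)
    )
    context_vowel_distributions: dict[str, dict[str, float]] = field(
        default_factory=default_vowel_distributions
    )
    devoicing_rate: float = 0.85
    deletion_rate: float = 0.10
    long_vowel_rate: float = 0.08
    homophony_rate: float = 0.05
    zipf_exponent: float = 0.3
    pos_labels: tuple[str, ...] = ("Noun", "Verb", "Adjective", "Adverb", "Particle")

    def validate(self) -> None:
        for name, rate in (("devoicing_rate", self.devoicing_rate),
                           ("deletion_rate", self.deletion_rate),
                           ("long_vowel_rate", self.long_vowel_rate),
                           ("homophony_rate", self.homophony_rate)):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {rate}")
        for name, dist in (
            ("word_length_distribution", self.word_length_distribution),
            ("words_per_phrase_distribution", self.words_per_phrase_distribution),
        ):
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        for c, dist in self.context_vowel_distributions.items():
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError(f"vowel distribution for {c!r} must sum to 1")
        for c in self.consonant_weights:
            if c not in self.context_vowel_distributions:
                raise ValueError(f"no vowel distribution for consonant {c!r}")


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    planted_forms: dict[tuple[str, str], tuple[str, ...]]
    vowel_distributions: dict[str, dict[str, float]]
    planted_mode: dict[str, str]  # consonant -> modal vowel quality
    n_eligible: int  # short high vowels in a devoicing-eligible position
    devoiced_per_context: Counter  # (prev consonant, devoiced label) -> count, pre-deletion
    deleted_per_context: Counter  # (prev surviving label, deleted label) -> count
    devoiced_surviving_per_context: Counter
    cc_types_from_deletion: set[tuple[str, str]]
    n_devoiced_pre: int = 0
    n_deleted: int = 0

    @property
    def n_devoiced_surviving(self) -> int:
        return self.n_devoiced_pre - self.n_deleted

    def planted_devoiced_vowel(self, context: str) -> Optional[str]:
        """Modal deleted (devoiced) vowel label after *context*, if any."""
        tallies = {lab: n for (c, lab), n in self.deleted_per_context.items()
                   if c == context}
        if not tallies:
            return None
        return min(tallies, key=lambda lab: (-tallies[lab], lab))

    def planted_deleted_quality(self, context: str) -> Optional[str]:
        """Quality of the vowel the deletion process removes after *context*.

        The voiced/devoiced surface variants of that vowel are products of
        the same devoicing process, so recovery is assessed at the quality
        level.
        """
        lab = self.planted_devoiced_vowel(context)
        if lab is None:
            return None
        return vowel_quality(lab)


def _sample_dist(rng: np.random.Generator, dist: dict, size: int) -> list:
    keys = list(dist)
    p = np.asarray([dist[k] for k in keys], dtype=float)
    p = p / p.sum()
    idx = rng.choice(len(keys), size=size, p=p)
    return [keys[i] for i in idx]


def generate_corpus(config: SyntheticConfig) -> tuple[Corpus, GroundTruth]:
    """Generate a corpus and its ground truth from the config alone.

    Deletion is applied through the same :func:`apply_deletion` transform
    used for real corpora; the ground truth records the deletion sites by
    diffing the pre- and post-deletion phrase streams.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    gen_ss, del_ss = ss.spawn(2)
    rng = np.random.default_rng(gen_ss)
    deletion_seed = int(del_ss.generate_state(1)[0] % (2**31))

    inventory = default_inventory()
    voiceless = VOICELESS_CONSONANTS

    # --- word types: fixed underlying CV forms -----------------------------
    cons_labels = list(config.consonant_weights)
    cons_p = np.asarray([config.consonant_weights[c] for c in cons_labels])
    cons_p = cons_p / cons_p.sum()
    lengths = _sample_dist(rng, config.word_length_distribution,
                           config.n_word_types)
    forms: list[tuple[str, ...]] = []
    keys: list[tuple[str, str]] = []
    for t in range(config.n_word_types):
        orth = f"w{t:05d}"
        pos = config.pos_labels[rng.integers(len(config.pos_labels))]
        if forms and rng.random() < config.homophony_rate:
            form = forms[int(rng.integers(len(forms)))]
        else:
            morae = []
            for _ in range(lengths[t]):
                c = cons_labels[int(rng.choice(len(cons_labels), p=cons_p))]
                vdist = config.context_vowel_distributions[c]
                q = _sample_dist(rng, vdist, 1)[0]
                long = bool(rng.random() < config.long_vowel_rate)
                morae.extend([c, vowel_label(q, devoiced=False, long=long)])
            form = tuple(morae)
        forms.append(form)
        keys.append((orth, pos))

    # --- token sampling (Zipf-weighted types) ------------------------------
    type_w = 1.0 / np.arange(1, config.n_word_types + 1) ** config.zipf_exponent
    type_p = type_w / type_w.sum()
    phrase_lens = _sample_dist(rng, config.words_per_phrase_distribution,
                               config.n_phrases)
    n_tokens = int(sum(phrase_lens))
    token_types = rng.choice(config.n_word_types, size=n_tokens, p=type_p)

    # --- surface realization: devoicing -------------------------------------
    n_eligible = 0
    devoiced_per_context: Counter = Counter()
    n_devoiced = 0
    phrases: list[Phrase] = []
    tok = 0
    for pid in range(config.n_phrases):
        n_words = phrase_lens[pid]
        word_type_ids = token_types[tok:tok + n_words]
        tok += n_words
        word_forms = [list(forms[t]) for t in word_type_ids]
        for wi, labs in enumerate(word_forms):
            for j in range(1, len(labs), 2):  # vowel slots of the CV template
                q = labs[j]
                if q not in HIGH_VOWELS:  # long/devoiced never planted here
                    continue
                prev = labs[j - 1]
                if prev not in voiceless:
                    continue
                if j + 1 < len(labs):
                    nxt = labs[j + 1]
                elif wi + 1 < len(word_forms):
                    nxt = word_forms[wi + 1][0]
                else:
                    nxt = None  # phrase-final
                if nxt is not None and nxt not in voiceless:
                    continue
                n_eligible += 1
                if rng.random() < config.devoicing_rate:
                    lab = vowel_label(q, devoiced=True)
                    labs[j] = lab
                    devoiced_per_context[(prev, lab)] += 1
                    n_devoiced += 1
        words = tuple(
            WordToken(keys[t][0], keys[t][1], tuple(labs))
            for t, labs in zip(word_type_ids, word_forms)
        )
        phrases.append(Phrase(f"p{pid:06d}", words))

    pre = Corpus(tuple(phrases), inventory)

    # --- deletion (shared pre-processing transform) + ground-truth diff ----
    post = apply_deletion(pre, config.deletion_rate, deletion_seed)
    deleted_per_context: Counter = Counter()
    n_deleted = 0
    cc_types: set[tuple[str, str]] = set()
    for pre_ph, post_ph in zip(pre.phrases, post.phrases):
        s_pre, s_post = pre_ph.stream(), post_ph.stream()
        i = j = 0
        while i < len(s_pre):
            if j < len(s_post) and s_pre[i] == s_post[j]:
                i += 1
                j += 1
            else:
                ctx = s_pre[i - 1] if i > 0 else "#"
                deleted_per_context[(ctx, s_pre[i])] += 1
                n_deleted += 1
                i += 1
        assert j == len(s_post), "deletion diff misaligned"
        for a, b in zip(s_post, s_post[1:]):
            if inventory[a].is_consonant and inventory[b].is_consonant:
                cc_types.add((a, b))

    truth = GroundTruth(
        planted_forms=dict(zip(keys, forms)),
        vowel_distributions={c: dict(d) for c, d in
                             config.context_vowel_distributions.items()},
        planted_mode={
            c: min(d, key=lambda q: (-d[q], q))
            for c, d in config.context_vowel_distributions.items()
        },
        n_eligible=n_eligible,
        devoiced_per_context=devoiced_per_context,
        deleted_per_context=deleted_per_context,
        devoiced_surviving_per_context=devoiced_per_context - deleted_per_context,
        cc_types_from_deletion=cc_types,
        n_devoiced_pre=n_devoiced,
        n_deleted=n_deleted,
    )
    return post, truth


def recount_ground_truth(corpus: Corpus, truth: GroundTruth) -> list[str]:
    """Re-tally devoiced vowels and CC biphones from the corpus and compare.

    Returns a list of mismatch descriptions; an empty list means the pair
    is consistent.  A mismatched pair yields a non-empty verdict, not an
    exception.
    """
    inv = corpus.inventory
    devoiced: Counter = Counter()
    cc: set[tuple[str, str]] = set()
    for ph in corpus.phrases:
        s = ph.stream()
        for i, lab in enumerate(s):
            p = inv[lab]
            if p.is_devoiced_vowel:
                ctx = s[i - 1] if i > 0 else "#"
                devoiced[(ctx, lab)] += 1
        for a, b in zip(s, s[1:]):
            if inv[a].is_consonant and inv[b].is_consonant:
                cc.add((a, b))
    mismatches: list[str] = []
    for key in set(devoiced) | set(truth.devoiced_surviving_per_context):
        got = devoiced.get(key, 0)
        want = truth.devoiced_surviving_per_context.get(key, 0)
        if got != want:
            mismatches.append(
                f"devoiced tally {key}: corpus has {got}, truth has {want}"
            )
    if cc != truth.cc_types_from_deletion:
        extra = cc - truth.cc_types_from_deletion
        missing = truth.cc_types_from_deletion - cc
        mismatches.append(
            f"CC biphone types differ (extra in corpus: {sorted(extra)}, "
            f"missing from corpus: {sorted(missing)})"
        )
    return mismatches
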