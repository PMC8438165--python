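"""Surface-form lexicon keyed by meaning proxies.

A learner that tracks which surface forms map to the same meaning can later
learn alternations between those forms.  Meaning is proxied by the pair
(orthography identifier, syntactic category): homophones with different
orthography or category stay separate entries, and each entry accumulates
token counts per distinct surface phone sequence.  No underlying forms are
inferred — the lexicon is strictly surface-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import pandas as pd

from .corpus import Corpus

logger = logging.getLogger(__name__)

Form = tuple[str, ...]


class LexicalKey(NamedTuple):
    orth_id: str
    pos: str


@dataclass
class LexicalEntry:
    key: LexicalKey
    forms: dict[Form, int] = field(default_factory=dict)
    gloss: Optional[str] = None  # expository only; never used for keying

    @property
    def n_tokens(self) -> int:
        return sum(self.forms.values())

    @property
    def is_multiform(self) -> bool:
        return len(self.forms) > 1


@dataclass
class Lexicon:
    entries: dict[LexicalKey, LexicalEntry] = field(default_factory=dict)
    n_skipped: int = 0  # word tokens emptied by deletion, not stored

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def n_tokens(self) -> int:
        return sum(e.n_tokens for e in self.entries.values())


def build_lexicon(corpus: Corpus,
                  glosses: Optional[dict[LexicalKey, str]] = None) -> Lexicon:
    """Accumulate per-(orth_id, pos) surface-form counts over the corpus.

    The corpus should already be pre-processed (palatalization collapsed,
    deletion applied) so the lexicon sees the same surface forms as the
    phrase-level analyses.  Word tokens whose phone sequence was emptied by
    deletion are skipped with a logged warning, not stored as empty forms.
    """
    lex = Lexicon()
    for phrase, word in corpus.iter_words():
        if not word.phones:
            logger.warning(
                "skipping emptied word token %r/%r in phrase %r",
                word.orth_id, word.pos, phrase.phrase_id,
            )
            lex.n_skipped += 1
            continue
        key = LexicalKey(word.orth_id, word.pos)
        entry = lex.entries.get(key)
        if entry is None:
            entry = LexicalEntry(key, gloss=(glosses or {}).get(key))
            lex.entries[key] = entry
        entry.forms[word.phones] = entry.forms.get(word.phones, 0) + 1
    return lex


def baseline_form(entry: LexicalEntry) -> tuple[Form, list[Form]]:
    """The most frequent surface form of an entry, plus all forms tied with it.

    The baseline anchors alternation extraction.  When several forms share
    the maximal count the lexicographically smallest is returned as the
    primary baseline and ``tied_forms`` has >= 2 elements, signalling the
    both-directions comparison regime downstream.
    """
    if not entry.forms:
        raise ValueError(f"entry {entry.key} has no forms")
    top = max(entry.forms.values())
    tied = sorted(f for f, c in entry.forms.items() if c == top)
    return tied[0], tied


class VariationSummary(NamedTuple):
    n_entries: int
    n_multiform: int


def variation_summary(lexicon: Lexicon) -> VariationSummary:
    """How many entries exist and how many carry more than one surface form."""
    n = len(lexicon.entries)
    multi = sum(1 for e in lexicon.entries.values() if e.is_multiform)
    return VariationSummary(n, multi)


def lexicon_frame(lexicon: Lexicon) -> pd.DataFrame:
    """Tidy (orth_id, pos, form, count) table, forms joined with spaces."""
    rows = []
    for key in sorted(lexicon.entries):
        entry = lexicon.entries[key]
        for form, count in sorted(entry.forms.items(),
                                  key=lambda fc: (-fc[1], fc[0])):
            rows.append({"orth_id": key.orth_id, "pos": key.pos,
                         "form": " ".join(form), "count": count})
    return pd.DataFrame(rows, columns=["orth_id", "pos", "form", "count"])
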