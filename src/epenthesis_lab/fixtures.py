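"""Tiny built-in corpora for demonstrations and tests.

The toy lexicon is the classic five-lexeme homophony example: three lexemes
all pronounceable [ʃita] (``sh i t a``) that differ in orthography —
'did' (Verb), 'down' (Noun), 'tongue' (Noun) — showing surface variation
between plain, devoiced and deleted realizations of the [i], plus two fully
homophonous [aru] lexemes ('exists', Verb vs. 'a certain…', Adjective)
distinguished only by syntactic category.
"""

from __future__ import annotations

from importlib import resources

from .corpus import Corpus, Phrase, WordToken, read_corpus
from .lexicon import LexicalKey

#: (orth_id, pos, gloss, [(surface form, token count), ...])
TOY_ROWS = [
    ("shita1", "Verb", "did",
     [(("sh", "i0", "t", "a"), 7), (("sh", "t", "a"), 2),
      (("sh", "i", "t", "a"), 1)]),
    ("shita2", "Noun", "down",
     [(("sh", "i0", "t", "a"), 4), (("sh", "i", "t", "a"), 1)]),
    ("shita3", "Noun", "tongue",
     [(("sh", "i0", "t", "a"), 1), (("sh", "t", "a"), 1)]),
    ("aru", "Verb", "exists", [(("a", "r", "u"), 10)]),
    ("aru", "Adjective", "a certain…", [(("a", "r", "u"), 5)]),
]


def toy_lexicon_glosses() -> dict[LexicalKey, str]:
    return {LexicalKey(orth, pos): gloss for orth, pos, gloss, _ in TOY_ROWS}


def toy_lexicon_corpus() -> Corpus:
    """The toy token stream as a corpus, one single-word phrase per token."""
    phrases = []
    i = 0
    for orth, pos, _gloss, realizations in TOY_ROWS:
        for form, count in realizations:
            for _ in range(count):
                phrases.append(
                    Phrase(f"p{i:04d}", (WordToken(orth, pos, form),))
                )
                i += 1
    return Corpus(tuple(phrases))


def toy_lexicon_path() -> str:
    """Path of the shipped JSON-Lines copy of the toy stream."""
    return str(resources.files("epenthesis_lab") / "data" / "toy_lexicon.jsonl")


def load_toy_lexicon_corpus() -> Corpus:
    return read_corpus(toy_lexicon_path())
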