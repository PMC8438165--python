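"""Corpus data model, JSON-Lines dialect, and the two pre-processing steps.

A corpus is an ordered sequence of intonational phrases, each an ordered
sequence of word tokens carrying an orthography identifier, a syntactic
category, and a phone sequence.  On disk, one phrase per line::

    {"phrase_id": str, "words": [{"orth_id": str, "pos": str, "phones": [str, ...]}]}

Pre-processing mirrors how the raw transcriptions are conditioned before any
counting: coarticulatory ("phonetic") palatalization annotations are
collapsed onto their phonological counterparts, and devoiced vowels are
probabilistically deleted, leaving no trace.  Both transforms are pure
functions of their inputs (plus the seed), and are applied once so that the
phonotactic, surprisal and lexical analyses all see the same surface forms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Union

import numpy as np

from .phones import (
    BOUNDARY,
    Phone,
    default_inventory,
    parse_label,
    phonological_counterpart,
)

PathLike = Union[str, Path]


class CorpusFormatError(ValueError):
    """A corpus file record violates the JSON-Lines dialect."""


@dataclass(frozen=True)
class WordToken:
    orth_id: str
    pos: str
    phones: tuple[str, ...]


@dataclass(frozen=True)
class Phrase:
    phrase_id: str
    words: tuple[WordToken, ...]

    def stream(self) -> list[str]:
        """Concatenated phone labels of all words (no internal boundaries)."""
        out: list[str] = []
        for w in self.words:
            out.extend(w.phones)
        return out


@dataclass
class Corpus:
    phrases: tuple[Phrase, ...]
    inventory: dict[str, Phone] = field(default_factory=default_inventory)

    def __post_init__(self) -> None:
        for ph in self.phrases:
            for w in ph.words:
                for lab in w.phones:
                    if lab not in self.inventory:
                        raise CorpusFormatError(f"unknown phone label {lab!r}")
                    if lab == BOUNDARY:
                        raise CorpusFormatError(
                            f"boundary phone inside phrase {ph.phrase_id!r}"
                        )

    def __len__(self) -> int:
        return len(self.phrases)

    def iter_words(self) -> Iterator[tuple[Phrase, WordToken]]:
        for ph in self.phrases:
            for w in ph.words:
                yield ph, w

    def iter_phones(self) -> Iterator[str]:
        for ph in self.phrases:
            for w in ph.words:
                yield from w.phones

    def n_words(self) -> int:
        return sum(len(ph.words) for ph in self.phrases)

    def n_phones(self) -> int:
        return sum(len(w.phones) for _, w in self.iter_words())


# ---------------------------------------------------------------------------
# reading / writing

def read_inventory(path: PathLike) -> dict[str, Phone]:
    """Read an inventory file (JSON mapping label -> attribute dict).

    Invalid attribute combinations (e.g. a vowel carrying a palatalized
    flag) raise :class:`CorpusFormatError` naming the offending label.
    """
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    inv: dict[str, Phone] = {}
    for label, attrs in raw.items():
        try:
            inv[label] = Phone(label=label, **attrs)
        except (TypeError, ValueError) as exc:
            raise CorpusFormatError(f"inventory entry {label!r}: {exc}") from exc
    return inv


def write_inventory(inventory: dict[str, Phone], path: PathLike) -> None:
    raw = {}
    for label, ph in sorted(inventory.items()):
        attrs = {"kind": ph.kind}
        if ph.kind == "vowel":
            attrs.update(quality=ph.quality, voicing=ph.voicing, length=ph.length)
        elif ph.kind == "consonant":
            attrs.update(palatalized=ph.palatalized,
                         palatalization_source=ph.palatalization_source)
        raw[label] = attrs
    Path(path).write_text(
        json.dumps(raw, indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )


def read_corpus(path: PathLike,
                inventory: Optional[dict[str, Phone]] = None) -> Corpus:
    """Read a JSON-Lines corpus file.

    Malformed records raise :class:`CorpusFormatError` naming the line
    number and field; unknown phone labels name the label.  Round-trips
    byte-exactly with :func:`write_corpus` for canonical files.
    """
    inv = default_inventory() if inventory is None else inventory
    phrases: list[Phrase] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(f"line {lineno}: invalid JSON ({exc})") from exc
            if not isinstance(rec, dict) or "phrase_id" not in rec:
                raise CorpusFormatError(f"line {lineno}: missing field 'phrase_id'")
            if "words" not in rec or not isinstance(rec["words"], list) or not rec["words"]:
                raise CorpusFormatError(f"line {lineno}: missing/empty field 'words'")
            words = []
            for wi, w in enumerate(rec["words"]):
                for fld in ("orth_id", "pos", "phones"):
                    if not isinstance(w, dict) or fld not in w:
                        raise CorpusFormatError(
                            f"line {lineno}: word {wi}: missing field {fld!r}"
                        )
                if not w["phones"]:
                    raise CorpusFormatError(
                        f"line {lineno}: word {wi}: field 'phones' is empty"
                    )
                for lab in w["phones"]:
                    if lab not in inv:
                        raise CorpusFormatError(
                            f"line {lineno}: word {wi}: unknown phone label {lab!r}"
                        )
                words.append(WordToken(str(w["orth_id"]), str(w["pos"]),
                                       tuple(w["phones"])))
            phrases.append(Phrase(str(rec["phrase_id"]), tuple(words)))
    return Corpus(tuple(phrases), inv)


def write_corpus(corpus: Corpus, path: PathLike) -> None:
    """Write the canonical JSON-Lines form (one phrase per line, UTF-8)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for ph in corpus.phrases:
            rec = {
                "phrase_id": ph.phrase_id,
                "words": [
                    {"orth_id": w.orth_id, "pos": w.pos, "phones": list(w.phones)}
                    for w in ph.words
                ],
            }
            fh.write(json.dumps(rec, ensure_ascii=False, separators=(",", ":")))
            fh.write("\n")


# ---------------------------------------------------------------------------
# pre-processing

def collapse_palatalization(corpus: Corpus) -> Corpus:
    """Merge phonetically palatalized consonants with their phonological twins.

    Coarticulatory palatalization annotations occur exclusively before
    [i, iː] and are not plausibly distinct on the surface; every consonant
    with ``palatalization_source == "phonetic"`` is relabeled to its
    phonological counterpart.  Total phone count is conserved.
    """
    mapping: dict[str, str] = {}
    for label, ph in corpus.inventory.items():
        if ph.kind == "consonant" and ph.palatalization_source == "phonetic":
            target = phonological_counterpart(label)
            if target not in corpus.inventory:
                raise ValueError(
                    f"phonetically palatalized {label!r} has no phonological "
                    f"counterpart {target!r} in the inventory"
                )
            mapping[label] = target
    if not mapping:
        return corpus
    new_inventory = {
        label: ph for label, ph in corpus.inventory.items() if label not in mapping
    }
    new_phrases = tuple(
        Phrase(
            ph.phrase_id,
            tuple(
                WordToken(w.orth_id, w.pos,
                          tuple(mapping.get(lab, lab) for lab in w.phones))
                for w in ph.words
            ),
        )
        for ph in corpus.phrases
    )
    return Corpus(new_phrases, new_inventory)


def apply_deletion(corpus: Corpus, rate: float, seed: int,
                   include_long: bool = True) -> Corpus:
    """Delete each devoiced vowel token independently with probability *rate*.

    Deletion leaves no placeholder.  Voiced vowels, consonants and codas are
    never touched.  The pseudorandom stream visits devoiced-vowel tokens in
    corpus order, so the same (corpus, rate, seed) always yields the same
    output.  ``include_long=False`` restricts deletion to short devoiced
    vowels.

    Word tokens emptied by deletion are kept (with an empty phone tuple);
    downstream consumers decide how to handle them.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"deletion rate must lie in [0, 1], got {rate}")
    rng = np.random.default_rng(seed)
    inv = corpus.inventory
    new_phrases = []
    for ph in corpus.phrases:
        new_words = []
        for w in ph.words:
            kept = []
            for lab in w.phones:
                p = inv[lab]
                if p.is_devoiced_vowel and (include_long or p.length == "short"):
                    if rng.random() < rate:
                        continue
                kept.append(lab)
            new_words.append(replace(w, phones=tuple(kept)))
        new_phrases.append(Phrase(ph.phrase_id, tuple(new_words)))
    return Corpus(tuple(new_phrases), dict(inv))


def phone_streams(corpus: Corpus, with_boundaries: bool = False) -> list[list[str]]:
    """One label stream per phrase; words are concatenated unsegmented.

    With ``with_boundaries`` a boundary label is prepended and appended to
    each stream — never inserted between words, since phonotactic learning
    operates on unsegmented intonational phrases.
    """
    streams = []
    for ph in corpus.phrases:
        s = ph.stream()
        if with_boundaries:
            s = [BOUNDARY] + s + [BOUNDARY]
        streams.append(s)
    return streams


def corpus_from_streams(
    word_streams: Iterable[tuple[str, list[tuple[str, str, list[str]]]]],
    inventory: Optional[dict[str, Phone]] = None,
) -> Corpus:
    """Convenience constructor from (phrase_id, [(orth_id, pos, phones)]) rows."""
    inv = default_inventory() if inventory is None else inventory
    phrases = tuple(
        Phrase(pid, tuple(WordToken(o, pos, tuple(phs)) for o, pos, phs in words))
        for pid, words in word_streams
    )
    return Corpus(phrases, inv)
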