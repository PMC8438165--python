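"""Surface phone inventory.

The segment inventory mirrors the annotation scheme of a phone-level
Japanese speech corpus, using ASCII-safe labels:

* consonants: ``p t k b d g ts dz F s sh h C ch jh m n r w y z`` plus the
  palatalized set ``py ky by gy tj dj kw Fj B`` (``F`` = [ɸ], ``sh`` = [ʃ],
  ``C`` = [ç], ``ch`` = [ʧ], ``jh`` = [ʤ], ``B`` = [β]);
* a consonant annotated as *phonetically* palatalized (coarticulatory
  fronting before [i, iː], as opposed to phonologically palatalized) carries
  a trailing ``~`` and names its phonological counterpart by stripping it
  (``sh~`` → ``sh``);
* vowels: quality in ``i e a o u``, an optional ``0`` marking devoicing and
  an optional ``:`` marking length, e.g. ``u``, ``u0``, ``u:``, ``u0:`` —
  5 qualities × {voiced, devoiced} × {short, long} = 20 surface vowels;
* the placeless codas ``N`` (moraic nasal) and ``Q`` (first half of a
  geminate), whose place is fully determined by the following segment;
* the boundary symbol ``#``, only ever appended at phrase edges.

The mapping to IPA is invertible; no romanization beyond it is attempted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

BOUNDARY = "#"

VOWEL_QUALITIES = ("a", "e", "i", "o", "u")

_VOWEL_RE = re.compile(r"^([aeiou])(0?)(:?)$")

PLAIN_CONSONANTS = (
    "p", "t", "k", "b", "d", "g", "ts", "dz", "F", "s", "sh", "h", "C",
    "ch", "jh", "m", "n", "r", "w", "y", "z",
)
PALATALIZED_CONSONANTS = ("py", "ky", "by", "gy", "tj", "dj", "kw", "Fj", "B",
                          "sh", "C", "ch", "jh")
ALL_CONSONANTS = tuple(sorted(set(PLAIN_CONSONANTS) | set(PALATALIZED_CONSONANTS)))

#: consonants produced without vocal-fold vibration; the flanking condition
#: for high-vowel devoicing.
VOICELESS_CONSONANTS = frozenset(
    {"p", "t", "k", "ts", "s", "sh", "h", "C", "ch", "F", "py", "ky", "tj", "Fj", "kw"}
)

PLACELESS_CODAS = ("N", "Q")

#: phonological palatalized consonants that also occur with a coarticulatory
#: ("phonetic") palatalization annotation in the raw transcriptions.
PHONETIC_PALATALIZATION_TWINS = ("sh", "ch", "jh", "C", "ky", "gy")

KINDS = ("consonant", "vowel", "placeless-coda", "boundary")


@dataclass(frozen=True)
class Phone:
    """A surface segment with its phonological attributes.

    Vowel attributes (``quality``, ``voicing``, ``length``) are defined iff
    ``kind == "vowel"``; ``palatalized`` and ``palatalization_source`` iff
    ``kind == "consonant"``.
    """

    label: str
    kind: str
    quality: Optional[str] = None
    voicing: Optional[str] = None
    length: Optional[str] = None
    palatalized: Optional[bool] = None
    palatalization_source: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown phone kind {self.kind!r} for {self.label!r}")
        if self.kind == "vowel":
            if self.quality not in VOWEL_QUALITIES:
                raise ValueError(f"vowel {self.label!r} needs a quality in {VOWEL_QUALITIES}")
            if self.voicing not in ("voiced", "devoiced"):
                raise ValueError(f"vowel {self.label!r} needs voicing voiced/devoiced")
            if self.length not in ("short", "long"):
                raise ValueError(f"vowel {self.label!r} needs length short/long")
            if self.palatalized is not None or self.palatalization_source is not None:
                raise ValueError(
                    f"vowel {self.label!r} may not carry palatalization attributes"
                )
        else:
            if any(v is not None for v in (self.quality, self.voicing, self.length)):
                raise ValueError(
                    f"non-vowel {self.label!r} may not carry vowel attributes"
                )
            if self.kind == "consonant":
                if self.palatalized is None:
                    raise ValueError(f"consonant {self.label!r} needs a palatalized flag")
                if self.palatalization_source not in ("none", "phonetic", "phonological"):
                    raise ValueError(
                        f"consonant {self.label!r} needs a palatalization source"
                    )
            elif self.palatalized is not None or self.palatalization_source is not None:
                raise ValueError(
                    f"{self.kind} {self.label!r} may not carry palatalization attributes"
                )

    @property
    def is_vowel(self) -> bool:
        return self.kind == "vowel"

    @property
    def is_consonant(self) -> bool:
        return self.kind == "consonant"

    @property
    def is_devoiced_vowel(self) -> bool:
        return self.kind == "vowel" and self.voicing == "devoiced"


def is_vowel_label(label: str) -> bool:
    """True iff *label* follows the vowel encoding (quality + 0? + :?)."""
    return bool(_VOWEL_RE.match(label))


def vowel_quality(label: str) -> str:
    m = _VOWEL_RE.match(label)
    if not m:
        raise ValueError(f"{label!r} is not a vowel label")
    return m.group(1)


def vowel_label(quality: str, devoiced: bool = False, long: bool = False) -> str:
    if quality not in VOWEL_QUALITIES:
        raise ValueError(f"unknown vowel quality {quality!r}")
    return quality + ("0" if devoiced else "") + (":" if long else "")


def parse_label(label: str) -> Phone:
    """Build a :class:`Phone` from its ASCII label.

    Raises :class:`ValueError` for labels outside the documented scheme.
    """
    if label == BOUNDARY:
        return Phone(label, "boundary")
    if label in PLACELESS_CODAS:
        return Phone(label, "placeless-coda")
    m = _VOWEL_RE.match(label)
    if m:
        return Phone(
            label,
            "vowel",
            quality=m.group(1),
            voicing="devoiced" if m.group(2) else "voiced",
            length="long" if m.group(3) else "short",
        )
    phonetic = label.endswith("~")
    base = label[:-1] if phonetic else label
    if base in ALL_CONSONANTS:
        palatalized = base in PALATALIZED_CONSONANTS
        if phonetic and not palatalized:
            raise ValueError(f"phonetic palatalization mark on non-palatalized {label!r}")
        source = "phonetic" if phonetic else (
            "phonological" if palatalized else "none"
        )
        return Phone(label, "consonant", palatalized=palatalized,
                     palatalization_source=source)
    raise ValueError(f"unknown phone label {label!r}")


def phonological_counterpart(label: str) -> str:
    """Merged label for a phonetically palatalized consonant (``sh~`` → ``sh``)."""
    if not label.endswith("~"):
        raise ValueError(f"{label!r} is not a phonetic-palatalization label")
    return label[:-1]


def default_inventory() -> dict[str, Phone]:
    """The full default inventory, keyed by label.

    Contains all consonants, their phonetic-palatalization twins, the 20
    surface vowels, the placeless codas and the boundary symbol.
    """
    inv: dict[str, Phone] = {}
    for c in ALL_CONSONANTS:
        inv[c] = parse_label(c)
    for c in PHONETIC_PALATALIZATION_TWINS:
        inv[c + "~"] = parse_label(c + "~")
    for q in VOWEL_QUALITIES:
        for devoiced in (False, True):
            for long in (False, True):
                lab = vowel_label(q, devoiced, long)
                inv[lab] = parse_label(lab)
    for coda in PLACELESS_CODAS:
        inv[coda] = parse_label(coda)
    inv[BOUNDARY] = parse_label(BOUNDARY)
    return inv
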