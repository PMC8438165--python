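"""Learning phonological alternations as weighted, contextualized edit operations.

Each lexical entry's surface forms are compared against the entry's
baseline (most frequent) form.  The alignment between an alternate and the
baseline is the longest-contiguous-matching-block recursion
(Ratcliff–Obershelp, as implemented by :class:`difflib.SequenceMatcher`);
the resulting block operations are decomposed into per-segment *equal /
replace / delete / insert* operations oriented so that applying them to the
ALTERNATE reconstructs the BASELINE — a vowel that is present in the
baseline but missing in the alternate therefore surfaces as a ∅→v insert,
exactly the structure that vowel devoicing-and-deletion creates.

Operations are weighted by the alternate form's token count (the baseline
is also compared against itself, weighted by its own count, so
non-alternating words contribute an explicit keep-equal bias), and
contextualized with the immediately preceding baseline segment (a word
boundary for word-initial sites).  Per context the weights define a
probability distribution over operation signatures, and each signature's
surprisal is

    s(y→z | x) = -log2 Pr(y→z | x)    [bits],

quantifying how unexpected it is for the grammar to perform that operation
after segment x.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from difflib import SequenceMatcher
from typing import Iterable, Optional, Sequence

import pandas as pd

from .phones import is_vowel_label
from .lexicon import Form, Lexicon, baseline_form

WORD_BOUNDARY = "#"

#: operation signature: (kind, from_seg-or-"", to_seg-or-"")
Signature = tuple[str, str, str]


@dataclass(frozen=True)
class EditOp:
    """One per-segment edit, sited on the baseline.

    ``site`` is the index in the baseline where the op applies (for a
    delete: the gap position, i.e. the index of the next baseline segment).
    ``from_seg``/``to_seg`` are None for the empty side of inserts/deletes.
    """

    kind: str  # equal | replace | delete | insert
    from_seg: Optional[str]  # alternate side
    to_seg: Optional[str]  # baseline side
    site: int
    context: Optional[str] = None
    weight: float = 0.0

    def __post_init__(self) -> None:
        if self.kind == "insert" and not (self.from_seg is None and self.to_seg):
            raise ValueError("insert requires from_seg=None and a to_seg")
        if self.kind == "delete" and not (self.from_seg and self.to_seg is None):
            raise ValueError("delete requires a from_seg and to_seg=None")
        if self.kind == "equal" and self.from_seg != self.to_seg:
            raise ValueError("equal requires identical segments")
        if self.kind == "replace" and (
            self.from_seg is None or self.to_seg is None or self.from_seg == self.to_seg
        ):
            raise ValueError("replace requires two distinct segments")

    @property
    def signature(self) -> Signature:
        return (self.kind, self.from_seg or "", self.to_seg or "")


def diff_ops(baseline: Sequence[str], alternate: Sequence[str]) -> list[EditOp]:
    """Per-segment edit operations transforming *alternate* into *baseline*.

    Block operations from the longest-matching-block alignment are
    decomposed into single-segment ops: replace blocks pair segments
    positionally, with overhang becoming inserts (baseline longer) or
    deletes (alternate longer).  Applying the ops to the alternate always
    reconstructs the baseline.
    """
    if not baseline:
        raise ValueError("baseline must be non-empty")
    baseline = list(baseline)
    alternate = list(alternate)
    sm = SequenceMatcher(a=alternate, b=baseline, autojunk=False)
    ops: list[EditOp] = []
    for tag, i1, i2, j1, j2 in sm.get_opcodes():
        if tag == "equal":
            for t in range(j2 - j1):
                seg = baseline[j1 + t]
                ops.append(EditOp("equal", seg, seg, site=j1 + t))
        elif tag == "delete":
            for t in range(i2 - i1):
                ops.append(EditOp("delete", alternate[i1 + t], None, site=j1))
        elif tag == "insert":
            for t in range(j2 - j1):
                ops.append(EditOp("insert", None, baseline[j1 + t], site=j1 + t))
        else:  # replace
            m, n = i2 - i1, j2 - j1
            for t in range(min(m, n)):
                frm, to = alternate[i1 + t], baseline[j1 + t]
                if frm == to:  # positional pairing may line up identical segments
                    ops.append(EditOp("equal", frm, to, site=j1 + t))
                else:
                    ops.append(EditOp("replace", frm, to, site=j1 + t))
            for t in range(min(m, n), n):  # baseline overhang -> inserts
                ops.append(EditOp("insert", None, baseline[j1 + t], site=j1 + t))
            for t in range(min(m, n), m):  # alternate overhang -> deletes
                ops.append(EditOp("delete", alternate[i1 + t], None, site=j2))
    return ops


def contextualize(ops: Iterable[EditOp], baseline: Sequence[str]) -> list[EditOp]:
    """Attach the preceding-baseline-segment context to each op.

    An op sited at baseline position 0 is word-initial and receives the
    word-boundary context.  The context is read from the baseline side of
    the alignment; for an insert the preceding aligned segment is shared by
    both forms.
    """
    out = []
    for op in ops:
        ctx = WORD_BOUNDARY if op.site == 0 else baseline[op.site - 1]
        out.append(replace(op, context=ctx))
    return out


@dataclass
class AlternationTable:
    """Context-conditioned, frequency-weighted operation statistics.

    ``stats[context][signature]`` is the accumulated weight; per context the
    weights normalize to the operation distribution that surprisal is
    computed from (keep-equal operations are part of the denominator — the
    keep-equal bias of a mostly non-alternating lexicon lives there).
    """

    stats: dict[str, dict[Signature, float]]

    def total(self, context: str) -> float:
        if context not in self.stats:
            raise KeyError(f"context {context!r} has no operations")
        return sum(self.stats[context].values())

    def contexts(self) -> list[str]:
        return sorted(self.stats)

    def add(self, context: str, signature: Signature, weight: float) -> None:
        self.stats.setdefault(context, {})
        self.stats[context][signature] = (
            self.stats[context].get(signature, 0.0) + weight
        )


def collect_operations(lexicon: Lexicon,
                       include_self: bool = True) -> AlternationTable:
    """Extract, weight and accumulate contextual edit ops over a lexicon.

    Per entry: each alternate's ops against the baseline are weighted by the
    alternate's token count; the baseline (and every non-alternating word)
    is compared against itself, weighted by its own count.  Alternates tied
    with the baseline in frequency are compared in both directions, each
    direction weighted by half the form count, so neither ordering is
    privileged and total weight mass is preserved.  ``include_self=False``
    drops the self-comparisons (and with them the explicit keep-equal bias)
    from the table.
    """
    table = AlternationTable(stats={})
    for entry in lexicon.entries.values():
        base, tied = baseline_form(entry)
        top_count = entry.forms[base]
        for form, count in entry.forms.items():
            if form == base:
                if include_self:
                    _accumulate(table, base, base, float(count))
                continue
            if count == top_count:
                _accumulate(table, base, form, count / 2.0)
                _accumulate(table, form, base, count / 2.0)
            else:
                _accumulate(table, base, form, float(count))
    return table


def _accumulate(table: AlternationTable, baseline: Form, alternate: Form,
                weight: float) -> None:
    for op in contextualize(diff_ops(baseline, alternate), baseline):
        table.add(op.context, op.signature, weight)


def op_surprisal(table: AlternationTable, context: str,
                 signature: Signature) -> float:
    """-log2 of the signature's weight share within its context, in bits.

    Returns ``math.inf`` for a signature unobserved in an observed context
    (rendered as absent in reports); raises :class:`KeyError` for an
    unknown context.
    """
    total = table.total(context)
    w = table.stats[context].get(signature, 0.0)
    if w == 0.0:
        return math.inf
    return -math.log2(w / total)


def zero_to_vowel_report(table: AlternationTable, k: int = 3,
                         contexts: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Per context, the k ∅→vowel (insert) signatures with lowest surprisal.

    Ascending by surprisal, ties lexicographic by vowel label; contexts with
    no vowel inserts (or fewer than k) get dash cells.  ``contexts``
    defaults to every context in the table.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rows = []
    for c in (contexts if contexts is not None else table.contexts()):
        sigs = table.stats.get(c, {})
        total = sum(sigs.values())
        inserts = [
            (-math.log2(w / total), sig[2], w)
            for sig, w in sigs.items()
            if sig[0] == "insert" and is_vowel_label(sig[2])
        ]
        inserts.sort(key=lambda t: (t[0], t[1]))
        row: dict[str, object] = {"context": c}
        for i in range(k):
            if i < len(inserts):
                bits, vowel, _w = inserts[i]
                row[f"vowel_{i + 1}"] = vowel
                row[f"bits_{i + 1}"] = f"{bits:.3f}"
            else:
                row[f"vowel_{i + 1}"] = "-"
                row[f"bits_{i + 1}"] = "-"
        rows.append(row)
    cols = ["context"]
    for i in range(1, k + 1):
        cols += [f"vowel_{i}", f"bits_{i}"]
    return pd.DataFrame(rows, columns=cols)


def operations_frame(table: AlternationTable) -> pd.DataFrame:
    """Tidy (context, kind, from, to, weight, bits) table."""
    rows = []
    for c in table.contexts():
        total = table.total(c)
        for sig, w in sorted(table.stats[c].items()):
            rows.append({"context": c, "kind": sig[0], "from": sig[1],
                         "to": sig[2], "weight": w,
                         "bits": -math.log2(w / total)})
    return pd.DataFrame(rows,
                        columns=["context", "kind", "from", "to", "weight", "bits"])
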