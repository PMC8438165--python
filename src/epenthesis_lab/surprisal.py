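"""Conditional successor distributions and segment surprisal.

For each context segment C1 the model estimates the conditional probability
of every successor segment from adjacent-pair counts over unsegmented
phrase streams, and reports surprisal

    s(v | C1) = -log2 Pr(v | C1)    [bits].

The distribution ranges over ALL successors (consonants, vowels, codas,
boundary); ranking epenthetic-vowel candidates is a filtered view of the
same distribution and is deliberately NOT renormalized over vowels — the
candidate set is not restricted a priori, and devoiced vowels are successor
types of their own.  A successor never observed in a context has infinite
surprisal and is reported as absent, never as a finite number: no
pseudo-counts.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .phones import is_vowel_label


@dataclass
class ContextDistribution:
    """Successor counts and conditional probabilities per context segment."""

    counts: dict[str, Counter]
    totals: dict[str, int]

    @classmethod
    def from_counts(cls, counts: dict[str, Counter]) -> "ContextDistribution":
        counts = {c: Counter(s) for c, s in counts.items() if sum(s.values()) > 0}
        totals = {c: sum(s.values()) for c, s in counts.items()}
        return cls(counts=counts, totals=totals)

    def pr(self, context: str, successor: str) -> float:
        if context not in self.totals:
            raise KeyError(f"context {context!r} never observed")
        return self.counts[context].get(successor, 0) / self.totals[context]

    def contexts(self) -> list[str]:
        return sorted(self.counts)


def successor_distribution(streams: Iterable[Sequence[str]]) -> ContextDistribution:
    """Conditional successor counts from adjacent pairs within each stream."""
    counts: dict[str, Counter] = defaultdict(Counter)
    n_pairs = 0
    for s in streams:
        for c, nxt in zip(s, s[1:]):
            counts[c][nxt] += 1
            n_pairs += 1
    if n_pairs == 0:
        raise ValueError("no biphones: every stream is shorter than 2 phones")
    return ContextDistribution.from_counts(counts)


def surprisal(dist: ContextDistribution, context: str, successor: str) -> float:
    """-log2 Pr(successor | context), in bits.

    Returns ``math.inf`` for a successor unobserved in an observed context
    (callers must render it as absent, not as a number); raises
    :class:`KeyError` for an unknown context.
    """
    p = dist.pr(context, successor)
    if p == 0.0:
        return math.inf
    return -math.log2(p)


@dataclass(frozen=True)
class SurprisalEntry:
    context: str
    successor: str
    count: int
    pr: float
    surprisal: float


def rank_vowel_candidates(
    dist: ContextDistribution, context: str, k: int
) -> tuple[list[SurprisalEntry], bool]:
    """The k vowel successors with lowest surprisal after *context*, ascending.

    Ties are broken lexicographically by label.  Returns ``(entries,
    complete)``; ``complete`` is False when fewer than k vowel successors
    were observed (reports render the missing cells as dashes).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    succ = dist.counts[context] if context in dist.counts else None
    if succ is None:
        raise KeyError(f"context {context!r} never observed")
    entries = []
    for v, c in succ.items():
        if is_vowel_label(v):
            p = c / dist.totals[context]
            entries.append(SurprisalEntry(context, v, c, p, -math.log2(p)))
    entries.sort(key=lambda e: (e.surprisal, e.successor))
    return entries[:k], len(entries) >= k


@dataclass(frozen=True)
class SmoothingReport:
    """Surprisal of a direct C1→C2 transition vs. the epenthesized path C1→v→C2.

    ``direct`` is s(C2|C1); the path decomposes into ``insert_step``
    (s(v|C1)) and ``continue_step`` (s(C2|v)), with ``path_sum`` their sum.
    ``smoothed`` flags whether the path sum undercuts the direct surprisal;
    any unobserved transition makes the corresponding member infinite.
    """

    c1: str
    c2: str
    v: str
    direct: float
    insert_step: float
    continue_step: float

    @property
    def path_sum(self) -> float:
        return self.insert_step + self.continue_step

    @property
    def smoothed(self) -> bool:
        return self.path_sum < self.direct

    @property
    def has_infinite_member(self) -> bool:
        return any(math.isinf(x) for x in
                   (self.direct, self.insert_step, self.continue_step))


def smoothing_report(dist: ContextDistribution, c1: str, c2: str, v: str
                     ) -> SmoothingReport:
    """Compare the direct consonant transition against vowel epenthesis.

    Requires all three transitions' contexts (c1 and v) to be observed.
    """
    return SmoothingReport(
        c1=c1, c2=c2, v=v,
        direct=surprisal(dist, c1, c2),
        insert_step=surprisal(dist, c1, v),
        continue_step=surprisal(dist, v, c2),
    )


def surprisal_frame(dist: ContextDistribution,
                    contexts: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Tidy (context, successor, count, pr, bits) table."""
    rows = []
    for c in (contexts if contexts is not None else dist.contexts()):
        total = dist.totals[c]
        for s, n in sorted(dist.counts[c].items()):
            p = n / total
            rows.append({"context": c, "successor": s, "count": n,
                         "pr": p, "bits": -math.log2(p)})
    return pd.DataFrame(rows, columns=["context", "successor", "count", "pr", "bits"])


def candidate_frame(dist: ContextDistribution, contexts: Sequence[str],
                    k: int = 3) -> pd.DataFrame:
    """Lowest-surprisal vowel candidates per context, one wide row per context.

    Missing candidates (fewer than k observed vowels) are rendered as "-".
    """
    rows = []
    for c in contexts:
        entries, _complete = rank_vowel_candidates(dist, c, k)
        row: dict[str, object] = {"context": c}
        for i in range(k):
            if i < len(entries):
                row[f"vowel_{i + 1}"] = entries[i].successor
                row[f"bits_{i + 1}"] = f"{entries[i].surprisal:.3f}"
            else:
                row[f"vowel_{i + 1}"] = "-"
                row[f"bits_{i + 1}"] = "-"
        rows.append(row)
    cols = ["context"]
    for i in range(1, k + 1):
        cols += [f"vowel_{i}", f"bits_{i}"]
    return pd.DataFrame(rows, columns=cols)
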