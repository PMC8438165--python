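"""Biphone statistics and frequency-driven constraint induction.

Following the frequency-driven constraint induction of lexiconless
statistical word-segmentation models, we count adjacent ordered segment
pairs (biphones) over unsegmented intonational-phrase streams and compute
observed/expected ratios

    O/E(xy) = Pr(xy) / (ΣPr(xY) · ΣPr(Xy)),

where the expectation is the product of the biphone-position marginals (the
probability of x in first position times the probability of y in second
position), not unigram frequencies.  O/E = 1 means a biphone occurred
exactly as often as expected under independent combination; markedness
constraints (repair this biphone) are induced below a threshold, Contiguity
constraints (keep it intact) above one.  The strength of an induced
constraint is the biphone's expected probability E(xy).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

Biphone = tuple[str, str]


@dataclass
class BiphoneTable:
    """Joint and positional-marginal probabilities over adjacent pairs.

    Normally built from counts via :func:`count_biphones`; analytic tables
    with directly specified probabilities can be built with
    :meth:`from_probabilities` (these carry no counts).
    """

    counts: dict[Biphone, int]
    total: int
    pr: dict[Biphone, float] = field(repr=False)
    first_marginal: dict[str, float] = field(repr=False)
    second_marginal: dict[str, float] = field(repr=False)

    @classmethod
    def from_counts(cls, counts: Mapping[Biphone, int]) -> "BiphoneTable":
        counts = dict(counts)
        total = sum(counts.values())
        if total <= 0:
            raise ValueError("biphone table needs at least one observed biphone")
        pr = {bp: c / total for bp, c in counts.items()}
        first: dict[str, float] = {}
        second: dict[str, float] = {}
        for (x, y), p in pr.items():
            first[x] = first.get(x, 0.0) + p
            second[y] = second.get(y, 0.0) + p
        return cls(counts=counts, total=total, pr=pr,
                   first_marginal=first, second_marginal=second)

    @classmethod
    def from_probabilities(
        cls,
        pr: Mapping[Biphone, float],
        first_marginal: Mapping[str, float],
        second_marginal: Mapping[str, float],
    ) -> "BiphoneTable":
        """Analytic table with given joint and positional-marginal probabilities."""
        return cls(counts={}, total=0, pr=dict(pr),
                   first_marginal=dict(first_marginal),
                   second_marginal=dict(second_marginal))


@dataclass(frozen=True)
class Thresholds:
    """O/E thresholds for constraint induction (strict inequalities)."""

    theta_under: float = 0.75
    theta_over: float = 1.25

    def __post_init__(self) -> None:
        if not (0.0 < self.theta_under < 1.0 < self.theta_over):
            raise ValueError(
                f"need 0 < theta_under < 1 < theta_over, got "
                f"{self.theta_under}/{self.theta_over}"
            )


@dataclass(frozen=True)
class Constraint:
    kind: str  # "markedness" | "contiguity"
    biphone: Biphone
    strength: float  # E(xy) = first_marginal(x) * second_marginal(y)
    oe: float


def count_biphones(streams: Iterable[Sequence[str]]) -> BiphoneTable:
    """Count adjacent ordered pairs within each stream; pairs never span streams."""
    counts: Counter[Biphone] = Counter()
    for s in streams:
        counts.update(zip(s, s[1:]))
    if not counts:
        raise ValueError("no biphones: every stream is shorter than 2 phones")
    return BiphoneTable.from_counts(counts)


def expected_probability(table: BiphoneTable, x: str, y: str) -> float:
    """E(xy): product of the two positional marginals."""
    fx = table.first_marginal.get(x, 0.0)
    sy = table.second_marginal.get(y, 0.0)
    if fx <= 0.0 or sy <= 0.0:
        raise ValueError(
            f"E({x},{y}) undefined: zero positional marginal "
            f"(first={fx}, second={sy})"
        )
    return fx * sy


def oe_ratio(table: BiphoneTable, x: str, y: str) -> float:
    """Observed/expected ratio of the ordered biphone (x, y).

    Defined only when both positional marginals are positive; an unobserved
    biphone with positive marginals has O/E = 0.
    """
    e = expected_probability(table, x, y)
    return table.pr.get((x, y), 0.0) / e


def induce_constraints(
    table: BiphoneTable,
    thresholds: Thresholds = Thresholds(),
    include_unobserved: bool = False,
) -> list[Constraint]:
    """Induce markedness/Contiguity constraints from O/E ratios.

    By default only biphones that occur in the input induce constraints;
    ``include_unobserved`` extends induction to every (x, y) pair with
    positive marginals (unobserved pairs have O/E = 0 and always fall below
    the underrepresentation threshold).
    """
    if include_unobserved:
        pairs = [(x, y) for x in table.first_marginal for y in table.second_marginal]
    else:
        pairs = list(table.pr)
    out: list[Constraint] = []
    for x, y in pairs:
        oe = oe_ratio(table, x, y)
        e = expected_probability(table, x, y)
        if oe < thresholds.theta_under:
            out.append(Constraint("markedness", (x, y), e, oe))
        elif oe > thresholds.theta_over:
            out.append(Constraint("contiguity", (x, y), e, oe))
    return out


@dataclass
class ConstraintReport:
    contiguity: pd.DataFrame
    markedness: pd.DataFrame
    truncated: bool  # True if either table holds fewer than k constraints


def _rank(constraints: list[Constraint], k: int) -> pd.DataFrame:
    rows = sorted(constraints, key=lambda c: (-c.strength, c.biphone))[:k]
    return pd.DataFrame(
        [{"kind": c.kind, "x": c.biphone[0], "y": c.biphone[1],
          "strength": c.strength, "oe": c.oe} for c in rows],
        columns=["kind", "x", "y", "strength", "oe"],
    )


def constraint_report(constraints: Iterable[Constraint], k: int) -> ConstraintReport:
    """Top-k Contiguity and markedness constraints by descending strength.

    Ties are broken lexicographically by (x, y).  If a table holds fewer
    than k constraints, all are returned and the report is flagged.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    cons = list(constraints)
    contig = [c for c in cons if c.kind == "contiguity"]
    marked = [c for c in cons if c.kind == "markedness"]
    return ConstraintReport(
        contiguity=_rank(contig, k),
        markedness=_rank(marked, k),
        truncated=len(contig) < k or len(marked) < k,
    )


def biphone_frame(table: BiphoneTable) -> pd.DataFrame:
    """Tidy per-biphone table (x, y, count, pr, E, OE), sorted by (x, y)."""
    rows = []
    for (x, y), c in sorted(table.counts.items()):
        e = expected_probability(table, x, y)
        rows.append({"x": x, "y": y, "count": c, "pr": table.pr[(x, y)],
                     "E": e, "OE": table.pr[(x, y)] / e})
    return pd.DataFrame(rows, columns=["x", "y", "count", "pr", "E", "OE"])
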