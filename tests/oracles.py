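"""Brute-force reference implementations used only to check the library.

These stay deliberately naive: biphone tokens are materialized as explicit
lists and probabilities computed by scanning them, and edit scripts are
applied segment by segment.  They share no code with the implementations
they verify.
"""

from __future__ import annotations

import math
from typing import Sequence


def biphone_tokens(streams: Sequence[Sequence[str]]) -> list[tuple[str, str]]:
    toks = []
    for s in streams:
        for i in range(len(s) - 1):
            toks.append((s[i], s[i + 1]))
    return toks


def brute_oe(streams: Sequence[Sequence[str]], x: str, y: str) -> float:
    toks = biphone_tokens(streams)
    n = len(toks)
    pxy = sum(1 for t in toks if t == (x, y)) / n
    px = sum(1 for t in toks if t[0] == x) / n
    py = sum(1 for t in toks if t[1] == y) / n
    return pxy / (px * py)


def brute_surprisal(streams: Sequence[Sequence[str]], context: str,
                    successor: str) -> float:
    toks = biphone_tokens(streams)
    n_ctx = sum(1 for t in toks if t[0] == context)
    n_both = sum(1 for t in toks if t == (context, successor))
    if n_both == 0:
        return math.inf
    return -math.log2(n_both / n_ctx)


def apply_edit_script(ops, alternate: Sequence[str]) -> list[str]:
    """Replay an op list against the alternate; returns the rebuilt baseline.

    Consumes the alternate left to right (equal/replace/delete each eat one
    segment; insert eats none) and emits the baseline side.
    """
    out: list[str] = []
    i = 0
    for op in ops:
        if op.kind in ("equal", "replace", "delete"):
            assert i < len(alternate) and alternate[i] == op.from_seg, (
                f"op {op} does not match alternate at {i}"
            )
            i += 1
        if op.to_seg is not None:
            out.append(op.to_seg)
    assert i == len(alternate), "ops did not consume the whole alternate"
    return out
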