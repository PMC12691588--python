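"""Pairwise-alignment helpers built on edlib.

One identity convention is used everywhere in the package:

    identity = matches / alignment columns

where alignment columns include gap columns (each gap column counts as a
mismatch).  With an edit-distance alignment, columns = matches + substitutions
+ insertions + deletions and editDistance = substitutions + insertions +
deletions, so identity = (columns - editDistance) / columns.
"""

from __future__ import annotations

import re
from typing import NamedTuple

import edlib

_CIGAR_OP = re.compile(r"(\d+)([MIDX=])")


def _alignment_columns(cigar: str) -> int:
    return sum(int(n) for n, _ in _CIGAR_OP.findall(cigar))


def global_identity(a: str, b: str) -> float:
    """Identity of the global (Needleman-Wunsch) alignment of two sequences."""
    if not a or not b:
        return 0.0
    res = edlib.align(a, b, mode="NW", task="path")
    cols = _alignment_columns(res["cigar"])
    if cols == 0:
        return 0.0
    return (cols - res["editDistance"]) / cols


def edit_distance(a: str, b: str) -> int:
    """Global alignment edit distance (substitutions and indels each cost 1)."""
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


class InfixMatch(NamedTuple):
    start: int  # 0-based, inclusive
    end: int  # half-open
    identity: float


def _max_edit_for_identity(query_len: int, min_identity: float) -> int:
    # identity >= min_id implies dist <= cols*(1-min_id) and cols <= len+dist,
    # hence dist <= len*(1-min_id)/min_id; round up for safety.
    return int(query_len * (1.0 - min_identity) / min_identity) + 1


def find_infix_matches(
    query: str, target: str, min_identity: float
) -> list[InfixMatch]:
    """Best approximate occurrences of ``query`` inside ``target``.

    Uses edlib's infix (HW) mode: all best-scoring placements are returned,
    each re-scored with an exact global alignment against its target slice so
    the reported identity follows the package-wide convention.  Placements
    whose identity falls below ``min_identity`` are dropped.
    """
    if not query or not target:
        return []
    k = _max_edit_for_identity(len(query), min_identity)
    res = edlib.align(query, target, mode="HW", task="locations", k=k)
    if res["editDistance"] < 0:
        return []
    out: list[InfixMatch] = []
    seen: set[tuple[int, int]] = set()
    for loc in res["locations"]:
        start = loc[0] if loc[0] is not None else 0
        end = loc[1] + 1
        if (start, end) in seen:
            continue
        seen.add((start, end))
        ident = global_identity(query, target[start:end])
        if ident >= min_identity:
            out.append(InfixMatch(start, end, ident))
    out.sort(key=lambda m: (-m.identity, m.start))
    return out
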