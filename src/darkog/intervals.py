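"""Interval arithmetic on zero-based half-open intervals.

Used to turn per-protein domain annotations into putative functional
regions: functional-annotation intervals are merged, merged
transmembrane-span intervals are subtracted, and only regions whose
remaining length strictly exceeds a minimum (30 residues/bp by default)
are kept.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Sequence

from darkog.types import Interval


def merge_intervals(xs: Iterable[Interval]) -> list[Interval]:
    """Merge overlapping or touching intervals into disjoint sorted runs."""
    by_seq: dict[str, list[Interval]] = defaultdict(list)
    for iv in xs:
        by_seq[iv.seq_id].append(iv)
    out: list[Interval] = []
    for seq_id in sorted(by_seq):
        ivs = sorted(by_seq[seq_id], key=lambda i: (i.start, i.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:  # overlap or abut
                cur_end = max(cur_end, iv.end)
            else:
                out.append(Interval(seq_id, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        out.append(Interval(seq_id, cur_start, cur_end))
    return out


def subtract_intervals(a: Iterable[Interval], b: Iterable[Interval]) -> list[Interval]:
    """Remove from ``a`` every position covered by ``b`` (per sequence)."""
    a_merged = merge_intervals(a)
    b_by_seq: dict[str, list[Interval]] = defaultdict(list)
    for iv in merge_intervals(b):
        b_by_seq[iv.seq_id].append(iv)
    out: list[Interval] = []
    for iv in a_merged:
        pieces = [(iv.start, iv.end)]
        for cut in b_by_seq.get(iv.seq_id, []):
            next_pieces = []
            for s, e in pieces:
                if cut.end <= s or cut.start >= e:
                    next_pieces.append((s, e))
                    continue
                if cut.start > s:
                    next_pieces.append((s, cut.start))
                if cut.end < e:
                    next_pieces.append((cut.end, e))
            pieces = next_pieces
        out.extend(Interval(iv.seq_id, s, e) for s, e in pieces)
    return sorted(out)


def filter_min_length(xs: Iterable[Interval], min_len: int) -> list[Interval]:
    """Keep intervals whose length is strictly greater than ``min_len``."""
    return [iv for iv in xs if len(iv) > min_len]


def total_length(xs: Sequence[Interval]) -> int:
    return sum(len(iv) for iv in xs)
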