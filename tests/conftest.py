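"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from darkog.simulate import SimConfig, simulate_corpus
from darkog.types import Interval


@pytest.fixture(scope="session")
def small_corpus():
    """A small synthetic corpus shared by read-only tests."""
    return simulate_corpus(SimConfig(seed=7, n_families=80))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


# ---------------------------------------------------------------------------
# independent oracles (deliberately naive implementations)


def positions(intervals) -> dict[str, set[int]]:
    """Explicit per-position set representation of an interval collection."""
    out: dict[str, set[int]] = {}
    for iv in intervals:
        out.setdefault(iv.seq_id, set()).update(range(iv.start, iv.end))
    return {k: v for k, v in out.items() if v}


def intervals_from_positions(pos: dict[str, set[int]]):
    """Back-convert per-position sets to maximal runs (for oracle checks)."""
    out = []
    for seq_id, ps in pos.items():
        sorted_ps = sorted(ps)
        start = prev = sorted_ps[0]
        for p in sorted_ps[1:]:
            if p != prev + 1:
                out.append(Interval(seq_id, start, prev + 1))
                start = p
            prev = p
        out.append(Interval(seq_id, start, prev + 1))
    return sorted(out)


def lca_oracle(datasets, records, ladder):
    """Scan ranks most->least specific, testing cardinality-1 of non-missing
    taxa over the member datasets."""
    for rank in ladder:
        if rank == "tax_id":
            vals = [str(records[d].tax_id) for d in datasets]
        else:
            vals = [records[d].lineage.get(rank) for d in datasets]
            if any(v is None for v in vals):
                continue
        if len(set(vals)) == 1:
            return rank, vals[0]
    return "root", "cellular organisms"


def bfs_components(nodes, edges):
    """Connected-component labels by explicit breadth-first search."""
    adj = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    labels = {}
    label = 0
    for start in nodes:
        if start in labels:
            continue
        queue = [start]
        labels[start] = label
        while queue:
            cur = queue.pop(0)
            for nb in adj[cur]:
                if nb not in labels:
                    labels[nb] = label
                    queue.append(nb)
        label += 1
    return labels


def dedup_oracle(hits):
    """Exhaustive per-unordered-pair max of normalized score."""
    from collections import defaultdict

    groups = defaultdict(list)
    for h in hits:
        groups[tuple(sorted((h.query_og, h.target_og)))].append(h)
    best = {}
    for key, hs in groups.items():
        ranked = sorted(
            hs, key=lambda h: (-(h.score / h.aln_len), -h.probability, h.query_og)
        )
        best[key] = ranked[0]
    return best
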