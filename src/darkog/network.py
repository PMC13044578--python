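"""Remote-homology network of orthogroups.

All-versus-all HMM-HMM hits between families are filtered on alignment
probability and query/subject coverage, scored by length-normalized
alignment score, collapsed to at most one undirected edge per family
pair (keeping the best-scoring hit; forward and reverse hits between the
same pair are redundant), and loaded into an undirected graph whose
connected components expose "hub-and-burst" structure: broadly
distributed, usually annotated families surrounded by narrow-lineage
dark satellites.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional

import networkx as nx
import pandas as pd

from darkog.types import HomologyHit

logger = logging.getLogger(__name__)

#: The filtering recipe keeps hits with probability >= 50%; the headline
#: network in the results applies the stricter >= 90%.  Both are presets.
PROBABILITY_PRESETS = {"methods": 50.0, "results": 90.0}


@dataclass(frozen=True)
class NetworkConfig:
    min_probability: float = 50.0
    min_q_cov: float = 0.6
    min_s_cov: float = 0.6
    drop_self: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_probability <= 100.0:
            raise ValueError("min_probability must be in [0, 100]")
        for cov in (self.min_q_cov, self.min_s_cov):
            if not 0.0 <= cov <= 1.0:
                raise ValueError("coverage thresholds must be in [0, 1]")

    @classmethod
    def preset(cls, name: str) -> "NetworkConfig":
        return cls(min_probability=PROBABILITY_PRESETS[name])


def filter_hits(hits: Iterable[HomologyHit], cfg: NetworkConfig = NetworkConfig()):
    """Keep hits with probability and both coverages at/above thresholds
    (all inclusive); drop self-hits when configured."""
    for hit in hits:
        if cfg.drop_self and hit.query_og == hit.target_og:
            continue
        if hit.probability < cfg.min_probability:
            continue
        if hit.q_cov < cfg.min_q_cov or hit.t_cov < cfg.min_s_cov:
            continue
        yield hit


def normalize_score(hit: HomologyHit) -> float:
    """Alignment score divided by alignment length."""
    if hit.aln_len < 1:
        raise ValueError("alignment length must be >= 1")
    return hit.score / hit.aln_len


def deduplicate(hits: Iterable[HomologyHit]) -> dict[tuple[str, str], HomologyHit]:
    """One hit per unordered OG pair: maximal normalized score wins.

    Ties break by higher probability, then lexicographic query id, making
    the result independent of input row order.
    """
    best: dict[tuple[str, str], HomologyHit] = {}
    for hit in hits:
        key = tuple(sorted((hit.query_og, hit.target_og)))
        cur = best.get(key)
        if cur is None:
            best[key] = hit
            continue
        new_rank = (normalize_score(hit), hit.probability)
        cur_rank = (normalize_score(cur), cur.probability)
        if new_rank > cur_rank or (new_rank == cur_rank and hit.query_og < cur.query_og):
            best[key] = hit
    return best


def build_graph(
    edges: Mapping[tuple[str, str], HomologyHit],
    node_attrs: Optional[pd.DataFrame] = None,
) -> nx.Graph:
    """Undirected weighted graph from deduplicated edges.

    ``node_attrs``, when given, is indexed by og_id and defines the node
    universe: singleton OGs without edges become isolated nodes, and an
    edge touching an OG outside the universe is an error.
    """
    g = nx.Graph()
    universe: Optional[set[str]] = None
    if node_attrs is not None:
        universe = set(node_attrs.index.astype(str))
        for og_id, row in node_attrs.iterrows():
            g.add_node(str(og_id), **{k: v for k, v in row.items() if pd.notna(v)})
    for (a, b), hit in edges.items():
        if universe is not None and (a not in universe or b not in universe):
            missing = [x for x in (a, b) if x not in universe]
            raise KeyError(f"edge references unknown node(s) {missing}")
        g.add_edge(a, b, weight=normalize_score(hit), probability=hit.probability)
    return g


def component_stats(g: nx.Graph) -> dict:
    comps = list(nx.connected_components(g))
    sizes = sorted((len(c) for c in comps), reverse=True)
    return {
        "n_nodes": g.number_of_nodes(),
        "n_edges": g.number_of_edges(),
        "n_components": len(comps),
        "largest_component_size": sizes[0] if sizes else 0,
    }


def component_labels(g: nx.Graph) -> dict[str, int]:
    """Stable component ids: components ordered by their smallest node."""
    comps = sorted(nx.connected_components(g), key=lambda c: min(c))
    return {node: i for i, comp in enumerate(comps) for node in comp}


def attribute_mixing(g: nx.Graph, attrs: Iterable[str] = ("darkness", "lca_rank")) -> pd.DataFrame:
    """Per-component tallies of node attribute values.

    Supports burst summaries such as counting narrow-LCA dark OGs sitting
    in the same component as broad-LCA light OGs.
    """
    labels = component_labels(g)
    rows = []
    for node, comp in labels.items():
        row = {"og_id": node, "component": comp}
        for attr in attrs:
            row[attr] = g.nodes[node].get(attr)
        rows.append(row)
    df = pd.DataFrame(rows)
    tallies = (
        df.melt(id_vars=["component", "og_id"], var_name="attribute", value_name="value")
        .dropna(subset=["value"])
        .groupby(["component", "attribute", "value"])
        .size()
        .rename("count")
        .reset_index()
    )
    return tallies


def write_network(g: nx.Graph, out_dir) -> dict:
    """Write edge list, component table, summary JSON and GraphML."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    edges = pd.DataFrame(
        [
            {"og_a": a, "og_b": b, "weight": d["weight"], "probability": d["probability"]}
            for a, b, d in g.edges(data=True)
        ]
    )
    edges.to_csv(out_dir / "edges.tsv", sep="\t", index=False)
    labels = component_labels(g)
    pd.DataFrame(
        sorted(labels.items()), columns=["og_id", "component_id"]
    ).to_csv(out_dir / "components.tsv", sep="\t", index=False)
    stats = component_stats(g)
    (out_dir / "summary.json").write_text(json.dumps(stats, indent=2))
    nx.write_graphml(g, out_dir / "network.graphml")
    return stats
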