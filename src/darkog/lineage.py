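"""LCA taxonomic assignment, conserved-family selection, representatives.

Each orthogroup is placed at the most specific rank of a configurable
rank ladder at which every member dataset carries the same (non-missing)
taxon — a lowest-common-ancestor walk over lineage vectors rather than
over a tree.  Dark orthogroups restricted to one of three nested lineage
groups (stony corals within hexacorals within cnidarians) and covering at
least half of that group's datasets are flagged as conserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from darkog.types import Darkness, DatasetRecord, Orthogroup, ProteinRef

logger = logging.getLogger(__name__)

#: Rank ladder, most specific first.  The custom "suborder" rank carries
#: the Complex/Robust split of stony corals and sits between order and
#: class, the only placement consistent with it refining Scleractinia.
DEFAULT_RANK_LADDER: tuple[str, ...] = (
    "tax_id",
    "isolate",
    "species",
    "genus",
    "family",
    "order",
    "suborder",
    "class",
    "subphylum",
    "phylum",
    "clade1",
    "kingdom",
    "clade",
    "superkingdom",
    "no rank",
)

#: Sentinel returned when no ladder rank is shared by all member datasets.
ROOT_SENTINEL = ("root", "cellular organisms")


def validate_ladder(ladder: Sequence[str]) -> None:
    if len(set(ladder)) != len(ladder):
        raise ValueError("rank ladder contains duplicate ranks")
    if not ladder:
        raise ValueError("rank ladder must be non-empty")


def assign_lca(
    og: Orthogroup,
    records: Mapping[str, DatasetRecord],
    ladder: Sequence[str] = DEFAULT_RANK_LADDER,
) -> tuple[str, str]:
    """Most specific ladder rank at which all member datasets agree.

    A dataset missing a taxon at a rank cannot certify agreement there, so
    the walk skips to the next (broader) rank.  ``tax_id`` participates as
    the most specific pseudo-rank: single-dataset OGs resolve to it.  If no
    rank is shared at all the root sentinel is returned and the OG flagged.
    """
    validate_ladder(ladder)
    datasets = sorted(og.member_datasets)
    recs = []
    for d in datasets:
        if d not in records:
            raise KeyError(f"no DatasetRecord for member dataset {d} of {og.og_id}")
        recs.append(records[d])
    for rank in ladder:
        if rank == "tax_id":
            taxa = {str(r.tax_id) for r in recs}
        else:
            values = [r.taxon_at(rank) for r in recs]
            if any(v is None for v in values):
                continue
            taxa = set(values)
        if len(taxa) == 1:
            taxon = taxa.pop()
            og.lca_rank, og.lca_taxon = rank, taxon
            return rank, taxon
    og.lca_rank, og.lca_taxon = ROOT_SENTINEL
    og.annotations["lca_unresolved"] = True
    return ROOT_SENTINEL


@dataclass(frozen=True)
class LineageGroupSpec:
    """Nested lineage groups used for the conserved-family selection.

    ``groups`` maps group name -> member dataset ids, ordered narrowest
    first (e.g. Scleractinia, Hexacorallia, Cnidaria); each group must be
    a subset of the next.
    """

    groups: tuple[tuple[str, frozenset[str]], ...]

    @classmethod
    def from_dict(cls, d: Mapping[str, Iterable[str]]) -> "LineageGroupSpec":
        groups = tuple((name, frozenset(ids)) for name, ids in d.items())
        if not groups or any(not ids for _, ids in groups):
            raise ValueError("each lineage group must be non-empty")
        for (n1, g1), (n2, g2) in zip(groups, groups[1:]):
            if not g1 <= g2:
                raise ValueError(f"group {n1} is not nested inside {n2}")
        return cls(groups)

    def narrowest_containing(self, datasets: frozenset[str]) -> Optional[str]:
        """Name of the narrowest group containing all datasets, or None."""
        for name, ids in self.groups:
            if datasets <= ids:
                return name
        return None

    def size(self, name: str) -> int:
        for n, ids in self.groups:
            if n == name:
                return len(ids)
        raise KeyError(name)


def select_conserved_dark(
    ogs: Iterable[Orthogroup],
    groups: LineageGroupSpec,
    min_coverage: float = 0.5,
) -> list[Orthogroup]:
    """Select dark OGs conserved across one of the nested lineage groups.

    An OG qualifies iff it is dark, all member datasets lie inside one of
    the groups, and its distinct member datasets cover at least
    ``min_coverage`` of the *narrowest* containing group (inclusive
    threshold, so 59 of 118 datasets qualifies at 0.5).  Each selected OG
    gets ``conserved_group`` set to that narrowest group, making the
    categories mutually exclusive.
    """
    selected = []
    for og in ogs:
        if og.darkness != Darkness.dark:
            continue
        datasets = og.member_datasets
        category = groups.narrowest_containing(datasets)
        if category is None:
            continue
        coverage = len(datasets) / groups.size(category)
        if coverage >= min_coverage:
            og.conserved_group = category
            og.annotations["coverage"] = coverage
            selected.append(og)
    return selected


def greedy_centroid_votes(
    members: Sequence[ProteinRef],
    scores: Mapping[tuple[ProteinRef, ProteinRef], float],
    threshold: float = 50.0,
) -> dict[ProteinRef, int]:
    """Greedy centroid clustering on a symmetric pairwise score matrix.

    Members are visited in descending row-sum order; each unassigned
    member becomes a centroid and claims every unassigned member scoring
    at or above ``threshold`` against it.  Each centroid receives one vote
    per sequence in its cluster (itself included), mirroring how a
    members->representative clustering output would be tallied.
    """
    def pair_score(a: ProteinRef, b: ProteinRef) -> float:
        return scores.get((a, b), scores.get((b, a), 0.0))

    row_sum = {m: sum(pair_score(m, o) for o in members if o != m) for m in members}
    ordered = sorted(members, key=lambda m: (-row_sum[m], m.token))
    votes: dict[ProteinRef, int] = {m: 0 for m in members}
    unassigned = set(members)
    for m in ordered:
        if m not in unassigned:
            continue
        cluster = {m} | {
            o for o in unassigned if o != m and pair_score(m, o) >= threshold
        }
        unassigned -= cluster
        votes[m] += len(cluster)
    return votes


def pick_representative(
    og: Orthogroup,
    votes: Optional[Mapping[ProteinRef, int]] = None,
    scores: Optional[Mapping[tuple[ProteinRef, ProteinRef], float]] = None,
    cluster_threshold: float = 50.0,
) -> ProteinRef:
    """Choose the representative sequence of an orthogroup.

    With precomputed ``votes``, the member with the maximal count wins;
    ties are broken lexicographically by id and recorded as an OG
    annotation.  Without votes, a pairwise score matrix is re-clustered
    greedily to produce them.
    """
    members = sorted(og.members)
    if len(members) == 1:
        og.representative = members[0]
        return members[0]
    if votes is None:
        if scores is None:
            raise ValueError("either votes or a pairwise score matrix is required")
        votes = greedy_centroid_votes(members, scores, cluster_threshold)
    best = max(votes.values())
    tied = sorted((m for m in members if votes.get(m, 0) == best),
                  key=lambda m: m.token)
    if len(tied) > 1:
        og.annotations["representative_ties"] = [m.token for m in tied]
        logger.info("%s: %d tied representatives, lexicographic choice %s",
                    og.og_id, len(tied), tied[0].token)
    og.representative = tied[0]
    return tied[0]


def patristic_distances(tree, from_taxon: str) -> dict[str, float]:
    """Patristic distance (sum of branch lengths) from one tip to all tips.

    ``tree`` is a dendropy Tree whose taxon labels are dataset ids.
    """
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    if from_taxon not in taxa:
        raise KeyError(f"taxon {from_taxon!r} not on tree")
    src = taxa[from_taxon]
    return {label: float(pdm.patristic_distance(src, t))
            for label, t in taxa.items()}
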