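"""Shared domain types for the dark-gene-family pipeline.

A *dataset* is one genome or transcriptome (one tip of the species tree).
An *orthogroup* (OG) is a gene family clustered across datasets.  A gene
is *dark* when none of its database homology hits carries an informative
functional description, and *light* otherwise.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Optional


class SourceKind(str, enum.Enum):
    genome = "genome"
    transcriptome = "transcriptome"


class Darkness(str, enum.Enum):
    dark = "dark"
    light = "light"
    unset = "unset"


@dataclass(frozen=True)
class DatasetRecord:
    """One genome/transcriptome with its taxonomy lineage.

    ``lineage`` maps rank name -> taxon name; ranks are restricted to the
    configured rank ladder and missing ranks are simply absent.
    """

    dataset_id: str
    tax_id: int
    lineage: Mapping[str, str]
    source_kind: SourceKind = SourceKind.genome

    def taxon_at(self, rank: str) -> Optional[str]:
        return self.lineage.get(rank)


@dataclass(frozen=True, order=True)
class ProteinRef:
    """A protein identified by (dataset, protein id); length in residues."""

    dataset_id: str
    protein_id: str
    length: Optional[int] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.length is not None and self.length < 1:
            raise ValueError(
                f"protein length must be >= 1, got {self.length} for "
                f"{self.dataset_id}|{self.protein_id}"
            )

    @property
    def token(self) -> str:
        return f"{self.dataset_id}|{self.protein_id}"


@dataclass
class Orthogroup:
    """A gene family: members, darkness call, LCA placement, representative."""

    og_id: str
    members: frozenset[ProteinRef]
    darkness: Darkness = Darkness.unset
    lca_rank: Optional[str] = None
    lca_taxon: Optional[str] = None
    representative: Optional[ProteinRef] = None
    conserved_group: Optional[str] = None
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"orthogroup {self.og_id} has no members")
        if self.representative is not None and self.representative not in self.members:
            raise ValueError(
                f"representative {self.representative.token} is not a member of "
                f"{self.og_id}"
            )

    @property
    def member_datasets(self) -> frozenset[str]:
        return frozenset(m.dataset_id for m in self.members)


@dataclass(frozen=True)
class AnnotationHit:
    """One database homology hit for a query protein (BLAST/DIAMOND style)."""

    query: ProteinRef
    subject_id: str
    e_value: float
    bitscore: float
    description: str

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError(f"e-value must be >= 0, got {self.e_value}")


@dataclass(frozen=True)
class HomologyHit:
    """One HMM-HMM remote-homology hit between two orthogroups.

    Coordinates are 1-based inclusive alignment columns (hhblits
    convention); ``probability`` is on the percent scale.
    """

    query_og: str
    target_og: str
    probability: float
    e_value: float
    score: float
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    aln_len: int
    q_len: int
    t_len: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 100.0:
            raise ValueError(f"probability must be in [0, 100], got {self.probability}")
        if self.aln_len < 1:
            raise ValueError("alignment length must be >= 1")
        if not (1 <= self.q_start <= self.q_end <= self.q_len):
            raise ValueError(
                f"bad query coordinates {self.q_start}-{self.q_end}/{self.q_len}"
            )
        if not (1 <= self.t_start <= self.t_end <= self.t_len):
            raise ValueError(
                f"bad target coordinates {self.t_start}-{self.t_end}/{self.t_len}"
            )

    @property
    def q_cov(self) -> float:
        return (self.q_end - self.q_start + 1) / self.q_len

    @property
    def t_cov(self) -> float:
        return (self.t_end - self.t_start + 1) / self.t_len


@dataclass(frozen=True, order=True)
class Interval:
    """Zero-based half-open interval [start, end) on a named sequence."""

    seq_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"interval start must be < end, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start
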