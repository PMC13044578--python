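"""Dark/light classification of proteins and orthogroups.

A protein is *light* (has a putative function) if at least one of its
exhaustive database homology hits, at or below the e-value cutoff, carries
a description that does not contain any functionally ambiguous phrase
("uncharacterized protein", "hypothetical protein", ...).  A protein with
no hits, or only ambiguous hits, is *dark*.  An orthogroup is dark iff all
of its member proteins are dark.

Phrase matching is case-insensitive substring containment; blank
descriptions count as ambiguous.  Hits above the e-value cutoff are
ignored entirely, so classification is reproducible from stored hit
tables regardless of the search-time threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from darkog.intervals import filter_min_length, merge_intervals, subtract_intervals
from darkog.types import AnnotationHit, Darkness, Interval, Orthogroup, ProteinRef

AMBIGUOUS_PHRASES = (
    "uncharacterized protein",
    "hypothetical protein",
    "predicted protein",
    "expressed protein",
    "unnamed protein product",
)

#: Minimum residual length (strictly greater-than) for a putative
#: functional region after transmembrane subtraction.
MIN_REGION_LENGTH = 30


@dataclass(frozen=True)
class DarknessConfig:
    e_value_cutoff: float = 1e-5
    ambiguous_phrases: tuple[str, ...] = AMBIGUOUS_PHRASES

    def __post_init__(self) -> None:
        if self.e_value_cutoff <= 0:
            raise ValueError("e_value_cutoff must be > 0")
        if not self.ambiguous_phrases:
            raise ValueError("ambiguous_phrases must be non-empty")

    def is_ambiguous(self, description: str) -> bool:
        text = description.strip().lower()
        if not text:
            return True
        return any(p in text for p in self.ambiguous_phrases)


def classify_protein(
    hits: Iterable[AnnotationHit], cfg: DarknessConfig = DarknessConfig()
) -> Darkness:
    """Classify one protein from its (possibly empty) hit set."""
    for hit in hits:
        if hit.e_value <= cfg.e_value_cutoff and not cfg.is_ambiguous(hit.description):
            return Darkness.light
    return Darkness.dark


def classify_orthogroup(
    og: Orthogroup, protein_calls: Mapping[ProteinRef, Darkness]
) -> Darkness:
    """Dark iff every member is dark; light iff any member is light."""
    for member in og.members:
        try:
            call = protein_calls[member]
        except KeyError:
            raise KeyError(
                f"no darkness call for member {member.token} of {og.og_id}"
            ) from None
        if call == Darkness.light:
            return Darkness.light
        if call != Darkness.dark:
            raise ValueError(f"member {member.token} has unset darkness call")
    return Darkness.dark


def classify_corpus(
    ogs: Iterable[Orthogroup],
    hits_by_protein: Mapping[ProteinRef, list[AnnotationHit]],
    cfg: DarknessConfig = DarknessConfig(),
) -> tuple[dict[ProteinRef, Darkness], dict[str, Darkness]]:
    """Classify every protein and orthogroup in a corpus; sets og.darkness."""
    protein_calls: dict[ProteinRef, Darkness] = {}
    og_calls: dict[str, Darkness] = {}
    for og in ogs:
        for member in og.members:
            if member not in protein_calls:
                protein_calls[member] = classify_protein(
                    hits_by_protein.get(member, []), cfg
                )
        call = classify_orthogroup(og, protein_calls)
        og.darkness = call
        og_calls[og.og_id] = call
    return protein_calls, og_calls


def darkness_summary(
    protein_calls: Mapping[ProteinRef, Darkness],
    og_calls: Mapping[str, Darkness],
) -> pd.DataFrame:
    """Corpus-level counts: proteins, dark proteins, dark fraction, OGs."""
    if not protein_calls:
        raise ValueError("empty corpus: no protein calls")
    n_proteins = len(protein_calls)
    n_dark = sum(1 for c in protein_calls.values() if c == Darkness.dark)
    n_ogs = len(og_calls)
    n_dark_ogs = sum(1 for c in og_calls.values() if c == Darkness.dark)
    return pd.DataFrame(
        [
            {
                "n_proteins": n_proteins,
                "n_dark": n_dark,
                "fraction_dark": n_dark / n_proteins,
                "n_ogs": n_ogs,
                "n_dark_ogs": n_dark_ogs,
            }
        ]
    )


@dataclass
class FunctionalRegions:
    """Functional regions of a protein after transmembrane subtraction."""

    regions: list[Interval] = field(default_factory=list)
    membrane_associated: bool = False


def derive_functional_regions(
    functional: Iterable[Interval],
    transmembrane: Iterable[Interval],
    min_length: int = MIN_REGION_LENGTH,
) -> FunctionalRegions:
    """Merge functional annotations, subtract merged TM spans, keep >min_length.

    The protein is flagged "putatively membrane associated" whenever it has
    any predicted transmembrane span at all.
    """
    tm_list, func_list = list(transmembrane), list(functional)
    tm = merge_intervals(tm_list) if tm_list else []
    merged = merge_intervals(func_list) if func_list else []
    remaining = subtract_intervals(merged, tm) if tm else merged
    kept = filter_min_length(remaining, min_length)
    return FunctionalRegions(regions=kept, membrane_associated=bool(tm))
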