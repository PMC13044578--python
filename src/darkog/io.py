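"""Readers and writers for every external table format the pipeline touches.

Dialects supported:

* Orthogroup membership — OrthoFinder-style wide TSV (``og_id`` column then
  one column per dataset, cells holding comma-separated protein ids) and a
  long 2-column TSV (``og_id`` TAB ``dataset|protein``, one member per row).
* Lineage tables — CSV with ``dataset_id``, ``tax_id`` and one column per
  taxonomic rank (ncbitax2lin-style; extra columns ignored).
* Remote-homology hits — hhblits-style TSV with 1-based inclusive alignment
  coordinates, converted/validated on read and streamed row by row.
* Intervals — 3-column BED (already zero-based half-open).
* Annotation hits — BLAST/DIAMOND outfmt-6-style TSV with a trailing
  description column.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import pandas as pd

from darkog.types import (
    AnnotationHit,
    DatasetRecord,
    HomologyHit,
    Interval,
    Orthogroup,
    ProteinRef,
    SourceKind,
)

logger = logging.getLogger(__name__)

MEMBER_DELIMITER = "|"

HOMOLOGY_HIT_COLUMNS = (
    "query",
    "target",
    "probability",
    "evalue",
    "score",
    "qstart",
    "qend",
    "tstart",
    "tend",
    "alnlen",
    "qlen",
    "tlen",
)


class ParseError(ValueError):
    """A malformed row in an input table; message names the line number."""


def _parse_member_token(token: str, delimiter: str, line_no: int, path) -> ProteinRef:
    token = token.strip()
    if delimiter not in token:
        raise ParseError(
            f"{path}:{line_no}: member token {token!r} lacks delimiter {delimiter!r}"
        )
    dataset_id, protein_id = token.split(delimiter, 1)
    if not dataset_id or not protein_id:
        raise ParseError(f"{path}:{line_no}: empty dataset or protein id in {token!r}")
    return ProteinRef(dataset_id=dataset_id, protein_id=protein_id)


def read_orthogroups(
    path,
    format: str = "long",
    delimiter: str = MEMBER_DELIMITER,
) -> list[Orthogroup]:
    """Read orthogroup membership from TSV.

    ``format`` is ``"long"`` (two columns: og_id, member token) or
    ``"orthofinder"`` (header row of dataset names; cells hold
    comma-separated protein ids).  Duplicate member tokens within an OG are
    deduplicated with a warning; duplicate og_ids across rows are an error
    in the wide dialect (and merged rows in the long dialect).
    """
    path = Path(path)
    members: dict[str, set[ProteinRef]] = {}
    order: list[str] = []
    with path.open() as fh:
        if format == "long":
            for line_no, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ParseError(f"{path}:{line_no}: expected 2 columns")
                og_id = parts[0].strip()
                if not og_id:
                    raise ParseError(f"{path}:{line_no}: empty og_id")
                ref = _parse_member_token(parts[1], delimiter, line_no, path)
                if og_id not in members:
                    members[og_id] = set()
                    order.append(og_id)
                if ref in members[og_id]:
                    logger.warning(
                        "%s:%d: duplicate member %s in %s; deduplicated",
                        path, line_no, ref.token, og_id,
                    )
                members[og_id].add(ref)
        elif format == "orthofinder":
            reader = csv.reader(fh, delimiter="\t")
            header = next(reader, None)
            if header is None or len(header) < 2:
                raise ParseError(f"{path}:1: missing header with dataset columns")
            datasets = header[1:]
            for line_no, row in enumerate(reader, start=2):
                if not row:
                    continue
                og_id = row[0].strip()
                if not og_id:
                    raise ParseError(f"{path}:{line_no}: empty og_id")
                if og_id in members:
                    raise ParseError(f"{path}:{line_no}: duplicate og_id {og_id}")
                members[og_id] = set()
                order.append(og_id)
                for dataset, cell in zip(datasets, row[1:]):
                    cell = cell.strip()
                    if not cell:
                        continue  # dataset absent from this OG
                    for pid in cell.split(","):
                        pid = pid.strip()
                        if not pid:
                            continue
                        ref = ProteinRef(dataset_id=dataset, protein_id=pid)
                        if ref in members[og_id]:
                            logger.warning(
                                "%s:%d: duplicate member %s in %s; deduplicated",
                                path, line_no, ref.token, og_id,
                            )
                        members[og_id].add(ref)
        else:
            raise ValueError(f"unknown orthogroup format {format!r}")
    ogs = []
    for og_id in order:
        if not members[og_id]:
            raise ParseError(f"{path}: orthogroup {og_id} has zero members")
        ogs.append(Orthogroup(og_id=og_id, members=frozenset(members[og_id])))
    return ogs


def write_orthogroups(ogs: Iterable[Orthogroup], path, delimiter: str = MEMBER_DELIMITER) -> None:
    """Write orthogroups in the long 2-column dialect (round-trip safe)."""
    path = Path(path)
    with path.open("w") as fh:
        for og in ogs:
            for ref in sorted(og.members):
                fh.write(f"{og.og_id}\t{ref.dataset_id}{delimiter}{ref.protein_id}\n")


def read_lineages(
    path,
    rank_ladder: Sequence[str],
    overrides: Optional[Mapping[str, tuple[str, str]]] = None,
) -> list[DatasetRecord]:
    """Read a lineage table (CSV) into DatasetRecords.

    Only columns present in ``rank_ladder`` are retained as lineage ranks
    (others are dropped with a log line).  ``overrides`` maps
    dataset_id -> (rank, taxon) applied after parsing, e.g. to stamp the
    custom Complex/Robust suborder onto stony-coral datasets.
    """
    if not rank_ladder:
        raise ValueError("rank_ladder must be non-empty")
    overrides = dict(overrides or {})
    df = pd.read_csv(path, dtype=str)
    required = {"dataset_id", "tax_id"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing required columns {sorted(missing)}")
    ladder = set(rank_ladder)
    rank_cols = [c for c in df.columns if c in ladder]
    dropped = [c for c in df.columns if c not in ladder and c not in
               ("dataset_id", "tax_id", "source_kind")]
    if dropped:
        logger.info("%s: ignoring non-ladder columns %s", path, dropped)
    for rank, _taxon in overrides.values():
        if rank not in ladder:
            raise ValueError(f"override rank {rank!r} not in rank ladder")
    records: list[DatasetRecord] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        dataset_id = row["dataset_id"]
        if dataset_id in seen:
            raise ParseError(f"{path}: duplicate dataset_id {dataset_id}")
        seen.add(dataset_id)
        lineage = {
            c: row[c] for c in rank_cols
            if isinstance(row[c], str) and row[c].strip() != ""
        }
        if dataset_id in overrides:
            rank, taxon = overrides.pop(dataset_id)
            lineage[rank] = taxon
        kind = row.get("source_kind", "genome")
        records.append(
            DatasetRecord(
                dataset_id=dataset_id,
                tax_id=int(row["tax_id"]),
                lineage=lineage,
                source_kind=SourceKind(kind) if isinstance(kind, str) else SourceKind.genome,
            )
        )
    if overrides:
        raise ValueError(
            f"overrides reference datasets absent from {path}: {sorted(overrides)}"
        )
    return records


def write_lineages(records: Iterable[DatasetRecord], path, rank_ladder: Sequence[str]) -> None:
    rows = []
    for rec in records:
        row = {"dataset_id": rec.dataset_id, "tax_id": rec.tax_id,
               "source_kind": rec.source_kind.value}
        for rank in rank_ladder:
            if rank in row:  # tax_id is carried by the base column
                continue
            row[rank] = rec.lineage.get(rank, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_homology_hits(path) -> Iterator[HomologyHit]:
    """Stream hhblits-style remote-homology hits from TSV.

    Rows with out-of-range fields (probability outside [0,100], alignment
    ends past the sequence length) are rejected with a warning rather than
    silently coerced.  The file is never materialized in memory.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        missing = [c for c in HOMOLOGY_HIT_COLUMNS if c not in idx]
        if missing:
            raise ParseError(f"{path}:1: missing columns {missing}")
        extra = [c for c in header if c not in HOMOLOGY_HIT_COLUMNS]
        if extra:
            logger.info("%s: ignoring extra columns %s", path, extra)
        for line_no, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            try:
                hit = HomologyHit(
                    query_og=parts[idx["query"]],
                    target_og=parts[idx["target"]],
                    probability=float(parts[idx["probability"]]),
                    e_value=float(parts[idx["evalue"]]),
                    score=float(parts[idx["score"]]),
                    q_start=int(parts[idx["qstart"]]),
                    q_end=int(parts[idx["qend"]]),
                    t_start=int(parts[idx["tstart"]]),
                    t_end=int(parts[idx["tend"]]),
                    aln_len=int(parts[idx["alnlen"]]),
                    q_len=int(parts[idx["qlen"]]),
                    t_len=int(parts[idx["tlen"]]),
                )
            except (ValueError, IndexError) as exc:
                logger.warning("%s:%d: rejected hit row (%s)", path, line_no, exc)
                continue
            yield hit


def write_homology_hits(hits: Iterable[HomologyHit], path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(HOMOLOGY_HIT_COLUMNS) + "\n")
        for h in hits:
            fh.write(
                f"{h.query_og}\t{h.target_og}\t{h.probability:g}\t{h.e_value:g}\t"
                f"{h.score:g}\t{h.q_start}\t{h.q_end}\t{h.t_start}\t{h.t_end}\t"
                f"{h.aln_len}\t{h.q_len}\t{h.t_len}\n"
            )


def read_annotation_hits(path) -> Iterator[AnnotationHit]:
    """Stream DIAMOND-style annotation hits from TSV.

    Expected columns: dataset_id, protein_id, subject_id, evalue, bitscore,
    description (header required; extra columns ignored).
    """
    path = Path(path)
    required = ("dataset_id", "protein_id", "subject_id", "evalue", "bitscore",
                "description")
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        missing = [c for c in required if c not in idx]
        if missing:
            raise ParseError(f"{path}:1: missing columns {missing}")
        for line_no, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            try:
                yield AnnotationHit(
                    query=ProteinRef(parts[idx["dataset_id"]], parts[idx["protein_id"]]),
                    subject_id=parts[idx["subject_id"]],
                    e_value=float(parts[idx["evalue"]]),
                    bitscore=float(parts[idx["bitscore"]]),
                    description=parts[idx["description"]],
                )
            except (ValueError, IndexError) as exc:
                logger.warning("%s:%d: rejected annotation row (%s)", path, line_no, exc)
                continue


def read_bed(path) -> list[Interval]:
    """Read 3-column BED (zero-based half-open, as BED natively is)."""
    path = Path(path)
    out = []
    with path.open() as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{line_no}: expected >= 3 BED columns")
            out.append(Interval(parts[0], int(parts[1]), int(parts[2])))
    return out


def write_bed(xs: Iterable[Interval], path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for iv in sorted(xs):
            fh.write(f"{iv.seq_id}\t{iv.start}\t{iv.end}\n")
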