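"""End-to-end orchestration of the dark-family pipeline.

Stages run in the order classify -> LCA -> conserved selection ->
representatives -> HDF -> expression bias -> remote-homology network,
from a single config whose defaults are the study recipe (e-value 1e-5;
coverage 0.5; HDF classes 0.05/0.95 with a 0.5 call fraction; DEG rules
0.5/0.05; single-cell FC 2.0; network 50%/0.6/0.6).  The machine-readable
summary is content-addressed by a hash of the config: rerunning with an
unchanged config reloads the previous summary instead of recomputing.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import dendropy
import pandas as pd

from darkog import io as dio
from darkog.darkness import DarknessConfig, classify_corpus, darkness_summary
from darkog.expression import call_celltype_expression, call_degs, proportion_bias
from darkog.hdf import (
    DEFAULT_E_THRESHOLD,
    BitscoreObservation,
    assess_og,
    fit_decay,
    predict_undetected,
)
from darkog.lineage import (
    DEFAULT_RANK_LADDER,
    LineageGroupSpec,
    assign_lca,
    patristic_distances,
    select_conserved_dark,
)
from darkog.network import NetworkConfig, build_graph, deduplicate, filter_hits, write_network
from darkog.types import Darkness, DatasetRecord

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    orthogroups: Path
    lineages: Path
    annotation_hits: Path
    species_tree: Path
    bitscores: Path
    representatives: Path
    de_results: Path
    celltype_fc: Path
    homology_hits: Path
    node_attrs: Optional[Path] = None
    out_dir: Path = Path("darkog_out")
    og_format: str = "long"
    e_value_cutoff: float = 1e-5
    min_coverage: float = 0.5
    hdf_e_threshold: float = DEFAULT_E_THRESHOLD
    hdf_db_length: int = 10_000_000
    network: NetworkConfig = field(default_factory=NetworkConfig)
    groups: Optional[Mapping[str, list[str]]] = None
    seed: int = 0

    def validate(self) -> None:
        for name in ("orthogroups", "lineages", "annotation_hits", "species_tree",
                     "bitscores", "representatives", "de_results", "celltype_fc",
                     "homology_hits"):
            path = Path(getattr(self, name))
            if not path.exists():
                raise FileNotFoundError(f"input {name!r} not found: {path}")

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        d["network"] = dataclasses.asdict(self.network)
        payload = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def datasets_in_lca(records: Mapping[str, DatasetRecord], rank: str, taxon: str) -> set[str]:
    """All datasets whose lineage places them inside the (rank, taxon) clade."""
    if rank == "tax_id":
        return {d for d, r in records.items() if str(r.tax_id) == taxon}
    if rank == "root":
        return set(records)
    return {d for d, r in records.items() if r.taxon_at(rank) == taxon}


def default_groups(records: Mapping[str, DatasetRecord]) -> dict[str, list[str]]:
    """Nested Scleractinia/Hexacorallia/Cnidaria groups from lineage values."""
    return {
        "Scleractinia": sorted(d for d, r in records.items()
                               if r.taxon_at("order") == "Scleractinia"),
        "Hexacorallia": sorted(d for d, r in records.items()
                               if r.taxon_at("class") == "Hexacorallia"),
        "Cnidaria": sorted(d for d, r in records.items()
                           if r.taxon_at("phylum") == "Cnidaria"),
    }


def run_hdf_stage(
    ogs, records, tree, obs_df: pd.DataFrame, reps: Mapping[str, str],
    e_threshold: float, db_length: int,
) -> pd.DataFrame:
    """Fit per-family decay models and call HDF over non-LCA datasets."""
    rows = []
    dist_cache: dict[str, dict[str, float]] = {}
    for og in ogs:
        sub = obs_df[obs_df["og_id"] == og.og_id]
        rep_dataset = reps.get(og.og_id)
        if rep_dataset is None or sub.empty:
            continue
        if rep_dataset not in dist_cache:
            dist_cache[rep_dataset] = patristic_distances(tree, rep_dataset)
        dists = dist_cache[rep_dataset]
        obs = [
            BitscoreObservation(
                og_id=og.og_id, dataset_id=r["dataset"],
                distance=dists[r["dataset"]], bitscore=r["bitscore"],
                rep_length=int(r.get("rep_length", 1) or 1),
            )
            for _, r in sub.iterrows()
            if r["bitscore"] > 0
        ]
        distinct_d = {o.distance for o in obs}
        if len(obs) < 3 or len(distinct_d) < 2:
            rows.append({"og_id": og.og_id, "og_call": "ambiguous",
                         "support": 0, "against": 0, "ambiguous": 0,
                         "not_scorable": True})
            continue
        fit = fit_decay(obs)
        rep_length = obs[0].rep_length
        member_datasets = og.member_datasets
        predictions = {
            d: predict_undetected(fit, dists[d], (rep_length, db_length), e_threshold)
            for d in records if d not in member_datasets
        }
        lca_set = datasets_in_lca(records, og.lca_rank or "root", og.lca_taxon or "")
        assessment = assess_og(og, predictions, lca_set)
        rows.append({
            "og_id": og.og_id, "og_call": assessment.og_call.value,
            "support": assessment.support, "against": assessment.against,
            "ambiguous": assessment.ambiguous,
            "not_scorable": assessment.not_scorable,
            "a": fit.a, "b": fit.b, "residual_sd": fit.residual_sd,
        })
    return pd.DataFrame(rows)


def run_all(config: PipelineConfig, force: bool = False) -> dict:
    """Execute every stage and return the machine-readable summary."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    summary_path = out / "summary.json"
    if summary_path.exists() and not force:
        cached = json.loads(summary_path.read_text())
        if cached.get("config_hash") == cfg_hash:
            logger.info("config unchanged (%s); reusing cached summary", cfg_hash)
            return cached

    # --- classify
    ogs = dio.read_orthogroups(config.orthogroups, format=config.og_format)
    records = {r.dataset_id: r for r in
               dio.read_lineages(config.lineages, DEFAULT_RANK_LADDER)}
    hits_by_protein: dict = {}
    for hit in dio.read_annotation_hits(config.annotation_hits):
        hits_by_protein.setdefault(hit.query, []).append(hit)
    protein_calls, og_calls = classify_corpus(
        ogs, hits_by_protein, DarknessConfig(e_value_cutoff=config.e_value_cutoff)
    )
    summary_df = darkness_summary(protein_calls, og_calls)

    # --- LCA
    for og in ogs:
        assign_lca(og, records)

    # --- conserved selection
    group_map = config.groups or default_groups(records)
    groups = LineageGroupSpec.from_dict(group_map)
    conserved = select_conserved_dark(ogs, groups, config.min_coverage)
    per_category = pd.Series(
        [og.conserved_group for og in conserved]
    ).value_counts().to_dict() if conserved else {}

    # --- representatives (from precomputed table)
    reps_df = pd.read_csv(config.representatives, sep="\t")
    reps = {r["og_id"]: r["representative"].split("|", 1)[0]
            for _, r in reps_df.iterrows()}

    # --- HDF on conserved dark families
    tree = dendropy.Tree.get(path=str(config.species_tree), schema="newick")
    obs_df = pd.read_csv(config.bitscores, sep="\t")
    hdf_df = run_hdf_stage(conserved, records, tree, obs_df, reps,
                           config.hdf_e_threshold, config.hdf_db_length)
    hdf_counts = (hdf_df["og_call"].value_counts().to_dict()
                  if not hdf_df.empty else {})

    # --- expression bias
    group_of = {og_id: call.value for og_id, call in og_calls.items()}
    de = pd.read_csv(config.de_results, sep="\t")
    deg = call_degs(de)
    deg = deg.rename(columns={"comparison": "unit"})
    de_table, de_delta = proportion_bias(deg, group_of)
    sc = pd.read_csv(config.celltype_fc, sep="\t")
    sc_sig = call_celltype_expression(sc)
    sc_deltas = {}
    for gran, sub in sc_sig.groupby("granularity"):
        unit_df = sub.rename(columns={"cell_type": "unit"})[["gene", "unit"]]
        _, delta = proportion_bias(unit_df, group_of)
        sc_deltas[gran] = {str(k): (None if pd.isna(v) else float(v))
                           for k, v in delta.items()}

    # --- network
    hit_stream = dio.read_homology_hits(config.homology_hits)
    edges = deduplicate(filter_hits(hit_stream, config.network))
    attrs = (pd.read_csv(config.node_attrs, sep="\t", index_col="og_id")
             if config.node_attrs else None)
    graph = build_graph(edges, attrs)
    net_stats = write_network(graph, out / "network")

    summary = {
        "config_hash": cfg_hash,
        "darkness": summary_df.iloc[0].to_dict(),
        "n_conserved_dark": len(conserved),
        "conserved_per_category": per_category,
        "hdf_calls": hdf_counts,
        "hdf_supported_fraction": (
            hdf_counts.get("hdf_supported", 0) / len(hdf_df) if len(hdf_df) else None
        ),
        "de_delta": {str(k): (None if pd.isna(v) else float(v))
                     for k, v in de_delta.items()},
        "celltype_delta": sc_deltas,
        "network": net_stats,
    }
    summary["darkness"] = {k: (float(v) if isinstance(v, float) else int(v))
                           for k, v in summary["darkness"].items()}
    summary_path.write_text(json.dumps(summary, indent=2, default=float))

    de_table.to_csv(out / "expression_bias.tsv", sep="\t", index=False)
    hdf_df.to_csv(out / "hdf_calls.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"og_id": og.og_id, "category": og.conserved_group,
          "n_datasets": len(og.member_datasets),
          "coverage": og.annotations.get("coverage"),
          "lca_rank": og.lca_rank, "lca_taxon": og.lca_taxon}
         for og in conserved]
    ).to_csv(out / "conserved_dark.tsv", sep="\t", index=False)
    return summary


def format_report(summary: dict) -> str:
    """Human-readable report mirroring the headline result ratios."""
    lines = ["darkog pipeline report", "=" * 22]
    dk = summary["darkness"]
    lines.append(
        f"Proteins: {int(dk['n_proteins'])}  dark: {int(dk['n_dark'])} "
        f"({100 * dk['fraction_dark']:.1f}%)"
    )
    lines.append(
        f"Orthogroups: {int(dk['n_ogs'])}  dark: {int(dk['n_dark_ogs'])}"
    )
    lines.append(f"Conserved dark families: {summary['n_conserved_dark']} "
                 f"({summary['conserved_per_category']})")
    calls = summary["hdf_calls"]
    total = sum(calls.values())
    if total:
        sup = calls.get("hdf_supported", 0)
        rej = calls.get("hdf_rejected", 0)
        lines.append(
            f"HDF: supported {sup}/{total} ({100 * sup / total:.1f}%), "
            f"rejected {rej}/{total} ({100 * rej / total:.1f}%)"
        )
    net = summary["network"]
    lines.append(
        f"Network: {net['n_nodes']} nodes, {net['n_edges']} edges, "
        f"{net['n_components']} components (largest {net['largest_component_size']})"
    )
    return "\n".join(lines)
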