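"""Synthetic corpus generator with planted ground truth.

Generates every input the pipeline consumes — taxonomy and species tree,
orthogroup membership, annotation-hit descriptions, bitscore
observations, expression tables, and a remote-homology hit table — from
a single integer seed, together with truth tables recording what was
planted, so every stage can be tested end to end at desk scale.

The generative model mirrors the analysis assumptions rather than
evolving sequences: a pure-birth species tree with nested
Scleractinia < Hexacorallia < Cnidaria groups plus outgroups; per-family
exponential bitscore decay B(d) = a*exp(-b*d) + Gaussian noise truncated
at zero, with a fast/slow decay-rate regime mix; dataset absence caused
either by gene loss on a branch (recorded as cause "loss") or by the
true bitscore falling below the detection floor (cause "hdf"), which is
what makes fast-decay families apparently lineage-restricted; family
level darkness driving deterministic hit descriptions; planted
cell-type/treatment enrichment probabilities for dark vs light genes;
and a hub-and-burst remote-homology topology (broad light hubs with
narrow dark satellites) with decoy rows straddling the filter
thresholds.

A single seed drives per-stage substreams so stages can be regenerated
independently; identical config + seed gives byte-identical files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from darkog.darkness import AMBIGUOUS_PHRASES
from darkog.hdf import BitscoreObservation, bitscore_floor
from darkog.types import (
    AnnotationHit,
    DatasetRecord,
    HomologyHit,
    Orthogroup,
    ProteinRef,
    SourceKind,
)

_STREAMS = {"tree": 0, "families": 1, "expression": 2, "network": 3}

INFORMATIVE_DESCRIPTIONS = (
    "calmodulin-like protein",
    "green fluorescent protein",
    "carbonic anhydrase 2",
    "galaxin precursor",
    "collagen alpha chain",
    "heat shock protein 70",
    "small cysteine-rich protein",
    "toxin-like peptide",
)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic corpus.

    Defaults give a desk-scale corpus of 40 datasets (12 stony corals
    split equally into Complex/Robust suborders, 10 further hexacorals,
    10 further cnidarians, 8 outgroups) and 2,000 gene families with an
    11.4% dark fraction.
    """

    seed: int = 0
    n_scleractinia: int = 12
    n_other_hexacorallia: int = 10
    n_other_cnidaria: int = 10
    n_outgroup: int = 8
    mean_branch_length: float = 0.15
    n_families: int = 2000
    dark_fraction: float = 0.114
    a_range: tuple[float, float] = (200.0, 400.0)
    b_slow_range: tuple[float, float] = (0.05, 0.2)
    b_fast_range: tuple[float, float] = (1.5, 3.0)
    fast_fraction: float = 0.5
    noise_sd: float = 10.0
    loss_prob: float = 0.05
    rep_length_mean: int = 300
    db_length: int = 10_000_000
    e_threshold: float = 1e-3
    # expression: per-unit probability that a dark / light gene is significant
    comparisons: tuple[str, ...] = ("heat_vs_control_T1", "heat_vs_control_T2",
                                    "pH_vs_control_T1", "pH_vs_control_T2")
    cell_types: tuple[str, ...] = ("calicoblast", "gastrodermis", "epidermis",
                                   "cnidocyte", "neuron")
    enriched_cell_type: str = "calicoblast"
    enrichment: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "calicoblast": {"dark": 0.40, "light": 0.10},
            "default": {"dark": 0.15, "light": 0.15},
        }
    )
    # hub-and-burst network
    n_hubs: int = 3
    satellites_per_hub: int = 10
    n_decoys_per_hub: int = 5

    def __post_init__(self) -> None:
        if not 0.0 <= self.dark_fraction <= 1.0:
            raise ValueError("dark_fraction must be in [0, 1]")
        if not 0.0 <= self.loss_prob <= 1.0:
            raise ValueError("loss_prob must be in [0, 1]")
        if not 0.0 <= self.fast_fraction <= 1.0:
            raise ValueError("fast_fraction must be in [0, 1]")
        if self.mean_branch_length <= 0:
            raise ValueError("mean_branch_length must be > 0")
        for n in (self.n_scleractinia, self.n_other_hexacorallia,
                  self.n_other_cnidaria):
            if n < 2:
                raise ValueError("each lineage group needs >= 2 datasets")


def _rng(cfg: SimConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=cfg.seed, spawn_key=(_STREAMS[stream],))
    )


# ---------------------------------------------------------------------------
# taxonomy and tree


def _join(rng, children, mean_bl):
    """Random binary coalescence of subtree nodes into one node."""
    nodes = list(children)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = dendropy.Node()
        parent.add_child(a)
        parent.add_child(b)
        a.edge.length = float(rng.exponential(mean_bl)) + 0.01
        b.edge.length = float(rng.exponential(mean_bl)) + 0.01
        nodes.append(parent)
    return nodes[0]


def _leaf(label: str):
    node = dendropy.Node()
    node._sim_label = label
    return node


def simulate_taxonomy_and_tree(
    cfg: SimConfig,
) -> tuple[list[DatasetRecord], dendropy.Tree, dict[str, list[str]]]:
    """Pure-birth-style species tree with nested lineage groups.

    Returns dataset records, the tree (taxon labels = dataset ids), and
    the named clade -> dataset-id map used to plant family origins.
    """
    rng = _rng(cfg, "tree")
    n_complex = cfg.n_scleractinia // 2
    complex_ids = [f"coralC{i:02d}" for i in range(n_complex)]
    robust_ids = [f"coralR{i:02d}" for i in range(cfg.n_scleractinia - n_complex)]
    hexa_ids = [f"hexa{i:02d}" for i in range(cfg.n_other_hexacorallia)]
    cnid_ids = [f"cnid{i:02d}" for i in range(cfg.n_other_cnidaria)]
    out_ids = [f"outg{i:02d}" for i in range(cfg.n_outgroup)]

    bl = cfg.mean_branch_length
    sub = {name: _join(rng, [_leaf(x) for x in ids], bl)
           for name, ids in (("complex", complex_ids), ("robust", robust_ids),
                             ("hexa", hexa_ids), ("cnid", cnid_ids),
                             ("out", out_ids))}

    def stem(node, length):
        node.edge.length = length
        return node

    scler = dendropy.Node()
    scler.add_child(stem(sub["complex"], float(rng.exponential(bl)) + 0.05))
    scler.add_child(stem(sub["robust"], float(rng.exponential(bl)) + 0.05))
    hexa = dendropy.Node()
    hexa.add_child(stem(scler, float(rng.exponential(bl)) + 0.1))
    hexa.add_child(stem(sub["hexa"], float(rng.exponential(bl)) + 0.1))
    cnid = dendropy.Node()
    cnid.add_child(stem(hexa, float(rng.exponential(bl)) + 0.15))
    cnid.add_child(stem(sub["cnid"], float(rng.exponential(bl)) + 0.15))
    root = dendropy.Node()
    root.add_child(stem(cnid, float(rng.exponential(bl)) + 0.2))
    root.add_child(stem(sub["out"], float(rng.exponential(bl)) + 0.2))

    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = True
    for leaf in tree.leaf_node_iter():
        leaf.taxon = tns.require_taxon(label=leaf._sim_label)

    scler_ids = complex_ids + robust_ids
    all_hexa = scler_ids + hexa_ids
    all_cnid = all_hexa + cnid_ids
    clades = {
        "Scleractinia": scler_ids,
        "Hexacorallia": all_hexa,
        "Cnidaria": all_cnid,
        "Metazoa": all_cnid + out_ids,
    }

    out_phyla = ["Porifera", "Placozoa", "Ctenophora", "Chordata"]
    records = []
    for i, dataset_id in enumerate(clades["Metazoa"]):
        lineage = {
            "no rank": "cellular organisms",
            "superkingdom": "Eukaryota",
            "kingdom": "Metazoa",
            "species": f"Species {dataset_id}",
            "genus": f"Genus_{dataset_id}",
        }
        if dataset_id in all_cnid:
            lineage["phylum"] = "Cnidaria"
            if dataset_id in all_hexa:
                lineage["class"] = "Hexacorallia"
                if dataset_id in scler_ids:
                    lineage["order"] = "Scleractinia"
                    lineage["suborder"] = ("Complex" if dataset_id in complex_ids
                                           else "Robust")
                    lineage["family"] = ("Acroporidae" if dataset_id in complex_ids
                                         else "Pocilloporidae")
                else:
                    lineage["order"] = "Actiniaria"
            else:
                lineage["class"] = "Hydrozoa"
                lineage["order"] = "Anthoathecata"
        else:
            lineage["phylum"] = out_phyla[i % len(out_phyla)]
        kind = SourceKind.genome if i % 3 else SourceKind.transcriptome
        records.append(
            DatasetRecord(dataset_id=dataset_id, tax_id=100000 + i,
                          lineage=lineage, source_kind=kind)
        )
    return records, tree, clades


def patristic_matrix(tree: dendropy.Tree) -> dict[str, dict[str, float]]:
    """Dense symmetric patristic distance lookup keyed by taxon label."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = list(tree.taxon_namespace)
    out: dict[str, dict[str, float]] = {t.label: {} for t in taxa}
    for t1 in taxa:
        for t2 in taxa:
            out[t1.label][t2.label] = (
                0.0 if t1 is t2 else float(pdm.patristic_distance(t1, t2))
            )
    return out


# ---------------------------------------------------------------------------
# families


@dataclass
class SimulatedFamily:
    og: Orthogroup
    dark: bool
    regime: str  # "fast" | "slow"
    a: float
    b: float
    origin_clade: str
    absent: dict[str, str]  # dataset -> cause ("loss" | "hdf")
    observations: list[BitscoreObservation]


def _survivors(tree: dendropy.Tree, clade_datasets: set[str],
               loss_prob: float, rng) -> set[str]:
    """Per-branch gene loss below the clade's MRCA; a lost edge removes
    the whole subtree under it."""
    taxa = [t for t in tree.taxon_namespace if t.label in clade_datasets]
    if len(taxa) == 1:
        return clade_datasets
    mrca = tree.mrca(taxa=taxa)
    surviving: set[str] = set()

    def walk(node):
        for child in node.child_nodes():
            if rng.random() < loss_prob:
                continue
            if child.is_leaf():
                if child.taxon.label in clade_datasets:
                    surviving.add(child.taxon.label)
            else:
                walk(child)

    walk(mrca)
    return surviving


def simulate_families(
    cfg: SimConfig,
    tree: dendropy.Tree,
    clades: Mapping[str, Sequence[str]],
    distances: Optional[dict[str, dict[str, float]]] = None,
) -> tuple[list[SimulatedFamily], dict[ProteinRef, list[AnnotationHit]], pd.DataFrame]:
    """Plant gene families on the tree with decay-driven membership.

    For each family: sample an origin clade, a darkness label, a decay
    regime and parameters (a, b); drop datasets by per-branch loss
    (cause "loss"); compute each remaining dataset's true bitscore
    against the representative and drop those below the detection floor
    (cause "hdf"); emit one member protein per surviving dataset, hit
    descriptions deterministic in the darkness label, and the truth table.
    """
    rng = _rng(cfg, "families")
    if distances is None:
        distances = patristic_matrix(tree)
    clade_names = ["Scleractinia", "Hexacorallia", "Cnidaria", "Metazoa"]
    clade_weights = np.array([0.35, 0.30, 0.25, 0.10])
    all_datasets = list(clades["Metazoa"])

    families: list[SimulatedFamily] = []
    hits: dict[ProteinRef, list[AnnotationHit]] = {}
    truth_rows = []
    for fam_idx in range(cfg.n_families):
        og_id = f"OG{fam_idx:06d}"
        origin = clade_names[rng.choice(len(clade_names), p=clade_weights)]
        clade_set = set(clades[origin])
        dark = bool(rng.random() < cfg.dark_fraction)
        fast = bool(rng.random() < cfg.fast_fraction)
        b = float(rng.uniform(*(cfg.b_fast_range if fast else cfg.b_slow_range)))
        a = float(rng.uniform(*cfg.a_range))
        rep_length = int(max(50, rng.normal(cfg.rep_length_mean, 50)))
        floor = bitscore_floor(rep_length, cfg.db_length, cfg.e_threshold)

        present = _survivors(tree, clade_set, cfg.loss_prob, rng)
        absent = {d: "loss" for d in clade_set - present}
        if not present:
            present = set(clade_set)
            absent = {}
        rep_dataset = sorted(present)[int(rng.integers(len(present)))]

        members: list[ProteinRef] = []
        observations: list[BitscoreObservation] = []
        for dataset in sorted(present):
            d = distances[rep_dataset][dataset]
            score = a * np.exp(-b * d) + rng.normal(0.0, cfg.noise_sd)
            score = max(score, 0.0)
            if dataset != rep_dataset and score < floor:
                absent[dataset] = "hdf"
                continue
            ref = ProteinRef(dataset_id=dataset,
                             protein_id=f"{og_id}.{dataset}.p1",
                             length=rep_length)
            members.append(ref)
            observations.append(
                BitscoreObservation(
                    og_id=og_id, dataset_id=dataset,
                    distance=d, bitscore=max(score, 0.01),
                    rep_length=rep_length,
                )
            )
        rep_ref = next(m for m in members if m.dataset_id == rep_dataset)
        og = Orthogroup(og_id=og_id, members=frozenset(members),
                        representative=rep_ref)

        for k, member in enumerate(sorted(members)):
            member_hits = []
            if dark:
                n_hits = int(rng.integers(1, 3))
                for h in range(n_hits):
                    phrase = AMBIGUOUS_PHRASES[int(rng.integers(len(AMBIGUOUS_PHRASES)))]
                    member_hits.append(
                        AnnotationHit(
                            query=member, subject_id=f"nr{fam_idx:06d}_{k}_{h}",
                            e_value=float(10.0 ** rng.uniform(-30, -6)),
                            bitscore=float(rng.uniform(60, 200)),
                            description=f"{phrase} {og_id}",
                        )
                    )
            else:
                desc = INFORMATIVE_DESCRIPTIONS[fam_idx % len(INFORMATIVE_DESCRIPTIONS)]
                member_hits.append(
                    AnnotationHit(
                        query=member, subject_id=f"nr{fam_idx:06d}_{k}_0",
                        e_value=float(10.0 ** rng.uniform(-30, -6)),
                        bitscore=float(rng.uniform(60, 200)),
                        description=desc,
                    )
                )
            hits[member] = member_hits

        fam = SimulatedFamily(
            og=og, dark=dark, regime="fast" if fast else "slow",
            a=a, b=b, origin_clade=origin, absent=absent,
            observations=observations,
        )
        families.append(fam)
        truth_rows.append(
            {
                "og_id": og_id, "dark": dark, "regime": fam.regime,
                "a": a, "b": b, "origin_clade": origin,
                "rep_dataset": rep_dataset, "rep_length": rep_length,
                "n_members": len(members),
                "n_absent_loss": sum(1 for c in absent.values() if c == "loss"),
                "n_absent_hdf": sum(1 for c in absent.values() if c == "hdf"),
            }
        )
    truth = pd.DataFrame(truth_rows).set_index("og_id")
    return families, hits, truth


# ---------------------------------------------------------------------------
# expression


def simulate_expression(
    cfg: SimConfig, truth: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """DE table, cell-type FC table, intensity matrix and design.

    Genes are the families of the focal species; per unit, a gene is
    significant with its group's planted probability.  Significant DE
    rows draw |log2FC| > 0.5 with p_adj < 0.05; non-significant rows fail
    at least one rule.  Cell-type FCs straddle the 2.0 cutoff.
    """
    rng = _rng(cfg, "expression")
    genes = list(truth.index)
    groups = np.where(truth["dark"].to_numpy(), "dark", "light")

    def unit_prob(unit: str, group: str) -> float:
        spec = cfg.enrichment.get(unit, cfg.enrichment["default"])
        return spec[group]

    de_rows = []
    for gene, group in zip(genes, groups):
        for comp in cfg.comparisons:
            sig = rng.random() < unit_prob(comp, group)
            if sig:
                lfc = float(rng.choice([-1, 1]) * (0.5 + rng.exponential(1.0) + 1e-6))
                padj = float(rng.uniform(0.0, 0.049))
            else:
                if rng.random() < 0.5:
                    lfc = float(rng.uniform(-0.5, 0.5))
                    padj = float(rng.uniform(0.0, 1.0))
                else:
                    lfc = float(rng.choice([-1, 1]) * (0.5 + rng.exponential(1.0)))
                    padj = float(rng.uniform(0.05, 1.0))
            de_rows.append({"gene": gene, "comparison": comp,
                            "log2_fc": lfc, "p_adj": padj})
    de = pd.DataFrame(de_rows)

    sc_rows = []
    for gene, group in zip(genes, groups):
        for ct in cfg.cell_types:
            for gran in ("broadcell", "cell", "metacell"):
                sig = rng.random() < unit_prob(ct, group)
                fc = float(rng.uniform(2.0 + 1e-6, 8.0)) if sig else float(rng.uniform(0.0, 2.0))
                sc_rows.append({"gene": gene, "granularity": gran,
                                "cell_type": ct, "fc": fc})
    sc = pd.DataFrame(sc_rows)

    n_prot = min(200, len(genes))
    prot_genes = genes[:n_prot]
    samples, design_rows = [], []
    for tp in ("T1", "T2"):
        for arm in ("control", "treatment"):
            for rep in range(3):
                s = f"{arm}_{tp}_r{rep}"
                samples.append(s)
                design_rows.append({"sample": s, "arm": arm, "time_point": tp})
    design = pd.DataFrame(design_rows)
    base = rng.lognormal(mean=10.0, sigma=0.5, size=n_prot)
    shifted = rng.random(n_prot) < 0.2
    data = np.empty((n_prot, len(samples)))
    for j, row in design.iterrows():
        mult = np.where(shifted & (row["arm"] == "treatment"), 2.0, 1.0)
        data[:, j] = base * mult * rng.lognormal(mean=0.0, sigma=0.05, size=n_prot)
    intensities = pd.DataFrame(data, index=prot_genes, columns=samples)
    return de, sc, intensities, design


# ---------------------------------------------------------------------------
# remote homology network


def simulate_remote_homology(
    cfg: SimConfig,
) -> tuple[list[HomologyHit], pd.DataFrame, pd.DataFrame]:
    """Hub-and-burst hit table with decoy sub-threshold rows.

    Each planted hub (broad-LCA, light) is connected to its satellites
    (narrow-LCA, dark) with probabilities/coverages above the filter
    thresholds; forward/reverse duplicates exercise deduplication, and
    decoy rows below the probability or coverage thresholds (including
    cross-hub decoys that would otherwise merge components) must never
    survive filtering.  Returns hits, a node-attribute table, and the
    truth component table.
    """
    rng = _rng(cfg, "network")
    hits: list[HomologyHit] = []
    attr_rows, truth_rows = [], []

    def make_hit(q, t, prob, q_cov, t_cov, score):
        q_len = int(rng.integers(150, 400))
        t_len = int(rng.integers(150, 400))
        q_aln = max(1, int(round(q_cov * q_len)))
        t_aln = max(1, int(round(t_cov * t_len)))
        q_start = int(rng.integers(1, q_len - q_aln + 2))
        t_start = int(rng.integers(1, t_len - t_aln + 2))
        return HomologyHit(
            query_og=q, target_og=t, probability=prob,
            e_value=float(10.0 ** rng.uniform(-30, -3)), score=score,
            q_start=q_start, q_end=q_start + q_aln - 1,
            t_start=t_start, t_end=t_start + t_aln - 1,
            aln_len=max(q_aln, t_aln), q_len=q_len, t_len=t_len,
        )

    for h in range(cfg.n_hubs):
        hub = f"HUB{h:03d}"
        attr_rows.append({"og_id": hub, "darkness": "light",
                          "lca_rank": "kingdom", "lca_taxon": "Metazoa"})
        truth_rows.append({"og_id": hub, "component": h})
        sats = [f"SAT{h:03d}_{s:02d}" for s in range(cfg.satellites_per_hub)]
        for sat in sats:
            attr_rows.append({"og_id": sat, "darkness": "dark",
                              "lca_rank": "species", "lca_taxon": f"Species {sat}"})
            truth_rows.append({"og_id": sat, "component": h})
            score = float(rng.uniform(100, 300))
            hits.append(make_hit(hub, sat, float(rng.uniform(90, 100)),
                                 float(rng.uniform(0.65, 0.95)),
                                 float(rng.uniform(0.65, 0.95)), score))
            # redundant reverse hit with a lower normalized score
            hits.append(make_hit(sat, hub, float(rng.uniform(60, 90)),
                                 float(rng.uniform(0.65, 0.95)),
                                 float(rng.uniform(0.65, 0.95)), score * 0.5))
        # self-hit decoy
        hits.append(make_hit(hub, hub, 99.0, 0.9, 0.9, 500.0))
        # decoys: below probability or coverage thresholds; cross-hub rows
        other_hub = f"HUB{(h + 1) % cfg.n_hubs:03d}"
        for _ in range(cfg.n_decoys_per_hub):
            kind = rng.integers(3)
            if kind == 0:
                hits.append(make_hit(sats[0], other_hub,
                                     float(rng.uniform(0, 49.9)),
                                     0.8, 0.8, float(rng.uniform(50, 100))))
            elif kind == 1:
                hits.append(make_hit(sats[1], other_hub, 95.0,
                                     float(rng.uniform(0.1, 0.59)),
                                     0.8, float(rng.uniform(50, 100))))
            else:
                hits.append(make_hit(sats[2], other_hub, 95.0, 0.8,
                                     float(rng.uniform(0.1, 0.59)),
                                     float(rng.uniform(50, 100))))
    attrs = pd.DataFrame(attr_rows).set_index("og_id")
    truth = pd.DataFrame(truth_rows).set_index("og_id")
    return hits, attrs, truth


# ---------------------------------------------------------------------------
# corpus


@dataclass
class SimulatedCorpus:
    config: SimConfig
    records: list[DatasetRecord]
    tree: dendropy.Tree
    clades: dict[str, list[str]]
    distances: dict[str, dict[str, float]]
    families: list[SimulatedFamily]
    annotation_hits: dict[ProteinRef, list[AnnotationHit]]
    family_truth: pd.DataFrame
    de_table: pd.DataFrame
    celltype_table: pd.DataFrame
    intensities: pd.DataFrame
    design: pd.DataFrame
    homology_hits: list[HomologyHit]
    node_attrs: pd.DataFrame
    network_truth: pd.DataFrame

    @property
    def orthogroups(self) -> list[Orthogroup]:
        return [f.og for f in self.families]

    def newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True)

    def write(self, out_dir) -> None:
        """Write every pipeline input format plus truth tables."""
        from darkog import io as dio
        from darkog.lineage import DEFAULT_RANK_LADDER

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        dio.write_orthogroups(self.orthogroups, out / "orthogroups.tsv")
        dio.write_lineages(self.records, out / "lineages.csv", DEFAULT_RANK_LADDER)
        (out / "species_tree.nwk").write_text(self.newick())
        with (out / "annotation_hits.tsv").open("w") as fh:
            fh.write("dataset_id\tprotein_id\tsubject_id\tevalue\tbitscore\tdescription\n")
            for ref in sorted(self.annotation_hits):
                for h in self.annotation_hits[ref]:
                    fh.write(
                        f"{ref.dataset_id}\t{ref.protein_id}\t{h.subject_id}\t"
                        f"{h.e_value:.6g}\t{h.bitscore:.6g}\t{h.description}\n"
                    )
        obs_rows = [
            {"og_id": o.og_id, "dataset": o.dataset_id, "distance": o.distance,
             "bitscore": o.bitscore, "rep_length": o.rep_length}
            for fam in self.families for o in fam.observations
        ]
        pd.DataFrame(obs_rows).to_csv(out / "bitscores.tsv", sep="\t", index=False)
        reps = pd.DataFrame(
            [{"og_id": f.og.og_id, "representative": f.og.representative.token}
             for f in self.families]
        )
        reps.to_csv(out / "representatives.tsv", sep="\t", index=False)
        self.family_truth.to_csv(out / "truth_families.tsv", sep="\t")
        self.de_table.to_csv(out / "de_results.tsv", sep="\t", index=False)
        self.celltype_table.to_csv(out / "celltype_fc.tsv", sep="\t", index=False)
        self.intensities.to_csv(out / "intensities.tsv", sep="\t")
        self.design.to_csv(out / "design.csv", index=False)
        dio.write_homology_hits(self.homology_hits, out / "remote_homology_hits.tsv")
        self.node_attrs.to_csv(out / "node_attrs.tsv", sep="\t")
        self.network_truth.to_csv(out / "truth_network.tsv", sep="\t")
        cfgdict = dataclasses.asdict(self.config)
        cfgdict["enrichment"] = {k: dict(v) for k, v in self.config.enrichment.items()}
        (out / "sim_config.json").write_text(pd.Series(cfgdict).to_json(indent=2))


def simulate_corpus(cfg: SimConfig = SimConfig()) -> SimulatedCorpus:
    """Generate the full synthetic corpus for one seed."""
    records, tree, clades = simulate_taxonomy_and_tree(cfg)
    distances = patristic_matrix(tree)
    families, ann_hits, truth = simulate_families(cfg, tree, clades, distances)
    de, sc, intensities, design = simulate_expression(cfg, truth)
    hh_hits, attrs, net_truth = simulate_remote_homology(cfg)
    return SimulatedCorpus(
        config=cfg, records=records, tree=tree,
        clades={k: list(v) for k, v in clades.items()},
        distances=distances, families=families,
        annotation_hits=ann_hits, family_truth=truth,
        de_table=de, celltype_table=sc,
        intensities=intensities, design=design,
        homology_hits=hh_hits, node_attrs=attrs, network_truth=net_truth,
    )


def simulate_protein_hits(
    labels: Mapping[ProteinRef, bool], rng: np.random.Generator
) -> dict[ProteinRef, list[AnnotationHit]]:
    """IID per-protein annotation hits for planted dark (True) labels."""
    out: dict[ProteinRef, list[AnnotationHit]] = {}
    for ref, dark in labels.items():
        if dark:
            phrase = AMBIGUOUS_PHRASES[int(rng.integers(len(AMBIGUOUS_PHRASES)))]
            desc = f"{phrase}, partial"
        else:
            desc = INFORMATIVE_DESCRIPTIONS[int(rng.integers(len(INFORMATIVE_DESCRIPTIONS)))]
        out[ref] = [
            AnnotationHit(query=ref, subject_id=f"s_{ref.protein_id}",
                          e_value=float(10.0 ** rng.uniform(-20, -6)),
                          bitscore=float(rng.uniform(60, 200)),
                          description=desc)
        ]
    return out
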