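"""LCA assignment, conserved-family selection, representative choice."""

import pytest

from darkog.lineage import (
    DEFAULT_RANK_LADDER,
    ROOT_SENTINEL,
    LineageGroupSpec,
    assign_lca,
    greedy_centroid_votes,
    pick_representative,
    select_conserved_dark,
    validate_ladder,
)
from darkog.types import Darkness, DatasetRecord, Orthogroup, ProteinRef

from conftest import lca_oracle


def rec(dataset_id, tax_id, **lineage):
    lineage.setdefault("no rank", "cellular organisms")
    return DatasetRecord(dataset_id=dataset_id, tax_id=tax_id, lineage=lineage)


def og_of(og_id, *datasets):
    return Orthogroup(og_id, frozenset(ProteinRef(d, f"{d}_p") for d in datasets))


CORAL_R = rec("coralR", 1, superkingdom="Eukaryota", kingdom="Metazoa",
              phylum="Cnidaria", **{"class": "Hexacorallia"},
              order="Scleractinia", suborder="Robust",
              genus="Pocillopora", species="P acuta")
CORAL_C = rec("coralC", 2, superkingdom="Eukaryota", kingdom="Metazoa",
              phylum="Cnidaria", **{"class": "Hexacorallia"},
              order="Scleractinia", suborder="Complex",
              genus="Montipora", species="M capitata")
SPONGE = rec("sponge", 3, superkingdom="Eukaryota", kingdom="Metazoa",
             phylum="Porifera", genus="Stylissa", species="S carteri")
RECORDS = {r.dataset_id: r for r in (CORAL_R, CORAL_C, SPONGE)}


class TestAssignLca:
    def test_single_dataset_resolves_to_tax_id(self):
        og = og_of("OG1", "coralR")
        assert assign_lca(og, RECORDS) == ("tax_id", "1")

    def test_robust_plus_complex_resolves_above_suborder(self):
        """Two stony corals from opposite suborders meet at the order."""
        og = og_of("OG1", "coralR", "coralC")
        assert assign_lca(og, RECORDS) == ("order", "Scleractinia")

    def test_coral_plus_sponge_resolves_at_kingdom(self):
        og = og_of("OG1", "coralR", "sponge")
        assert assign_lca(og, RECORDS) == ("kingdom", "Metazoa")

    def test_missing_rank_skipped_not_blocking(self):
        # sponge lacks order/class; a coral+sponge OG must not stall there
        og = og_of("OG1", "coralC", "sponge")
        rank, taxon = assign_lca(og, RECORDS)
        assert (rank, taxon) == ("kingdom", "Metazoa")

    def test_no_shared_rank_returns_flagged_sentinel(self):
        a = rec("a", 1, kingdom="Metazoa")
        b = DatasetRecord("b", 2, {"kingdom": "Viridiplantae"})
        og = og_of("OG1", "a", "b")
        assert assign_lca(og, {"a": a, "b": b}) == ROOT_SENTINEL
        assert og.annotations.get("lca_unresolved")

    def test_missing_record_is_error(self):
        with pytest.raises(KeyError):
            assign_lca(og_of("OG1", "nope"), RECORDS)

    def test_duplicate_rank_in_ladder_rejected(self):
        with pytest.raises(ValueError):
            validate_ladder(("species", "genus", "species"))

    def test_matches_bruteforce_on_random_taxonomies(self, rng):
        """assign_lca equals the rank-scan oracle on random lineage tables."""
        for trial in range(100):
            n = int(rng.integers(2, 10))
            records = {}
            for i in range(n):
                lineage = {}
                for depth, rank in enumerate(DEFAULT_RANK_LADDER[1:], start=1):
                    if rng.random() < 0.75:
                        breadth = max(1, 12 - depth)
                        lineage[rank] = f"{rank}_{rng.integers(breadth)}"
                records[f"d{i}"] = DatasetRecord(f"d{i}", int(rng.integers(1, 6)),
                                                 lineage)
            datasets = sorted(rng.choice(list(records), size=int(rng.integers(1, n + 1)),
                                         replace=False))
            og = og_of(f"T{trial}", *datasets)
            assert assign_lca(og, records) == lca_oracle(datasets, records,
                                                         DEFAULT_RANK_LADDER)


class TestSelectConservedDark:
    def make(self, n_members, dark=True, prefix="s"):
        og = og_of("OGx", *[f"{prefix}{i}" for i in range(n_members)])
        og.darkness = Darkness.dark if dark else Darkness.light
        return og

    def groups(self, n_scler=118, n_hexa=140, n_cnid=160):
        scler = [f"s{i}" for i in range(n_scler)]
        hexa = scler + [f"h{i}" for i in range(n_hexa - n_scler)]
        cnid = hexa + [f"c{i}" for i in range(n_cnid - n_hexa)]
        return LineageGroupSpec.from_dict(
            {"Scleractinia": scler, "Hexacorallia": hexa, "Cnidaria": cnid}
        )

    def test_half_coverage_is_inclusive(self):
        # 59 of 118 datasets is exactly 50% and qualifies
        og = self.make(59)
        sel = select_conserved_dark([og], self.groups())
        assert sel == [og] and og.conserved_group == "Scleractinia"

    def test_just_below_half_rejected(self):
        assert select_conserved_dark([self.make(58)], self.groups()) == []

    def test_outside_member_disqualifies(self):
        og = og_of("OGx", *[f"s{i}" for i in range(100)], "bilaterian")
        og.darkness = Darkness.dark
        assert select_conserved_dark([og], self.groups()) == []

    def test_light_og_never_selected(self):
        assert select_conserved_dark([self.make(118, dark=False)],
                                     self.groups()) == []

    def test_category_is_narrowest_group(self):
        """An OG of corals + other hexacorals is Hexacorallia, not Cnidaria,
        and the categories partition the selected set."""
        g = self.groups(n_scler=4, n_hexa=8, n_cnid=12)
        og = og_of("OGx", "s0", "s1", "s2", "h0", "h1")
        og.darkness = Darkness.dark
        sel = select_conserved_dark([og], g, min_coverage=0.5)
        assert sel and og.conserved_group == "Hexacorallia"

    def test_non_nested_groups_rejected(self):
        with pytest.raises(ValueError, match="nested"):
            LineageGroupSpec.from_dict({"A": ["x"], "B": ["y"]})

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            LineageGroupSpec.from_dict({"A": []})


class TestPickRepresentative:
    def refs(self, *names):
        return [ProteinRef("ds", n) for n in names]

    def test_vote_tie_breaks_lexicographically_with_annotation(self):
        a, b, c = self.refs("A", "B", "C")
        og = Orthogroup("OG1", frozenset([a, b, c]))
        votes = {a: 3, b: 3, c: 1}
        assert pick_representative(og, votes=votes) == a
        assert og.annotations["representative_ties"] == ["ds|A", "ds|B"]

    def test_max_votes_wins(self):
        a, b = self.refs("A", "B")
        og = Orthogroup("OG1", frozenset([a, b]))
        assert pick_representative(og, votes={b: 5, a: 1}) == b

    def test_singleton_is_its_own_representative(self):
        (a,) = self.refs("only")
        og = Orthogroup("OG1", frozenset([a]))
        assert pick_representative(og) == a

    def test_greedy_clustering_votes_prefer_central_sequence(self):
        # A scores high against everyone; B and C only against A
        a, b, c = self.refs("A", "B", "C")
        scores = {(a, b): 90.0, (a, c): 85.0, (b, c): 10.0}
        votes = greedy_centroid_votes([a, b, c], scores, threshold=50.0)
        assert votes[a] == 3 and votes[b] == 0 and votes[c] == 0
        og = Orthogroup("OG1", frozenset([a, b, c]))
        assert pick_representative(og, scores=scores) == a

    def test_needs_votes_or_scores(self):
        a, b = self.refs("A", "B")
        og = Orthogroup("OG1", frozenset([a, b]))
        with pytest.raises(ValueError):
            pick_representative(og)
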