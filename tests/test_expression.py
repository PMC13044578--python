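"""Expression significance rules, RBH mapping, proportion-bias statistics."""

import numpy as np
import pandas as pd
import pytest

from darkog.expression import (
    call_celltype_expression,
    call_degs,
    call_differential_proteins,
    filter_low_expression,
    map_ids_rbh,
    proportion_bias,
    welch_t,
)


class TestFilterLowExpression:
    def mat(self, row, n_samples=20):
        return pd.DataFrame([row * (n_samples // len(row))], index=["g1"])

    def test_above_fraction_kept(self):
        # counts > 10 in 3 of 20 samples: 0.15 > 0.10 -> kept
        counts = pd.DataFrame([[50] * 3 + [0] * 17], index=["g1"])
        assert list(filter_low_expression(counts)) == ["g1"]

    def test_exact_fraction_removed(self):
        # counts > 10 in exactly 2 of 20 samples (0.10) -> removed (strict)
        counts = pd.DataFrame([[50] * 2 + [0] * 18], index=["g1"])
        assert list(filter_low_expression(counts)) == []

    def test_count_threshold_strict(self):
        # a count of exactly 10 does not pass "count > 10"
        counts = pd.DataFrame([[10] * 20], index=["g1"])
        assert list(filter_low_expression(counts)) == []

    def test_all_zero_removed(self):
        counts = pd.DataFrame([[0] * 20], index=["g1"])
        assert list(filter_low_expression(counts)) == []

    def test_zero_samples_is_error(self):
        with pytest.raises(ValueError):
            filter_low_expression(pd.DataFrame(index=["g1"]))


class TestCallDegs:
    def de(self, lfc, padj, gene="g1", comparison="c1"):
        return pd.DataFrame([{"gene": gene, "comparison": comparison,
                              "log2_fc": lfc, "p_adj": padj}])

    def test_significant(self):
        assert len(call_degs(self.de(0.6, 0.01))) == 1

    def test_lfc_boundary_strict(self):
        assert len(call_degs(self.de(0.5, 0.001))) == 0

    def test_padj_boundary_strict(self):
        assert len(call_degs(self.de(1.0, 0.05))) == 0

    def test_negative_lfc_uses_absolute_value(self):
        assert len(call_degs(self.de(-0.8, 0.04))) == 1

    def test_missing_padj_skipped_with_warning(self, caplog):
        df = pd.concat([self.de(1.0, np.nan), self.de(1.0, 0.01, gene="g2")])
        with caplog.at_level("WARNING"):
            out = call_degs(df)
        assert list(out["gene"]) == ["g2"]


class TestDifferentialProteins:
    def run(self, control, treatment):
        samples = [f"c{i}" for i in range(len(control))] + \
                  [f"t{i}" for i in range(len(treatment))]
        intens = pd.DataFrame([list(control) + list(treatment)],
                              index=["p1"], columns=samples)
        design = pd.DataFrame(
            [{"sample": s, "arm": "control", "time_point": "T1"}
             for s in samples[:len(control)]]
            + [{"sample": s, "arm": "treatment", "time_point": "T1"}
               for s in samples[len(control):]]
        )
        return call_differential_proteins(intens, design).iloc[0]

    def test_clear_shift_significant(self):
        """(10,10,10) vs (40,40,40): log2 FC = 2, degenerate-variance p=0."""
        row = self.run((10, 10, 10), (40, 40, 40))
        assert row.fc == pytest.approx(2.0)
        assert row.p_value == 0.0 and row.significant

    def test_identical_arms_not_significant(self):
        row = self.run((10, 10, 10), (10, 10, 10))
        assert row.fc == 0.0 and row.p_value == 1.0 and not row.significant

    def test_fc_boundary_strict(self):
        """A log2 fold change of exactly 0.5 fails the strict rule even at
        tiny p, and a slightly smaller shift is likewise not significant."""
        from darkog.expression import is_differential

        assert not is_differential(0.5, 1e-9)
        assert not is_differential(-0.5, 1e-9)
        assert is_differential(0.5 + 1e-9, 1e-9)
        control = (100, 101, 99, 100)
        treatment = tuple(x * 2**0.49 for x in control)
        row = self.run(control, treatment)
        assert row.fc == pytest.approx(0.49, abs=1e-6)
        assert row.p_value < 0.05 and not row.significant

    def test_welch_matches_closed_form(self, rng):
        """welch_t agrees with the textbook statistic on random draws."""
        from scipy import stats as ss

        x = rng.normal(10, 2, 5)
        y = rng.normal(12, 3, 7)
        assert welch_t(x, y) == pytest.approx(
            ss.ttest_ind(y, x, equal_var=False).pvalue)

    def test_single_replicate_is_error(self):
        with pytest.raises(ValueError, match="replicates"):
            self.run((10,), (40, 41))


class TestCelltypeCalls:
    def fc_table(self, fc, gran="metacell"):
        return pd.DataFrame([{"gene": "g1", "granularity": gran,
                              "cell_type": "calicoblast", "fc": fc}])

    def test_above_cutoff_significant(self):
        assert len(call_celltype_expression(self.fc_table(2.5))) == 1

    def test_exactly_two_not_significant(self):
        assert len(call_celltype_expression(self.fc_table(2.0))) == 0

    def test_zero_not_significant(self):
        assert len(call_celltype_expression(self.fc_table(0.0))) == 0

    def test_negative_fc_is_error(self):
        with pytest.raises(ValueError, match="non-negative"):
            call_celltype_expression(self.fc_table(-1.0))

    def test_unknown_granularity_is_error(self):
        with pytest.raises(ValueError, match="granularity"):
            call_celltype_expression(self.fc_table(3.0, gran="supercell"))


def hit_row(q, s, bits, qlen=100, slen=100, qa=1, qb=80, sa=1, sb=80):
    return {"query": q, "subject": s, "bitscore": bits, "qstart": qa,
            "qend": qb, "qlen": qlen, "sstart": sa, "send": sb, "slen": slen}


class TestRbhMapping:
    def test_toy_reciprocal_pair_found(self):
        """Brute-force enumeration of a 3x3 toy: only (a1, b1) is mutual."""
        ab = pd.DataFrame([hit_row("a1", "b1", 200), hit_row("a1", "b2", 100),
                           hit_row("a2", "b2", 90), hit_row("a3", "b3", 50)])
        ba = pd.DataFrame([hit_row("b1", "a1", 190), hit_row("b2", "a1", 120),
                           hit_row("b3", "a2", 60)])
        assert map_ids_rbh(ab, ba) == {"a1": "b1"}

    def test_coverage_exactly_sixty_percent_excluded(self):
        ab = pd.DataFrame([hit_row("a1", "b1", 200, qa=1, qb=60, sa=1, sb=60)])
        ba = pd.DataFrame([hit_row("b1", "a1", 190, qa=1, qb=60, sa=1, sb=60)])
        assert map_ids_rbh(ab, ba) == {}

    def test_or_semantics_one_side_passing_suffices(self):
        ab = pd.DataFrame([hit_row("a1", "b1", 200, qa=1, qb=61, sa=1, sb=30)])
        ba = pd.DataFrame([hit_row("b1", "a1", 190)])
        assert map_ids_rbh(ab, ba) == {"a1": "b1"}
        assert map_ids_rbh(ab, ba, coverage_mode="and") == {}

    def test_one_directional_best_excluded(self):
        ab = pd.DataFrame([hit_row("a1", "b1", 200)])
        ba = pd.DataFrame([hit_row("b1", "a2", 300), hit_row("b1", "a1", 100)])
        assert map_ids_rbh(ab, ba) == {}

    def test_tied_best_hits_dropped(self, caplog):
        ab = pd.DataFrame([hit_row("a1", "b1", 200), hit_row("a1", "b2", 200)])
        ba = pd.DataFrame([hit_row("b1", "a1", 190)])
        with caplog.at_level("WARNING"):
            assert map_ids_rbh(ab, ba) == {}

    def test_symmetric_under_table_swap(self, rng):
        """Swapping the two hit tables yields the inverse map."""
        a_ids = [f"a{i}" for i in range(6)]
        b_ids = [f"b{i}" for i in range(6)]
        ab_rows, ba_rows = [], []
        for a in a_ids:
            for b in b_ids:
                bits = float(rng.integers(10, 500))
                ab_rows.append(hit_row(a, b, bits))
                ba_rows.append(hit_row(b, a, bits))
        ab, ba = pd.DataFrame(ab_rows), pd.DataFrame(ba_rows)
        fwd = map_ids_rbh(ab, ba)
        rev = map_ids_rbh(ba, ab)
        assert rev == {v: k for k, v in fwd.items()}


class TestProportionBias:
    def test_hand_enumeration(self):
        """Dark g1 sig in c1; dark g2 sig in c1 and c2: denominators count
        genes once, so prop_dark(c1)=1.0 and prop_dark(c2)=0.5."""
        sig = pd.DataFrame([{"gene": "g1", "unit": "c1"},
                            {"gene": "g2", "unit": "c1"},
                            {"gene": "g2", "unit": "c2"},
                            {"gene": "L1", "unit": "c1"}])
        group_of = {"g1": "dark", "g2": "dark", "L1": "light"}
        table, delta = proportion_bias(sig, group_of)
        dark = table[table.group == "dark"].set_index("unit")
        assert dark.loc["c1"].proportion == 1.0
        assert dark.loc["c2"].proportion == 0.5
        assert dark.loc["c1"].denominator == 2
        assert delta["c1"] == pytest.approx(0.0)  # light also 1.0 in c1
        assert delta["c2"] == pytest.approx(0.5)  # light absent from c2

    def test_no_light_genes_gives_missing_proportions(self):
        sig = pd.DataFrame([{"gene": "g1", "unit": "c1"}])
        table, delta = proportion_bias(sig, {"g1": "dark"})
        light = table[table.group == "light"]
        assert light.proportion.isna().all()
        assert np.isnan(delta["c1"])

    def test_proportions_need_not_sum_to_one_across_units(self):
        """A gene significant in k units adds to k numerators but one
        denominator, so per-unit proportions can sum past 1."""
        sig = pd.DataFrame([{"gene": "g1", "unit": u} for u in "abc"])
        table, _ = proportion_bias(sig, {"g1": "dark"})
        dark = table[table.group == "dark"]
        assert dark.proportion.sum() == pytest.approx(3.0)

    def test_ungrouped_gene_is_error(self):
        sig = pd.DataFrame([{"gene": "g1", "unit": "c1"}])
        with pytest.raises(KeyError):
            proportion_bias(sig, {})
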