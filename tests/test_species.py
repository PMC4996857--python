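"""Symbol mapping, expression deltas, consistency counting, and the
delta-sum alternative selection."""

import numpy as np
import pandas as pd
import pytest

from cardiomat import (ExpressionMatrix, SampleTable, ValidationError,
                       alternative_delta_selection, compute_deltas,
                       consistency_report, delta_correlation,
                       make_delta_table, map_symbols, selection_overlap)
from cardiomat.pca import GeneSelection


def delta_frame(mouse: dict[str, float], human: dict[str, float]) -> pd.DataFrame:
    genes = sorted(mouse)
    return pd.DataFrame(
        {"human_symbol": [g.upper() for g in genes],
         "delta_mouse": [mouse[g] for g in genes],
         "delta_human": [human[g] for g in genes]},
        index=pd.Index(genes, name="gene"),
    )


class TestMapSymbols:
    def test_case_fold_pairing(self):
        pairs = map_symbols(["Myh7", "Abc1"], ["MYH7", "XYZ2"])
        assert pairs["mouse_symbol"].tolist() == ["Myh7"]
        assert pairs["human_symbol"].tolist() == ["MYH7"]

    def test_case_variant_collision_collapsed(self):
        pairs = map_symbols(["Myh7", "MYH7", "myh7"], ["MYH7"])
        assert len(pairs) == 1
        assert pairs["mouse_symbol"].iloc[0] == "MYH7"  # lexicographic min

    def test_synthetic_pairing_equals_universe(self, mouse_pair, human_data):
        truth = mouse_pair[5]
        hm, _ = human_data
        pairs = map_symbols(truth.universe, hm.feature_ids)
        assert pairs["mouse_symbol"].tolist() == truth.universe


class TestDeltas:
    def test_group_mean_difference(self):
        m = ExpressionMatrix(pd.DataFrame(
            [[1.0, 1.0, -0.5, -0.5]], index=["g0"],
            columns=["s0", "s1", "s2", "s3"]))
        st = SampleTable(pd.DataFrame({
            "sample_id": ["s0", "s1", "s2", "s3"],
            "stage": [2, 2, 1, 1],
            "group": ["adult", "adult", "fetal", "fetal"],
            "species": "h", "batch": "b"}))
        d = compute_deltas(m, st, "adult", "fetal")
        assert d["g0"] == pytest.approx(1.5)
        # identical groups -> 0
        d2 = compute_deltas(m, st, "adult", "adult")
        assert d2["g0"] == 0.0

    def test_empty_group_rejected(self):
        m = ExpressionMatrix(pd.DataFrame([[1.0, 2.0]], index=["g0"],
                                          columns=["s0", "s1"]))
        st = SampleTable(pd.DataFrame({
            "sample_id": ["s0", "s1"], "stage": [1, 2],
            "group": ["fetal", "adult"], "species": "h", "batch": "b"}))
        with pytest.raises(ValidationError, match="empty group"):
            compute_deltas(m, st, "adult", "neonate")

    def test_brute_force_two_group_difference(self, human_data):
        hm, hs = human_data
        d = compute_deltas(hm, hs, "adult", "fetal")
        adult = hs.samples_in_group("adult")
        fetal = hs.samples_in_group("fetal")
        expect = hm.values[adult].mean(axis=1) - hm.values[fetal].mean(axis=1)
        assert np.allclose(d, expect, atol=1e-12)


class TestCorrelation:
    def test_identical_deltas_r_one(self):
        d = delta_frame({"a": 1, "b": 2, "c": 3}, {"a": 1, "b": 2, "c": 3})
        assert delta_correlation(d) == pytest.approx(1.0)

    def test_negated_deltas_r_minus_one(self):
        d = delta_frame({"a": 1, "b": 2, "c": 3}, {"a": -1, "b": -2, "c": -3})
        assert delta_correlation(d) == pytest.approx(-1.0)

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(2)
        mouse = {f"g{i}": float(x) for i, x in enumerate(rng.normal(size=30))}
        human = {f"g{i}": float(x) for i, x in enumerate(rng.normal(size=30))}
        d = delta_frame(mouse, human)
        shuffled = d.sample(frac=1, random_state=1)
        assert delta_correlation(d) == pytest.approx(delta_correlation(shuffled))

    def test_too_few_genes_rejected(self):
        d = delta_frame({"a": 1, "b": 2}, {"a": 1, "b": 2})
        with pytest.raises(ValidationError, match=">= 3"):
            delta_correlation(d)


class TestConsistency:
    def test_all_consistent(self):
        d = delta_frame({"m1": 1, "m2": 2, "i1": -1},
                        {"m1": 0.5, "m2": 0.1, "i1": -0.2})
        sel = GeneSelection(mature={"m1", "m2"}, immature={"i1"})
        rep = consistency_report(d, sel)
        assert rep.n_inconsistent == 0
        assert rep.n_consistent_mature == 2
        assert rep.n_consistent_immature == 1

    def test_zero_delta_counted_inconsistent_below_fc(self):
        d = delta_frame({"m1": 1.0}, {"m1": 0.0})
        sel = GeneSelection(mature={"m1"})
        rep = consistency_report(d, sel)
        assert rep.n_inconsistent == 1
        assert rep.n_inconsistent_above_fc == 0

    def test_fold_change_threshold_on_log2_scale(self):
        # |delta| > log2(1.5) ~ 0.585 counts as above-threshold
        d = delta_frame({"m1": 1.0, "m2": 1.0}, {"m1": -0.6, "m2": -0.5})
        sel = GeneSelection(mature={"m1", "m2"})
        rep = consistency_report(d, sel, fc_threshold=1.5)
        assert rep.n_inconsistent == 2
        assert rep.n_inconsistent_above_fc == 1

    def test_counts_partition_mapped_selection(self, mouse_pair, human_data):
        rng = np.random.default_rng(3)
        truth = mouse_pair[5]
        genes = truth.universe[:200]
        d = delta_frame({g: float(x) for g, x in zip(genes, rng.normal(size=200))},
                        {g: float(x) for g, x in zip(genes, rng.normal(size=200))})
        sel = GeneSelection(mature=set(genes[:30]), immature=set(genes[30:60]))
        rep = consistency_report(d, sel)
        assert (rep.n_consistent_mature + rep.n_consistent_immature
                + rep.n_inconsistent) == rep.n_mapped == 60

    def test_invalid_threshold_rejected(self):
        d = delta_frame({"a": 1}, {"a": 1})
        with pytest.raises(ValidationError, match="fc_threshold"):
            consistency_report(d, GeneSelection(), fc_threshold=1.0)


class TestDeltaSumSelection:
    def test_single_outlier_selected_mature(self):
        mouse = {f"g{i}": 0.01 * ((-1) ** i) for i in range(20)}
        human = dict(mouse)
        mouse["hot"], human["hot"] = 3.0, 3.0
        sel = alternative_delta_selection(delta_frame(mouse, human))
        assert sel.mature == {"hot"}
        assert sel.immature == set()

    def test_too_few_genes_rejected(self):
        d = delta_frame({"a": 1, "b": 2, "c": 3}, {"a": 1, "b": 2, "c": 3})
        with pytest.raises(ValidationError, match=">= 10"):
            alternative_delta_selection(d)

    def test_zero_sd_selects_nothing(self):
        mouse = {f"g{i}": 1.0 for i in range(12)}
        sel = alternative_delta_selection(delta_frame(mouse, mouse))
        assert sel.selected == set()


class TestOverlap:
    def test_identical_selections_jaccard_one(self):
        a = GeneSelection(mature={"x"}, immature={"y"})
        b = GeneSelection(mature={"x"}, immature={"y"})
        assert selection_overlap(a, b)["jaccard"] == 1.0

    def test_disjoint_selections_jaccard_zero(self):
        a = GeneSelection(mature={"x"})
        b = GeneSelection(mature={"z"})
        out = selection_overlap(a, b)
        assert out["jaccard"] == 0.0 and out["n_union"] == 2

    def test_counts_match_brute_force_set_ops(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(100)]
        pick = lambda: set(rng.choice(genes, size=20, replace=False))
        a = GeneSelection(mature=pick())
        a.immature = pick() - a.mature
        b = GeneSelection(mature=pick())
        b.immature = pick() - b.mature
        out = selection_overlap(a, b)
        assert out["n_intersection"] == len(a.selected & b.selected)
        assert out["n_union"] == len(a.selected | b.selected)
        assert out["jaccard"] == pytest.approx(
            len(a.selected & b.selected) / len(a.selected | b.selected))
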