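"""Stage means, rank distributions, and ordinal regression with FDR."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cardiomat import (ExpressionMatrix, SampleTable, ValidationError,
                       stage_means, stage_rank_distribution, stage_ranks,
                       stage_regression)


def matrix_for(samples: SampleTable, arr) -> ExpressionMatrix:
    arr = np.asarray(arr, dtype=float)
    return ExpressionMatrix(
        pd.DataFrame(arr, index=[f"g{i}" for i in range(arr.shape[0])],
                     columns=samples.sample_ids)
    )


class TestStageMeans:
    def test_two_values_average(self, staged_samples):
        m = matrix_for(staged_samples, [[1, 3, 0, 0, 0, 0, 0, 0]])
        prof = stage_means(m, staged_samples)
        assert prof.loc["g0", 1] == 2.0

    def test_single_sample_stage_passthrough(self):
        rows = [{"sample_id": f"s{j}", "stage": j + 1, "species": "m",
                 "batch": "b"} for j in range(3)]
        st = SampleTable(pd.DataFrame(rows))
        m = matrix_for(st, [[5.0, 7.0, 9.0]])
        prof = stage_means(m, st)
        assert prof.loc["g0"].tolist() == [5.0, 7.0, 9.0]

    def test_matches_brute_force_group_mean(self, mouse_pair):
        _, _, matrix_b, _, samples_b, _ = mouse_pair
        prof = stage_means(matrix_b, samples_b)
        stages = samples_b.stages_for(matrix_b.sample_ids)
        for s in (1, 3, 5):
            cols = [sid for sid, st in zip(matrix_b.sample_ids, stages) if st == s]
            expect = matrix_b.values[cols].mean(axis=1)
            assert np.allclose(prof[s], expect, atol=1e-12)

    def test_stage_with_no_samples_rejected(self, staged_samples):
        m = matrix_for(staged_samples, [[1] * 8])
        sub = m.with_values(m.values.iloc[:, :6])  # drops both stage-4 samples
        with pytest.raises(ValidationError, match="zero samples"):
            stage_means(sub, staged_samples)


class TestRanks:
    def test_monotone_gene_ranks_are_identity(self):
        prof = pd.DataFrame({1: [0.0], 2: [1.0], 3: [2.0], 4: [3.0], 5: [4.0]},
                            index=["g0"])
        ranks = stage_ranks(prof)
        assert ranks.loc["g0"].tolist() == [1, 2, 3, 4, 5]
        hist = stage_rank_distribution(prof)
        assert hist.loc[1, 1] == 1 and hist.loc[5, 5] == 1

    def test_constant_gene_all_rank_one_under_tie_rule(self):
        prof = pd.DataFrame({1: [2.0], 2: [2.0], 3: [2.0]}, index=["g0"])
        ranks = stage_ranks(prof)
        assert ranks.loc["g0"].tolist() == [1, 1, 1]

    def test_histogram_rows_sum_to_gene_count(self, mouse_pair):
        _, _, matrix_b, _, samples_b, _ = mouse_pair
        prof = stage_means(matrix_b, samples_b)
        hist = stage_rank_distribution(prof)
        assert (hist.sum(axis=1) == len(prof)).all()


class TestRegression:
    def test_exact_linear_fit(self):
        prof = pd.DataFrame([[1.0, 2.0, 3.0, 4.0, 5.0]], columns=[1, 2, 3, 4, 5],
                            index=["g0"])
        out = stage_regression(prof)
        assert out.loc["g0", "slope"] == pytest.approx(1.0, abs=1e-12)
        assert out.loc["g0", "intercept"] == pytest.approx(0.0, abs=1e-12)
        assert out.loc["g0", "p_value"] == 0.0

    def test_constant_response_convention(self):
        prof = pd.DataFrame([[3.0] * 5], columns=[1, 2, 3, 4, 5], index=["g0"])
        out = stage_regression(prof)
        assert out.loc["g0", "slope"] == 0.0
        assert out.loc["g0", "p_value"] == 1.0

    def test_fewer_than_three_stages_rejected(self):
        prof = pd.DataFrame([[1.0, 2.0]], columns=[1, 2], index=["g0"])
        with pytest.raises(ValidationError, match=">= 3"):
            stage_regression(prof)

    def test_matches_linregress_and_brute_force_bh(self):
        """Slopes/intercepts/p-values match scipy.stats.linregress per gene,
        and q-values match a hand-rolled BH step-up."""
        rng = np.random.default_rng(17)
        n = 200
        prof = pd.DataFrame(rng.normal(size=(n, 5)) + np.arange(5) *
                            rng.choice([0, 0.5], size=(n, 1)),
                            columns=[1, 2, 3, 4, 5])
        out = stage_regression(prof)
        s = np.arange(1, 6, dtype=float)
        pvals = []
        for i in range(n):
            lr = stats.linregress(s, prof.iloc[i].to_numpy())
            assert out["slope"].iloc[i] == pytest.approx(lr.slope, abs=1e-10)
            assert out["intercept"].iloc[i] == pytest.approx(lr.intercept, abs=1e-10)
            assert out["p_value"].iloc[i] == pytest.approx(lr.pvalue, abs=1e-10)
            pvals.append(lr.pvalue)
        # brute-force BH step-up
        p = np.asarray(pvals)
        order = np.argsort(p)
        q_sorted = p[order] * n / (np.arange(n) + 1)
        q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
        q = np.empty(n)
        q[order] = np.minimum(q_sorted, 1.0)
        assert np.allclose(out["q_value"].to_numpy(), q, atol=1e-10)

    def test_reversed_stage_order_negates_slopes(self):
        rng = np.random.default_rng(19)
        prof = pd.DataFrame(rng.normal(size=(50, 5)), columns=[1, 2, 3, 4, 5])
        rev = pd.DataFrame(prof.to_numpy()[:, ::-1], columns=[1, 2, 3, 4, 5])
        a = stage_regression(prof)
        b = stage_regression(rev)
        assert np.allclose(a["slope"].to_numpy(), -b["slope"].to_numpy(), atol=1e-12)
        assert np.allclose(a["p_value"].to_numpy(), b["p_value"].to_numpy(), atol=1e-12)

    def test_null_genes_fdr_controlled(self):
        """Under a pure-noise trajectory the fraction of q<0.1 genes stays at
        or below the nominal level (plus Monte Carlo slack)."""
        rng = np.random.default_rng(23)
        prof = pd.DataFrame(rng.normal(size=(2000, 5)), columns=[1, 2, 3, 4, 5])
        out = stage_regression(prof, q_threshold=0.1)
        assert out["significant"].mean() <= 0.1 + 0.02

    def test_planted_slope_signs_recovered(self, small_config):
        from dataclasses import replace
        from cardiomat import simulate_mouse_pair
        cfg = replace(small_config, noise_sd=0.1, batch_sd=0.0)
        _, _, matrix_b, _, samples_b, truth = simulate_mouse_pair(cfg)
        prof = stage_means(matrix_b, samples_b)
        out = stage_regression(prof)
        for g in matrix_b.feature_ids:
            d = truth.direction[g]
            if d != 0:
                assert np.sign(out.loc[g, "slope"]) == d
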