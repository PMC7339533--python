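"""Factorial model, diagnostics, AEP buckets, similarity and importances."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import jaccard as scipy_jaccard

from qaffp.chemdata import DescriptorMatrix
from qaffp.qaffp import QAFFPMatrix
from qaffp.stats import (
    aep_table,
    cell_means_oracle,
    diagnostics,
    fit_factorial,
    importance_summary,
    jaccard_dissimilarity,
    pairwise_similarity_analysis,
)


def _all_bit_vectors(length):
    return [np.array(b) for b in itertools.product((0, 1), repeat=length)]


class TestJaccard:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ((1, 0, 1), (1, 0, 1), 0.0),
            ((1, 1, 0, 0), (0, 0, 1, 1), 1.0),
            ((1, 1, 0, 0), (1, 0, 1, 0), 2 / 3),
            ((0, 0), (0, 0), 0.0),  # all-zero convention
        ],
    )
    def test_examples(self, a, b, expected):
        assert jaccard_dissimilarity(a, b) == pytest.approx(expected)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            jaccard_dissimilarity([1, 0], [1, 0, 1])

    def test_matches_exhaustive_counting_up_to_length_6(self):
        """Oracle: direct n01/n10/n11 counting on every vector pair."""
        for length in (1, 3, 6):
            vecs = _all_bit_vectors(length)
            for a, b in itertools.combinations_with_replacement(vecs, 2):
                n11 = int(np.sum((a == 1) & (b == 1)))
                n10 = int(np.sum((a == 1) & (b == 0)))
                n01 = int(np.sum((a == 0) & (b == 1)))
                denom = n11 + n10 + n01
                expected = 0.0 if denom == 0 else (n10 + n01) / denom
                assert jaccard_dissimilarity(a, b) == pytest.approx(expected)

    def test_agrees_with_scipy_on_nonzero_vectors(self, rng):
        for _ in range(50):
            a = rng.integers(0, 2, size=16)
            b = rng.integers(0, 2, size=16)
            if not (a | b).any():
                continue
            assert jaccard_dissimilarity(a, b) == pytest.approx(
                float(scipy_jaccard(a.astype(bool), b.astype(bool)))
            )

    def test_triangle_inequality_brute_force(self):
        vecs = np.array(_all_bit_vectors(5), dtype=bool)
        n = len(vecs)
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                D[i, j] = D[j, i] = jaccard_dissimilarity(vecs[i], vecs[j])
        lhs = D[:, None, :]  # d(i,k)
        rhs = D[:, :, None] + D[None, :, :]  # d(i,j) + d(j,k)
        assert np.all(lhs <= rhs + 1e-12)


class TestPairwiseSimilarity:
    def _matrices(self, morgan_rows, rv_rows):
        ids = [f"c{i}" for i in range(len(morgan_rows))]
        morgan = DescriptorMatrix(
            "morgan2", ids, [f"b{j}" for j in range(len(morgan_rows[0]))],
            np.array(morgan_rows, dtype=float),
        )
        rv = QAFFPMatrix(
            "rv", ids, [f"m{j}" for j in range(len(rv_rows[0]))],
            np.array(rv_rows, dtype=float),
        )
        return morgan, rv

    def test_pair_count(self, rng):
        n = 7
        morgan, rv = self._matrices(
            rng.integers(0, 2, size=(n, 12)), rng.normal(size=(n, 5))
        )
        pairs, _, _ = pairwise_similarity_analysis(morgan, rv)
        assert len(pairs) == n * (n - 1) // 2

    def test_duplicate_compound_pair(self):
        morgan, rv = self._matrices(
            [[1, 0, 1], [1, 0, 1]], [[5.0, 6.0, 7.0], [5.0, 6.0, 7.0]]
        )
        pairs, _, _ = pairwise_similarity_analysis(morgan, rv)
        assert pairs[0].jaccard_dissimilarity == 0.0
        assert pairs[0].bioactivity_correlation == pytest.approx(1.0)

    def test_structure_driven_profiles_give_negative_correlation(self, rng):
        # QAFFP entries = noisy linear readout of the fingerprint bits, so
        # structurally close pairs must have correlated profiles
        n, bits, models = 25, 32, 10
        morgan_rows = rng.integers(0, 2, size=(n, bits))
        W = rng.normal(size=(bits, models))
        rv_rows = morgan_rows @ W + rng.normal(0, 0.05, size=(n, models))
        morgan, rv = self._matrices(morgan_rows, rv_rows)
        _, corr, pval = pairwise_similarity_analysis(morgan, rv)
        assert corr < 0
        assert pval < 0.01

    def test_too_few_compounds(self):
        morgan, rv = self._matrices([[1, 0]], [[5.0, 6.0]])
        with pytest.raises(ValueError):
            pairwise_similarity_analysis(morgan, rv)


class TestFactorial:
    def test_constant_response(self, benchmark_results_balanced):
        df = benchmark_results_balanced.copy()
        df["rmse_test"] = 0.8
        fit = fit_factorial(df, ("D1", "morgan2"))
        assert fit.intercept == pytest.approx(0.8)
        assert np.allclose(fit.slopes, 0, atol=1e-10)

    def test_saturated_model_matches_cell_means(self, benchmark_results_balanced):
        fit = fit_factorial(benchmark_results_balanced, ("D1", "morgan2"))
        ref_mean, cell_means = cell_means_oracle(
            benchmark_results_balanced, ("D1", "morgan2")
        )
        assert fit.intercept == pytest.approx(ref_mean)
        fitted = pd.Series(fit.fitted, index=benchmark_results_balanced.index)
        for (ds, desc), mean in cell_means.items():
            mask = (benchmark_results_balanced["dataset"] == ds) & (
                benchmark_results_balanced["descriptor"] == desc
            )
            assert np.allclose(fitted[mask], mean)

    def test_hand_computed_slopes(self, benchmark_results_balanced):
        fit = fit_factorial(benchmark_results_balanced, ("D1", "morgan2"))
        _, means = cell_means_oracle(benchmark_results_balanced, ("D1", "morgan2"))
        # main effect of descriptor rv_qaffp = cell(D1, rv) - cell(D1, morgan2)
        desc_term = [t for t in fit.slopes.index if "rv_qaffp" in t and ":" not in t]
        assert fit.slopes[desc_term[0]] == pytest.approx(
            means[("D1", "rv_qaffp")] - means[("D1", "morgan2")]
        )
        ds_term = [t for t in fit.slopes.index if "D2" in t and ":" not in t]
        assert fit.slopes[ds_term[0]] == pytest.approx(
            means[("D2", "morgan2")] - means[("D1", "morgan2")]
        )

    def test_residuals_sum_to_zero_and_reconstruct(self, benchmark_results_balanced):
        fit = fit_factorial(benchmark_results_balanced, ("D1", "morgan2"))
        assert abs(fit.residuals.sum()) < 1e-10
        assert np.allclose(
            fit.fitted + fit.residuals,
            benchmark_results_balanced["rmse_test"].to_numpy(),
        )

    def test_cell_means_equivalence_exhaustive_small_designs(self, rng):
        """Saturated-fit oracle on every balanced design up to 3x3x5."""
        for nd in (2, 3):
            for nk in (2, 3):
                for nr in (2, 3, 5):
                    rows = []
                    for d in range(nd):
                        for k in range(nk):
                            for r in range(nr):
                                rows.append(
                                    {
                                        "dataset": f"D{d}",
                                        "descriptor": f"K{k}",
                                        "replicate": r,
                                        "rmse_test": rng.uniform(0.4, 1.2),
                                    }
                                )
                    df = pd.DataFrame(rows)
                    fit = fit_factorial(df, ("D0", "K0"))
                    ref, means = cell_means_oracle(df, ("D0", "K0"))
                    assert fit.intercept == pytest.approx(ref)
                    for (ds, desc), mean in means.items():
                        mask = (df["dataset"] == ds) & (df["descriptor"] == desc)
                        assert np.allclose(fit.fitted[mask.to_numpy()], mean)

    def test_unbalanced_design_rejected(self, benchmark_results_balanced):
        df = benchmark_results_balanced.iloc[:-1]
        with pytest.raises(ValueError, match="unbalanced"):
            fit_factorial(df, ("D1", "morgan2"))

    def test_missing_reference_level(self, benchmark_results_balanced):
        with pytest.raises(ValueError, match="reference"):
            fit_factorial(benchmark_results_balanced, ("nope", "morgan2"))

    def test_interaction_pvalue_detects_crossing(self, rng):
        rows = []
        for d in range(2):
            for k in range(2):
                base = 0.7 + 0.3 * (d == k)  # strong interaction
                for r in range(10):
                    rows.append(
                        {
                            "dataset": f"D{d}",
                            "descriptor": f"K{k}",
                            "replicate": r,
                            "rmse_test": base + rng.normal(0, 0.01),
                        }
                    )
        fit = fit_factorial(pd.DataFrame(rows), ("D0", "K0"))
        assert fit.interaction_pvalue < 1e-6


class TestDiagnostics:
    def test_normal_residuals_on_identity_line(self, rng):
        rows = []
        for d in range(2):
            for k in range(2):
                for r in range(200):
                    rows.append(
                        {
                            "dataset": f"D{d}",
                            "descriptor": f"K{k}",
                            "replicate": r,
                            "rmse_test": 0.8 + rng.normal(0, 0.05),
                        }
                    )
        fit = fit_factorial(pd.DataFrame(rows), ("D0", "K0"))
        rep = diagnostics(fit)
        assert not rep.degenerate
        # standardize both axes; identity-line agreement within tolerance
        sd = fit.residuals.std()
        inner = rep.qq.iloc[20:-20]  # tails of a finite sample wobble
        assert np.allclose(inner["theoretical"] * sd, inner["sample"], atol=0.04)
        assert not rep.heteroscedastic

    def test_zero_residuals_degenerate(self, benchmark_results_balanced):
        df = benchmark_results_balanced.copy()
        df["rmse_test"] = 0.5
        rep = diagnostics(fit_factorial(df, ("D1", "morgan2")))
        assert rep.degenerate

    def test_report_row_count(self, benchmark_results_balanced):
        fit = fit_factorial(benchmark_results_balanced, ("D1", "morgan2"))
        rep = diagnostics(fit)
        assert len(rep.residual_vs_fitted) == len(benchmark_results_balanced)
        assert len(rep.qq) == len(benchmark_results_balanced)


def _pred_frame(aeps, dataset="D0"):
    return pd.DataFrame(
        {
            "dataset": dataset,
            "replicate": 0,
            "compound_id": [f"c{i}" for i in range(len(aeps))],
            "observed": 6.0,
            "predicted": [6.0 + a for a in aeps],
        }
    )


class TestAEPTable:
    def test_identical_small_errors(self):
        a = _pred_frame([0.2, 0.2, 0.2])
        table = aep_table(a, a.copy())
        row = table.iloc[0]
        assert row["both_le_05"] == 100.0
        assert row["a_ge_10_b_le_05"] == 0.0
        assert row["a_le_05_b_ge_10"] == 0.0

    def test_manual_bucket_counts(self):
        a = _pred_frame([0.2, 0.7, 1.2, 0.3])
        b = _pred_frame([0.3, 0.8, 0.4, 1.5])
        row = aep_table(a, b).iloc[0]
        assert row["both_le_05"] == 25.0
        # buckets are cumulative: the (0.2, 0.3) pair also falls in <= 1.0
        assert row["both_le_10"] == 50.0
        assert row["a_ge_10_b_le_05"] == 25.0
        assert row["a_le_05_b_ge_10"] == 25.0

    def test_nested_buckets_monotone(self, rng):
        a = _pred_frame(rng.uniform(0, 3, size=50))
        b = _pred_frame(rng.uniform(0, 3, size=50))
        row = aep_table(a, b).iloc[0]
        assert row["both_le_05"] <= row["both_le_10"]

    def test_key_mismatch_rejected(self):
        a = _pred_frame([0.2, 0.4])
        b = _pred_frame([0.2, 0.4])
        b["compound_id"] = ["c0", "cX"]
        with pytest.raises(ValueError, match="keys"):
            aep_table(a, b)

    def test_empty_rejected(self):
        empty = _pred_frame([])
        with pytest.raises(ValueError):
            aep_table(empty, empty.copy())


class TestImportanceSummary:
    def test_identical_replicates_zero_sd(self):
        v = pd.Series([0.5, 0.3, 0.2], index=["a", "b", "c"])
        summary, _, _ = importance_summary([v, v.copy()])
        assert np.allclose(summary["sd_importance"], 0)

    def test_means_sum_to_one(self, rng):
        vecs = []
        for _ in range(5):
            x = rng.dirichlet(np.ones(10))
            vecs.append(pd.Series(x, index=[f"m{i}" for i in range(10)]))
        summary, _, _ = importance_summary(vecs)
        assert summary["mean_importance"].sum() == pytest.approx(1.0)

    def test_null_correlation_with_q2(self, rng):
        n_feat = 1000
        names = [f"m{i}" for i in range(n_feat)]
        vecs = [
            pd.Series(rng.dirichlet(np.ones(n_feat)), index=names) for _ in range(3)
        ]
        q2 = pd.Series(rng.uniform(0, 1, size=n_feat), index=names)
        _, corr, pval = importance_summary(vecs, q2)
        assert abs(corr) < 0.1
        assert pval > 0.05

    def test_name_mismatch_rejected(self):
        v1 = pd.Series([1.0], index=["a"])
        v2 = pd.Series([1.0], index=["b"])
        with pytest.raises(ValueError, match="names"):
            importance_summary([v1, v2])
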