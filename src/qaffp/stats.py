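"""Statistical analysis of benchmark output.

Covers four analyses: (1) the fixed-effect full-factorial linear model of
test-set RMSE with dataset, descriptor and interaction terms under treatment
coding, plus residual diagnostics; (2) joint absolute-error-in-prediction
(AEP) bucket tables comparing two descriptor sets; (3) chemical-similarity
vs bioactivity-similarity analysis (Jaccard–Needham dissimilarity on Morgan
bits against Pearson correlation of rv-QAFFP profiles); and (4) per-feature
random-forest importance summaries joined to base-model predictivity.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.stats.diagnostic import het_breuschpagan

from qaffp.chemdata import DescriptorMatrix
from qaffp.qaffp import QAFFPMatrix

AEP_BUCKETS = (
    ("both_le_05", lambda a, b: (a <= 0.5) & (b <= 0.5)),
    ("both_le_10", lambda a, b: (a <= 1.0) & (b <= 1.0)),
    ("a_ge_10_b_le_05", lambda a, b: (a >= 1.0) & (b <= 0.5)),
    ("a_le_05_b_ge_10", lambda a, b: (a <= 0.5) & (b >= 1.0)),
    ("a_ge_20_b_le_10", lambda a, b: (a >= 2.0) & (b <= 1.0)),
    ("a_le_10_b_ge_20", lambda a, b: (a <= 1.0) & (b >= 2.0)),
    ("a_ge_30_b_le_10", lambda a, b: (a >= 3.0) & (b <= 1.0)),
    ("a_le_10_b_ge_30", lambda a, b: (a <= 1.0) & (b >= 3.0)),
)


def jaccard_dissimilarity(a, b) -> float:
    """Jaccard–Needham dissimilarity between two binary vectors.

    (n10 + n01) / (n11 + n10 + n01), with the all-zero/all-zero pair defined
    as 0 by convention.
    """
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("bit vectors differ in length")
    union = np.count_nonzero(a | b)
    if union == 0:
        return 0.0
    return float(np.count_nonzero(a != b) / union)


@dataclass(frozen=True)
class SimilarityPair:
    compound_i: str
    compound_j: str
    jaccard_dissimilarity: float
    bioactivity_correlation: float


def pairwise_similarity_analysis(
    morgan: DescriptorMatrix, rv_qaffp: QAFFPMatrix | DescriptorMatrix
) -> tuple[list[SimilarityPair], float, float]:
    """Chemical vs bioactivity similarity over all compound pairs.

    Returns the scored pairs plus the Pearson correlation (and two-sided
    p-value) between structural dissimilarity and bioactivity-profile
    correlation across pairs.  The expected signature on real data is a
    negative correlation: structurally close pairs have correlated predicted
    bioactivity profiles.
    """
    rv_rows = rv_qaffp.values
    rv_ids = list(rv_qaffp.row_ids)
    if list(morgan.row_ids) != rv_ids:
        raise ValueError("matrices must cover the same compounds in the same order")
    n = len(rv_ids)
    if n < 2:
        raise ValueError("need >= 2 compounds")
    pairs = []
    for i, j in itertools.combinations(range(n), 2):
        jac = jaccard_dissimilarity(morgan.values[i], morgan.values[j])
        vi, vj = rv_rows[i], rv_rows[j]
        if np.std(vi) == 0 or np.std(vj) == 0:
            corr = 0.0
        else:
            corr = float(sps.pearsonr(vi, vj).statistic)
        pairs.append(SimilarityPair(rv_ids[i], rv_ids[j], jac, corr))
    xs = np.array([p.jaccard_dissimilarity for p in pairs])
    ys = np.array([p.bioactivity_correlation for p in pairs])
    if np.std(xs) == 0 or np.std(ys) == 0:
        return pairs, 0.0, 1.0
    res = sps.pearsonr(xs, ys)
    return pairs, float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Factorial linear model
# ---------------------------------------------------------------------------

@dataclass
class FactorialFit:
    intercept: float  # mean RMSE of the reference (dataset, descriptor) cell
    slopes: pd.Series  # named coefficients (dataset, descriptor, interaction)
    residuals: np.ndarray
    fitted: np.ndarray
    adjusted_r2: float
    residual_se: float
    interaction_pvalue: float
    reference_levels: tuple[str, str]
    coef_table: pd.DataFrame  # coef, std err, t, p per term
    model_result: object  # statsmodels RegressionResults


def fit_factorial(
    results: pd.DataFrame, reference_levels: tuple[str, str]
) -> FactorialFit:
    """OLS fit of RMSE_test ~ dataset * descriptor with treatment coding.

    ``results`` needs columns (dataset, descriptor, replicate, rmse_test) and
    a balanced design: every (dataset, descriptor) cell with the same number
    of replicates.  With the full interaction the model is saturated, so the
    intercept equals the reference cell's mean RMSE and every cell's fitted
    value equals that cell's mean.
    """
    required = {"dataset", "descriptor", "rmse_test"}
    if not required.issubset(results.columns):
        raise ValueError(f"results table needs columns {sorted(required)}")
    counts = results.groupby(["dataset", "descriptor"]).size()
    expected = len(results["dataset"].unique()) * len(results["descriptor"].unique())
    if len(counts) != expected or counts.nunique() != 1:
        deficient = counts[counts != counts.max()]
        raise ValueError(
            "unbalanced design; deficient cells: "
            f"{deficient.index.tolist() or 'missing cells'}"
        )
    ref_ds, ref_desc = reference_levels
    if ref_ds not in set(results["dataset"]):
        raise ValueError(f"reference dataset {ref_ds!r} not present")
    if ref_desc not in set(results["descriptor"]):
        raise ValueError(f"reference descriptor {ref_desc!r} not present")

    df = results.copy()
    formula = (
        f"rmse_test ~ C(dataset, Treatment(reference={ref_ds!r})) * "
        f"C(descriptor, Treatment(reference={ref_desc!r}))"
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        # a saturated design without replication has zero residual df
        fit = smf.ols(formula, data=df).fit()

    # interaction F-test (only meaningful with replication within cells)
    n_cells = len(counts)
    if len(df) > n_cells:
        reduced = smf.ols(formula.replace("*", "+"), data=df).fit()
        anova = sm.stats.anova_lm(reduced, fit)
        interaction_p = float(anova["Pr(>F)"].iloc[-1])
        if np.isnan(interaction_p):  # zero residual variance
            interaction_p = 0.0 if fit.ssr < reduced.ssr else 1.0
    else:
        interaction_p = float("nan")

    params = fit.params
    with np.errstate(divide="ignore", invalid="ignore"):
        # saturated designs without replication have zero residual df;
        # standard errors and t/p values are then undefined (NaN/inf)
        adj_r2 = float(fit.rsquared_adj) if fit.df_resid > 0 else 1.0
        if not np.isfinite(adj_r2):
            adj_r2 = 1.0 if fit.ssr < 1e-12 else float("nan")
        coef_table = pd.DataFrame(
            {
                "coef": fit.params,
                "std_err": fit.bse,
                "t": fit.tvalues,
                "p_value": fit.pvalues,
            }
        )
    return FactorialFit(
        intercept=float(params["Intercept"]),
        slopes=params.drop("Intercept"),
        residuals=np.asarray(fit.resid),
        fitted=np.asarray(fit.fittedvalues),
        adjusted_r2=adj_r2,
        residual_se=float(np.sqrt(fit.mse_resid)) if fit.df_resid > 0 else 0.0,
        interaction_pvalue=interaction_p,
        reference_levels=reference_levels,
        coef_table=coef_table,
        model_result=fit,
    )


def cell_means_oracle(
    results: pd.DataFrame, reference_levels: tuple[str, str]
) -> tuple[float, dict[tuple[str, str], float]]:
    """Independent saturated-model oracle: per-cell mean RMSE.

    Returns the reference-cell mean (the intercept of the treatment-coded
    fit) and the mapping (dataset, descriptor) -> cell mean, which must equal
    the factorial fit's fitted values.
    """
    means = results.groupby(["dataset", "descriptor"])["rmse_test"].mean()
    ref = float(means[reference_levels])
    return ref, {k: float(v) for k, v in means.items()}


@dataclass
class DiagnosticReport:
    residual_vs_fitted: pd.DataFrame  # fitted, residual
    histogram: pd.DataFrame  # bin_left, bin_right, count
    qq: pd.DataFrame  # theoretical, sample quantiles
    heteroscedastic: bool
    bp_statistic: float
    bp_pvalue: float
    degenerate: bool


def diagnostics(fit: FactorialFit, n_bins: int = 30, alpha: float = 0.05) -> DiagnosticReport:
    """Residual diagnostics: spread vs fit, distribution shape, normal Q–Q.

    Heteroscedasticity is flagged with a Breusch–Pagan test of the residuals
    against the fitted values.  Zero-variance residuals short-circuit to a
    degenerate report.
    """
    resid = fit.residuals
    fitted = fit.fitted
    rvf = pd.DataFrame({"fitted": fitted, "residual": resid})
    if np.allclose(resid, 0):
        empty_hist = pd.DataFrame({"bin_left": [], "bin_right": [], "count": []})
        qq = pd.DataFrame({"theoretical": [], "sample": []})
        return DiagnosticReport(rvf, empty_hist, qq, False, 0.0, 1.0, True)

    counts, edges = np.histogram(resid, bins=n_bins)
    hist = pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )
    (theoretical, ordered), _ = sps.probplot(resid, dist="norm")
    qq = pd.DataFrame({"theoretical": theoretical, "sample": ordered})
    exog = sm.add_constant(fitted)
    bp_stat, bp_p, _, _ = het_breuschpagan(resid, exog)
    return DiagnosticReport(
        residual_vs_fitted=rvf,
        histogram=hist,
        qq=qq,
        heteroscedastic=bool(bp_p < alpha),
        bp_statistic=float(bp_stat),
        bp_pvalue=float(bp_p),
        degenerate=False,
    )


# ---------------------------------------------------------------------------
# AEP bucket table
# ---------------------------------------------------------------------------

def aep_table(pred_a: pd.DataFrame, pred_b: pd.DataFrame) -> pd.DataFrame:
    """Joint absolute-error bucket percentages per dataset.

    Both inputs are long prediction tables with columns
    (dataset, replicate, compound_id, observed, predicted), pooled over
    replicates; rows are joined on (dataset, replicate, compound_id).
    AEP = |observed − predicted|; percentages are over the pooled test-set
    instances of each dataset.
    """
    keys = ["dataset", "replicate", "compound_id"]
    for df, name in ((pred_a, "A"), (pred_b, "B")):
        missing = set(keys + ["observed", "predicted"]) - set(df.columns)
        if missing:
            raise ValueError(f"prediction table {name} lacks columns {sorted(missing)}")
    a = pred_a.copy()
    b = pred_b.copy()
    a["aep_a"] = (a["observed"] - a["predicted"]).abs()
    b["aep_b"] = (b["observed"] - b["predicted"]).abs()
    merged = a[keys + ["aep_a"]].merge(b[keys + ["aep_b"]], on=keys, how="outer")
    if merged[["aep_a", "aep_b"]].isna().any().any():
        raise ValueError("prediction tables do not share identical (dataset, replicate, compound) keys")
    if merged.empty:
        raise ValueError("no pooled predictions to bucket")
    rows = []
    for ds, grp in merged.groupby("dataset"):
        n = len(grp)
        row = {"dataset": ds, "n_instances": n}
        for name, cond in AEP_BUCKETS:
            row[name] = 100.0 * float(cond(grp["aep_a"], grp["aep_b"]).sum()) / n
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Feature-importance summary
# ---------------------------------------------------------------------------

def importance_summary(
    importance_vectors: list[pd.Series],
    base_model_q2: pd.Series | None = None,
) -> tuple[pd.DataFrame, float | None, float | None]:
    """Mean ± SD per-feature importance across replicates.

    When ``base_model_q2`` (indexed by model_id/feature name) is given, the
    mean importances are joined to it and the Pearson correlation between a
    base model's cross-validation predictivity and its average importance is
    reported (with two-sided p-value).
    """
    if len(importance_vectors) < 2:
        raise ValueError("need >= 2 replicates of importances")
    names = list(importance_vectors[0].index)
    for v in importance_vectors[1:]:
        if list(v.index) != names:
            raise ValueError("feature names differ across replicates")
    mat = np.vstack([v.to_numpy(dtype=float) for v in importance_vectors])
    summary = pd.DataFrame(
        {
            "feature": names,
            "mean_importance": mat.mean(axis=0),
            "sd_importance": mat.std(axis=0, ddof=1),
        }
    )
    if base_model_q2 is None:
        return summary, None, None
    joined = summary.set_index("feature").join(base_model_q2.rename("q2"), how="inner")
    if len(joined) < 3 or joined["q2"].std() == 0 or joined["mean_importance"].std() == 0:
        return summary, 0.0, 1.0
    res = sps.pearsonr(joined["mean_importance"], joined["q2"])
    return summary, float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Base-model R² cutoff sweep
# ---------------------------------------------------------------------------

def cutoff_sweep_analysis(
    registry,
    datasets: dict,
    morgan_by_dataset: dict[str, DescriptorMatrix],
    cutoffs: list[float],
    design,
    confidence: float = 0.90,
) -> pd.DataFrame:
    """Benchmark rv-QAFFP rebuilt at increasing base-model R² cutoffs.

    For each cutoff the panel is restricted to base models with
    R²_test >= cutoff, the rv-QAFFP matrices are rebuilt and the benchmark is
    re-run.  Returns a long table (cutoff, dataset, replicate, rmse_test,
    r2_test, n_models, skipped); a cutoff that removes every model is flagged
    skipped rather than fatal.  The per-cutoff mean RMSE identifies the
    arg-min cutoff.
    """
    from qaffp.benchmark import run_replicate, split_seed
    from qaffp.qaffp import QAFFPBuildConfig, build_rv_qaffp, subset_by_r2

    if sorted(cutoffs) != list(cutoffs):
        raise ValueError("cutoffs must be sorted ascending")
    rows = []
    for cutoff in cutoffs:
        ids = subset_by_r2(registry, cutoff)
        if not ids:
            rows.append(
                {
                    "cutoff": cutoff,
                    "dataset": None,
                    "replicate": None,
                    "rmse_test": np.nan,
                    "r2_test": np.nan,
                    "n_models": 0,
                    "skipped": True,
                }
            )
            continue
        config = QAFFPBuildConfig(
            model_subset=f"r2_cutoff:{cutoff}", confidence=confidence
        )
        for ds_id, dataset in datasets.items():
            rv = build_rv_qaffp(morgan_by_dataset[ds_id], registry, config)
            mat = rv.to_descriptor_matrix()
            for rep in range(design.n_replicates):
                seed = split_seed(design, ds_id, rep)
                res = run_replicate(dataset, mat, seed, design, replicate=rep)
                rows.append(
                    {
                        "cutoff": cutoff,
                        "dataset": ds_id,
                        "replicate": rep,
                        "rmse_test": res.rmse_test,
                        "r2_test": res.r2_test,
                        "n_models": len(ids),
                        "skipped": False,
                    }
                )
    return pd.DataFrame(rows)


def argmin_cutoff(sweep: pd.DataFrame) -> float:
    """The cutoff with the lowest mean test RMSE (skipped cutoffs excluded)."""
    ok = sweep[~sweep["skipped"]]
    if ok.empty:
        raise ValueError("every cutoff was skipped")
    means = ok.groupby("cutoff")["rmse_test"].mean()
    return float(means.idxmin())
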