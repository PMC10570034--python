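"""Statistical battery for methylation-by-annotation comparisons.

Covers: Welch's t (unequal-variance two-sample comparison of gene-level
weighted methylation), Benjamini-Hochberg FDR adjustment, logistic regression
of per-site methylation status on codon degeneracy and housekeeping status
with likelihood-ratio term tests, Tukey-style single-step pairwise contrasts,
and Kruskal-Wallis with Dunn post hoc.

The logistic model is fitted by IRLS (statsmodels GLM, binomial family) on
counts aggregated by (degeneracy, housekeeping) cell, which has the same
likelihood as the per-site Bernoulli model.  Term chi-squares are Type-II
likelihood-ratio tests: each main effect is tested by dropping it from the
additive model, the interaction by comparing the full model with the additive
one.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning


@dataclass
class TestResult:
    statistic: float
    df: float
    p_value: float
    method: str


@dataclass
class PairwiseContrast:
    level_a: str
    level_b: str
    estimate: float
    se: float
    z: float
    p_raw: float
    p_adjusted: float


def welch_t(a, b) -> TestResult:
    """Welch's unequal-variance two-sample t-test (two-sided)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("both groups have zero variance")
    res = sps.ttest_ind(a, b, equal_var=False)
    return TestResult(
        statistic=float(res.statistic), df=float(res.df),
        p_value=float(res.pvalue), method="welch_t",
    )


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class MethylationModelFit:
    """Fitted logistic regression of methylation status with LR term tests."""

    full: object  # statsmodels GLMResults
    term_tests: dict[str, TestResult]
    degeneracy_levels: list[int]
    param_names: list[str]
    separation: bool = False
    dropped_levels: list[int] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def _design(cells: pd.DataFrame, levels: list[int], terms: tuple[str, ...]):
    """Design matrix for the requested terms over aggregated cells."""
    cols = {"Intercept": np.ones(len(cells))}
    if "degeneracy" in terms:
        for lv in levels[1:]:
            cols[f"deg[{lv}]"] = (cells["degeneracy"] == lv).astype(float).to_numpy()
    if "housekeeping" in terms:
        cols["hk"] = cells["housekeeping"].astype(float).to_numpy()
    if "interaction" in terms:
        for lv in levels[1:]:
            cols[f"deg[{lv}]:hk"] = (
                (cells["degeneracy"] == lv) & cells["housekeeping"]
            ).astype(float).to_numpy()
    X = pd.DataFrame(cols, index=cells.index)
    return X


def _fit_glm(cells: pd.DataFrame, X: pd.DataFrame):
    endog = cells[["n_meth", "n_unmeth"]].to_numpy()
    model = sm.GLM(endog, X, family=sm.families.Binomial())
    # the interaction model is saturated on the cell table (df_resid = 0), which
    # makes statsmodels warn spuriously; separation is diagnosed explicitly in
    # fit_methylation_model instead
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PerfectSeparationWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        res = model.fit(maxiter=100, tol=1e-8)
    if not res.converged:
        raise RuntimeError("IRLS did not converge within 100 iterations")
    return res


def fit_methylation_model(obs: pd.DataFrame) -> MethylationModelFit:
    """Logistic regression of methylated ~ degeneracy * housekeeping.

    ``obs`` has boolean ``methylated``, categorical ``degeneracy`` in
    {0,2,3,4} and boolean ``housekeeping`` — one row per called CpG site in a
    coding position.  Reference levels: 0-fold degeneracy, non-housekeeping.
    Returns per-term likelihood-ratio chi-squares (Type II: main effects
    tested within the additive model) with df = number of dropped
    coefficients.  Complete separation is flagged, never silently reported.
    """
    warnings: list[str] = []
    counts = (
        obs.assign(methylated=obs["methylated"].astype(bool))
        .groupby(["degeneracy", "housekeeping"], observed=True)["methylated"]
        .agg(n_meth="sum", n_total="count")
        .reset_index()
    )
    counts["n_unmeth"] = counts["n_total"] - counts["n_meth"]

    all_levels = sorted(obs["degeneracy"].unique())
    present = sorted(counts.loc[counts["n_total"] > 0, "degeneracy"].unique())
    dropped = [lv for lv in all_levels if lv not in present]
    if dropped:
        warnings.append(f"degeneracy levels with no observations dropped: {dropped}")
    levels = present
    if len(levels) < 2:
        raise ValueError("at least two degeneracy levels with observations are required")
    cells = counts[counts["degeneracy"].isin(levels)].reset_index(drop=True)

    both_hk = cells["housekeeping"].nunique() == 2
    full_terms = ("degeneracy", "housekeeping", "interaction") if both_hk else ("degeneracy",)

    X_full = _design(cells, levels, full_terms)
    full = _fit_glm(cells, X_full)

    # separation diagnostic: cell probabilities pinned at 0/1 inflate |coef| and SE
    separation = bool(
        np.any(np.abs(full.params.to_numpy()) > 15)
        or np.any(full.bse.to_numpy() > 100)
        or cells["n_meth"].sum() == 0
        or cells["n_unmeth"].sum() == 0
    )
    if separation:
        warnings.append(
            "quasi-complete separation detected (degenerate cell frequencies); "
            "coefficients and contrasts are unreliable"
        )

    def lr(reduced_terms, larger_terms, name, df):
        res_r = _fit_glm(cells, _design(cells, levels, reduced_terms))
        res_l = _fit_glm(cells, _design(cells, levels, larger_terms))
        stat = max(0.0, 2.0 * (res_l.llf - res_r.llf))
        return TestResult(stat, df, float(sps.chi2.sf(stat, df)), f"lr_{name}")

    k = len(levels) - 1
    tests = {}
    if both_hk:
        additive = ("degeneracy", "housekeeping")
        tests["degeneracy"] = lr(("housekeeping",), additive, "degeneracy", k)
        tests["housekeeping"] = lr(("degeneracy",), additive, "housekeeping", 1)
        res_add = _fit_glm(cells, _design(cells, levels, additive))
        stat = max(0.0, 2.0 * (full.llf - res_add.llf))
        tests["interaction"] = TestResult(
            stat, k, float(sps.chi2.sf(stat, k)), "lr_interaction"
        )
    else:
        null = _fit_glm(cells, _design(cells, levels, ()))
        stat = max(0.0, 2.0 * (full.llf - null.llf))
        tests["degeneracy"] = TestResult(stat, k, float(sps.chi2.sf(stat, k)), "lr_degeneracy")

    return MethylationModelFit(
        full=full, term_tests=tests, degeneracy_levels=list(levels),
        param_names=list(X_full.columns), separation=separation,
        dropped_levels=dropped, warnings=warnings,
    )


def pairwise_contrasts(
    fit: MethylationModelFit,
    factor: str = "degeneracy",
    adjust: str = "single_step",
    at_housekeeping: bool = False,
    n_mc: int = 20000,
    seed: int = 20240915,
) -> list[PairwiseContrast]:
    """Tukey-style pairwise Wald z contrasts between degeneracy levels.

    The contrast for a pair is effect(lower fold) - effect(higher fold), so a
    positive z means the lower-degeneracy (more constrained) class is more
    methylated.  ``single_step`` approximates the Tukey max-|z| adjustment by
    seeded Monte-Carlo sampling from the contrasts' joint normal;
    ``bonferroni`` multiplies raw p by the number of pairs.
    """
    if factor != "degeneracy":
        raise ValueError(f"unknown factor {factor!r}")
    if adjust not in ("single_step", "bonferroni"):
        raise ValueError(f"unknown adjustment {adjust!r}")

    levels = fit.degeneracy_levels
    names = fit.param_names
    params = fit.full.params.to_numpy()
    cov = fit.full.cov_params().to_numpy()

    def effect_vector(level: int) -> np.ndarray:
        v = np.zeros(len(names))
        if level != levels[0]:
            v[names.index(f"deg[{level}]")] = 1.0
            if at_housekeeping and f"deg[{level}]:hk" in names:
                v[names.index(f"deg[{level}]:hk")] = 1.0
        return v

    pairs = list(itertools.combinations(levels, 2))
    L = np.array([effect_vector(a) - effect_vector(b) for a, b in pairs])
    est = L @ params
    vcv = L @ cov @ L.T
    se = np.sqrt(np.diag(vcv))
    z = est / se
    p_raw = 2.0 * sps.norm.sf(np.abs(z))

    m = len(pairs)
    if adjust == "bonferroni" or m == 1:
        p_adj = np.minimum(1.0, p_raw * m)
    else:
        corr = vcv / np.outer(se, se)
        rng = np.random.default_rng(seed)
        draws = rng.multivariate_normal(np.zeros(m), corr, size=n_mc, method="svd")
        maxabs = np.abs(draws).max(axis=1)
        p_adj = np.array([(maxabs >= abs(zi)).mean() for zi in z])
        p_adj = np.maximum(p_adj, p_raw)  # single-step never beats the raw p

    return [
        PairwiseContrast(
            level_a=f"{a}-fold", level_b=f"{b}-fold",
            estimate=float(est[i]), se=float(se[i]), z=float(z[i]),
            p_raw=float(p_raw[i]), p_adjusted=float(min(1.0, p_adj[i])),
        )
        for i, (a, b) in enumerate(pairs)
    ]


def kruskal_dunn(groups: dict[str, np.ndarray]) -> tuple[TestResult, list[PairwiseContrast]]:
    """Kruskal-Wallis across labelled groups plus Dunn post hoc (BH-adjusted).

    The KW H statistic is tie-corrected with df = k - 1.  Dunn z for a pair is
    the difference of mean pooled ranks over its standard error (with tie
    correction); the sign follows the listed group order (first - second).
    When every observation across all groups is identical H is 0 and p is 1.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("at least two groups are required")
    arrays = [np.asarray(groups[g], dtype=float) for g in labels]
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group must be non-empty")

    pooled = np.concatenate(arrays)
    k = len(labels)
    if np.all(pooled == pooled[0]):
        kw = TestResult(0.0, k - 1, 1.0, "kruskal_wallis")
        contrasts = [
            PairwiseContrast(a, b, 0.0, np.nan, 0.0, 1.0, 1.0)
            for a, b in itertools.combinations(labels, 2)
        ]
        return kw, contrasts

    h, p = sps.kruskal(*arrays)
    kw = TestResult(float(h), k - 1, float(p), "kruskal_wallis")

    ranks = sps.rankdata(pooled)
    n_tot = pooled.size
    sizes = np.array([a.size for a in arrays])
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    mean_rank = {
        g: ranks[bounds[i]:bounds[i + 1]].mean() for i, g in enumerate(labels)
    }
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n_tot - 1))
    var_unit = n_tot * (n_tot + 1) / 12.0 - tie_term

    zs, pairs = [], list(itertools.combinations(range(k), 2))
    for i, j in pairs:
        se = np.sqrt(var_unit * (1.0 / sizes[i] + 1.0 / sizes[j]))
        zs.append((mean_rank[labels[i]] - mean_rank[labels[j]]) / se)
    zs = np.array(zs)
    p_raw = 2.0 * sps.norm.sf(np.abs(zs))
    p_adj = bh_adjust(p_raw)
    contrasts = [
        PairwiseContrast(
            level_a=labels[i], level_b=labels[j],
            estimate=float(mean_rank[labels[i]] - mean_rank[labels[j]]),
            se=float(np.sqrt(var_unit * (1.0 / sizes[i] + 1.0 / sizes[j]))),
            z=float(zs[idx]), p_raw=float(p_raw[idx]), p_adjusted=float(p_adj[idx]),
        )
        for idx, (i, j) in enumerate(pairs)
    ]
    return kw, contrasts


def exon_rank_kruskal(
    summary: pd.DataFrame, max_rank: int = 6
) -> tuple[TestResult, list[PairwiseContrast]]:
    """Kruskal-Wallis over exon-rank and intergenic weighted levels.

    Groups are exon ranks 1..max_rank (instances beyond max_rank excluded)
    plus the intergenic windows — with six ranks this gives df = 6.  Rows with
    undefined levels (no coverage) are dropped.
    """
    groups: dict[str, np.ndarray] = {}
    for rank in range(1, max_rank + 1):
        vals = summary.loc[
            summary["category"] == f"exon_rank_{rank}", "weighted_level"
        ].dropna().to_numpy()
        if vals.size:
            groups[f"exon_rank_{rank}"] = vals
    inter = summary.loc[
        summary["category"] == "intergenic", "weighted_level"
    ].dropna().to_numpy()
    if inter.size:
        groups["intergenic"] = inter
    return kruskal_dunn(groups)


def te_intergenic_dunn(summary: pd.DataFrame) -> tuple[TestResult, list[PairwiseContrast]]:
    """TE vs intergenic rank comparison (the TE-depletion check)."""
    groups = {}
    for cat in ("intergenic", "TE"):
        vals = summary.loc[summary["category"] == cat, "weighted_level"].dropna().to_numpy()
        if vals.size:
            groups[cat] = vals
    return kruskal_dunn(groups)
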