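"""Cohort-level oncomotif-miRNA signature, clustering and survival analysis.

Given a tumor/normal cohort with paired miRNA (reads-per-million) and mRNA
(log2) expression, the analysis proceeds:

1. sum the expression of the oncomotif seed-family miRNAs per sample;
2. split samples into the top and bottom percentile groups of that sum;
3. derive a differential signature between the groups (two-sided t-test,
   Benjamini-Hochberg FDR, |log2FC| and FDR cutoffs);
4. hierarchically cluster all samples on the signature genes
   (1 - Spearman rho distance, complete linkage, two main clusters);
5. associate the summed expression with genotype (Wilcoxon rank-sum) and the
   cluster membership with relapse-free survival (Kaplan-Meier + log-rank,
   Cox proportional hazards with Efron tie handling).
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .motif import SeedFamily
from .screen import welch_rows

DEFAULT_PCT = 5.0
DEFAULT_FDR_THRESHOLD = 1e-5
DEFAULT_LFC_THRESHOLD = 1.0


def sum_family_expression(
    mirna_expr: pd.DataFrame, family
) -> pd.Series:
    """Per-sample sum of family-member miRNA expression on the native scale.

    ``mirna_expr`` is sample x miRNA; ``family`` is a SeedFamily or an id
    list.  Members missing from the matrix are skipped with a warning; an
    empty effective family is an error.
    """
    ids = list(family.member_ids) if isinstance(family, SeedFamily) else list(family)
    present = [m for m in ids if m in mirna_expr.columns]
    missing = sorted(set(ids) - set(present))
    if missing:
        warnings.warn(f"family members absent from matrix, skipped: {missing}")
    if not present:
        raise ValueError("no family member present in the expression matrix")
    sums = mirna_expr[present].sum(axis=1)
    sums.name = "family_sum"
    return sums


def percentile_groups(
    sums: pd.Series, pct: float = DEFAULT_PCT
) -> tuple[list[str], list[str]]:
    """(high, low) sample id lists: the k = ceil(n * pct/100) largest and
    smallest sums, ties broken by sample id for determinism."""
    if not 0 < pct < 50:
        raise ValueError("pct must be in (0, 50)")
    n = len(sums)
    k = math.ceil(n * pct / 100.0)
    if k < 2:
        raise ValueError(f"group size {k} < 2 (n={n}, pct={pct})")
    order = sorted(sums.index, key=lambda s: (sums[s], s))
    low = sorted(order[:k])
    high = sorted(order[-k:])
    return high, low


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR, mapped back to input order."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values outside [0,1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def derive_signature(
    mrna_expr: pd.DataFrame,
    high,
    low,
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-gene high-vs-low differential table with BH FDR and selection flag.

    ``mrna_expr`` is sample x gene (log2 scale).  log2fc = mean(high) -
    mean(low); selection requires FDR < ``fdr_threshold`` AND |log2fc| >
    ``lfc_threshold``.  Returns a frame with log2fc, p_value, fdr,
    direction (up/down) and ``selected``.
    """
    high, low = list(high), list(low)
    if set(high) & set(low):
        raise ValueError("high and low groups overlap")
    if len(high) < 2 or len(low) < 2:
        raise ValueError("each group needs >=2 samples")
    hi = mrna_expr.loc[high].values.T  # genes x samples
    lo = mrna_expr.loc[low].values.T
    delta, p = welch_rows(lo, hi, equal_var=equal_var)
    fdr = bh_adjust(p)
    out = pd.DataFrame(
        {
            "log2fc": delta,
            "p_value": p,
            "fdr": fdr,
            "direction": np.where(delta >= 0, "up", "down"),
        },
        index=mrna_expr.columns,
    )
    out["selected"] = (out["fdr"] < fdr_threshold) & (
        out["log2fc"].abs() > lfc_threshold
    )
    return out


def spearman_distance_matrix(expr: pd.DataFrame) -> np.ndarray:
    """Pairwise 1 - Spearman rho distance between sample rows.

    Raises on constant sample profiles (undefined rho), naming the sample.
    """
    vals = expr.values
    if np.ptp(vals, axis=1).min() == 0:
        bad = expr.index[np.ptp(vals, axis=1) == 0].tolist()
        raise ValueError(f"constant expression profile for sample(s): {bad}")
    ranks = stats.rankdata(vals, axis=1)
    rho = np.corrcoef(ranks)
    d = 1.0 - rho
    np.fill_diagonal(d, 0.0)
    # numerical symmetry
    return (d + d.T) / 2.0


def hierarchical_cluster(
    expr: pd.DataFrame,
) -> tuple[pd.Series, np.ndarray]:
    """Complete-linkage clustering on 1 - Spearman distance; k=2 main cut.

    ``expr`` is sample x gene, typically restricted to the signature genes.
    Returns (labels, linkage): labels in {"cluster_high", "cluster_low"}
    named so that cluster_high has the larger mean expression over the
    signature genes (the convention matching an activity-driven signature
    in which most selected genes are upregulated), and the scipy linkage
    matrix for dendrogram use.  Ties in the agglomeration follow scipy's
    index-order convention.
    """
    if expr.shape[0] < 2 or expr.shape[1] < 2:
        raise ValueError("need >=2 samples and >=2 genes")
    d = spearman_distance_matrix(expr)
    link = hierarchy.linkage(squareform(d, checks=False), method="complete")
    cut = hierarchy.fcluster(link, t=2, criterion="maxclust")
    labels = pd.Series(cut, index=expr.index)
    means = expr.mean(axis=1).groupby(labels).mean()
    high_cluster = means.idxmax()
    named = labels.map(
        lambda c: "cluster_high" if c == high_cluster else "cluster_low"
    )
    named.name = "cluster"
    return named, link


def genotype_association(
    sums: pd.Series, binary_label: pd.Series, exact_max_n: int = 20
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum of the summed expression between label
    groups; exact enumeration when combined n <= ``exact_max_n``, otherwise
    the tie-corrected normal approximation.  Returns (statistic, p)."""
    label = binary_label.reindex(sums.index)
    groups = label.dropna().unique()
    if len(groups) != 2:
        raise ValueError(f"need exactly two label groups, got {list(groups)}")
    a = sums[label == groups[0]].values
    b = sums[label == groups[1]].values
    if len(a) == 0 or len(b) == 0:
        raise ValueError("one label group is empty")
    method = "exact" if len(a) + len(b) <= exact_max_n else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def km_curve(times, events) -> pd.DataFrame:
    """Kaplan-Meier product-limit curve: S(t) = prod(1 - d_i/n_i)."""
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(times, float), np.asarray(events, int))
    sf = kmf.survival_function_
    return pd.DataFrame(
        {"time": sf.index.values, "survival": sf.iloc[:, 0].values}
    )


def km_logrank(
    times: pd.Series, events: pd.Series, groups: pd.Series
) -> dict:
    """Per-group KM curves plus the two-group log-rank test.

    Returns {"curves": {group: frame}, "chi2": float, "p": float}.  With no
    events anywhere the test is undefined and chi2/p are reported as NaN.
    """
    from lifelines.statistics import logrank_test

    times = pd.Series(np.asarray(times, float), index=groups.index)
    events = pd.Series(np.asarray(events, int), index=groups.index)
    if (times <= 0).any():
        raise ValueError("survival times must be positive")
    levels = sorted(groups.dropna().unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {levels}")
    curves = {
        g: km_curve(times[groups == g], events[groups == g]) for g in levels
    }
    if events.sum() == 0:
        return {"curves": curves, "chi2": float("nan"), "p": float("nan")}
    g0, g1 = levels
    res = logrank_test(
        times[groups == g0],
        times[groups == g1],
        event_observed_A=events[groups == g0],
        event_observed_B=events[groups == g1],
    )
    return {
        "curves": curves,
        "chi2": float(res.test_statistic),
        "p": float(res.p_value),
    }


def cox_regression(
    times: pd.Series,
    events: pd.Series,
    covariates: pd.DataFrame,
    ties: str = "efron",
) -> pd.DataFrame:
    """Cox proportional-hazards fit (partial likelihood, Efron ties default).

    Categorical covariates are expanded to indicator columns; constant
    covariates raise.  Returns the per-covariate summary with hazard ratio,
    95% CI bounds and Wald p.  Non-convergence surfaces as a
    ``ConvergenceError`` from the fitter, with iteration diagnostics.
    """
    from lifelines import CoxPHFitter

    if events.sum() < 1:
        raise ValueError("need at least one event")
    X = pd.get_dummies(covariates, drop_first=True, dtype=float)
    const = [c for c in X.columns if X[c].nunique() <= 1]
    if const:
        raise ValueError(f"constant covariate(s): {const}")
    df = X.copy()
    df["_time"] = np.asarray(times, float)
    df["_event"] = np.asarray(events, int)
    cph = CoxPHFitter()
    cph.fit(df, duration_col="_time", event_col="_event")
    if ties != "efron":
        raise NotImplementedError(
            "only Efron tie handling is exposed; Breslow differs only with "
            "tied event times"
        )
    summ = cph.summary
    return pd.DataFrame(
        {
            "coef": summ["coef"],
            "hazard_ratio": summ["exp(coef)"],
            "ci_lower": summ["exp(coef) lower 95%"],
            "ci_upper": summ["exp(coef) upper 95%"],
            "p_value": summ["p"],
        }
    )
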