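"""Multi-evidence miRNA target integration.

Combines three evidence tiers for each gene after miRNA-mimic transfection:
log2 fold change and t-test p at the mRNA level, the same at the protein
level (for the covered subset), and the number of independent prediction
algorithms (0-9) nominating the gene as a target.  A putative target is a
gene downregulated at mRNA and/or protein level (log2FC < 0, p < 0.05) that
is also predicted by at least five algorithms.

The prediction-consensus stratification ("0", "1-2", "3-4", ">4") and the
ECDF shift of fold changes across strata (two-sample Kolmogorov-Smirnov vs
the no-prediction stratum) quantify whether predicted targets are, as a
group, genuinely repressed.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .screen import welch_rows

STRATA = ("0", "1-2", "3-4", ">4")
MAX_ALGORITHMS = 9
DEFAULT_MIN_PREDICTIONS = 5
DEFAULT_P_THRESHOLD = 0.05


def split_arms(matrix: pd.DataFrame, case_prefix="mimic", ctrl_prefix="ctrl"):
    """Split a combined replicate matrix into (case, control) by column prefix."""
    case = [c for c in matrix.columns if c.startswith(case_prefix)]
    ctrl = [c for c in matrix.columns if c.startswith(ctrl_prefix)]
    if not case or not ctrl:
        raise ValueError(
            f"could not split arms by prefixes {case_prefix!r}/{ctrl_prefix!r}"
        )
    return matrix[case], matrix[ctrl]


def differential_table(
    case_matrix: pd.DataFrame,
    control_matrix: pd.DataFrame,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-gene log2FC (case minus control means) and two-sided t-test p.

    Inputs are log2-scale gene x replicate matrices over the same gene
    universe.  Degenerate zero-variance-in-both-arms rows get the analytic
    limit p (1 if means equal, else 0).
    """
    if not case_matrix.index.equals(control_matrix.index):
        raise ValueError("gene universes differ between arms")
    if case_matrix.shape[1] < 2 or control_matrix.shape[1] < 2:
        raise ValueError("each arm needs >=2 replicates")
    delta, p = welch_rows(
        control_matrix.values, case_matrix.values, equal_var=equal_var
    )
    return pd.DataFrame(
        {"log2fc": delta, "p_value": p}, index=case_matrix.index
    )


def stratify_by_predictions(prediction_count: pd.Series) -> pd.Series:
    """Map 0..9 prediction counts to the consensus strata 0 / 1-2 / 3-4 / >4."""
    counts = prediction_count.astype(int)
    bad = counts[(counts < 0) | (counts > MAX_ALGORITHMS)]
    if len(bad):
        raise ValueError(
            f"prediction counts outside 0..{MAX_ALGORITHMS}: "
            f"{bad.head().to_dict()}"
        )
    bins = pd.cut(
        counts,
        bins=[-0.5, 0.5, 2.5, 4.5, MAX_ALGORITHMS + 0.5],
        labels=STRATA,
    )
    return pd.Series(
        pd.Categorical(bins, categories=STRATA),
        index=prediction_count.index,
        name="stratum",
    )


def ecdf_curve(values: np.ndarray) -> pd.DataFrame:
    """Right-continuous ECDF over the sorted values, reaching exactly 1."""
    x = np.sort(np.asarray(values, dtype=float))
    y = np.arange(1, len(x) + 1) / len(x)
    return pd.DataFrame({"x": x, "cdf": y})


def ecdf_shift(
    fold_changes: pd.Series,
    strata: pd.Series,
    reference: str = "0",
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """ECDF curves per stratum plus two-sample KS statistic/p vs reference.

    Returns (curves, stats) where stats has one row per non-empty,
    non-reference stratum with its KS statistic and asymptotic p-value.
    Empty strata are dropped with a warning.
    """
    strata = strata.reindex(fold_changes.index)
    ref_vals = fold_changes[strata == reference].values
    if len(ref_vals) == 0:
        raise ValueError(f"reference stratum {reference!r} is empty")
    curves: dict[str, pd.DataFrame] = {}
    rows = []
    levels = list(strata.cat.categories) if hasattr(strata, "cat") else sorted(
        strata.dropna().unique()
    )
    for level in levels:
        vals = fold_changes[strata == level].values
        if len(vals) == 0:
            warnings.warn(f"stratum {level!r} is empty; curve omitted")
            continue
        curves[level] = ecdf_curve(vals)
        if level != reference:
            ks = stats.ks_2samp(vals, ref_vals, method="asymp")
            rows.append((level, len(vals), ks.statistic, ks.pvalue))
    shift = pd.DataFrame(
        rows, columns=["stratum", "n", "ks_statistic", "p_value"]
    ).set_index("stratum")
    return curves, shift


def build_evidence_table(
    mrna_diff: pd.DataFrame,
    protein_diff: pd.DataFrame | None,
    prediction_count: pd.Series,
) -> pd.DataFrame:
    """Assemble the per-gene evidence table over the mRNA gene universe.

    Genes absent from the protein tier keep NaN protein columns — they are
    evaluable via the mRNA branch only; missingness is recorded, never
    imputed.
    """
    ev = pd.DataFrame(
        {
            "mrna_log2fc": mrna_diff["log2fc"],
            "mrna_p": mrna_diff["p_value"],
        },
        index=mrna_diff.index,
    )
    if protein_diff is not None:
        ev["protein_log2fc"] = protein_diff["log2fc"].reindex(ev.index)
        ev["protein_p"] = protein_diff["p_value"].reindex(ev.index)
    else:
        ev["protein_log2fc"] = np.nan
        ev["protein_p"] = np.nan
    ev["prediction_count"] = (
        prediction_count.reindex(ev.index).fillna(0).astype(int)
    )
    ev["stratum"] = stratify_by_predictions(ev["prediction_count"])
    return ev


def call_putative_targets(
    evidence: pd.DataFrame,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    min_predictions: int = DEFAULT_MIN_PREDICTIONS,
) -> pd.DataFrame:
    """Flag putative targets and record which evidence branch fired.

    A gene is a putative target iff it is downregulated (log2FC < 0 and
    p < ``p_threshold``) at the mRNA level OR at the protein level (where
    observed), AND its prediction count is >= ``min_predictions``.  Adds
    ``putative_target`` and ``evidence`` (mRNA / protein / both / none)
    columns; returns the augmented table (input is not mutated).
    """
    ev = evidence.copy()
    mrna_down = (ev["mrna_log2fc"] < 0) & (ev["mrna_p"] < p_threshold)
    mrna_down = mrna_down.fillna(False)
    prot_down = (ev["protein_log2fc"] < 0) & (ev["protein_p"] < p_threshold)
    prot_down = prot_down.fillna(False)
    predicted = ev["prediction_count"] >= min_predictions
    ev["putative_target"] = (mrna_down | prot_down) & predicted
    evidence_label = np.select(
        [mrna_down & prot_down, mrna_down, prot_down],
        ["both", "mRNA", "protein"],
        default="none",
    )
    ev["evidence"] = evidence_label
    return ev


def prediction_count_histogram(prediction_count: pd.Series) -> pd.Series:
    """Exact histogram of prediction counts over 0..9 (no smoothing)."""
    counts = prediction_count.astype(int)
    if ((counts < 0) | (counts > MAX_ALGORITHMS)).any():
        raise ValueError(f"prediction counts outside 0..{MAX_ALGORITHMS}")
    return (
        counts.value_counts()
        .reindex(range(MAX_ALGORITHMS + 1), fill_value=0)
        .sort_index()
        .rename("n_genes")
    )
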