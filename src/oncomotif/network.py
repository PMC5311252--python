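"""Pan-cancer miRNA-mRNA correlation profiles and network export.

For each cohort, every gene's mRNA expression is correlated (Pearson) with
the per-sample summed oncomotif-miRNA expression (log2(sum+1) by default).
Putative targets with r below a strict threshold (default -0.15) are called
inverse-correlated — the cohort-level footprint of miRNA-mediated mRNA
degradation.  Cancer types are ranked by the mean correlation over the
curated tumor-suppressor panel, and a curated node/edge file is decorated
with correlation color bins for graph export; edges are copied from the
curation, never inferred.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

DEFAULT_INVERSE_THRESHOLD = -0.15
DEFAULT_COLOR_BINS = (-0.4, -0.15, 0.15, 0.4)


def correlate_genes(
    sums: pd.Series,
    mrna_expr: pd.DataFrame,
    log_scale: bool = True,
    annotation: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene Pearson r between summed family expression and expression.

    ``sums`` is per-sample (native RPM scale; log2(sum+1) is taken when
    ``log_scale``), ``mrna_expr`` sample x gene.  Zero-variance genes get
    r = NaN and a ``defined`` flag of False rather than a fabricated 0.
    """
    if not sums.index.equals(mrna_expr.index):
        sums = sums.reindex(mrna_expr.index)
        if sums.isna().any():
            raise ValueError("sample dimension mismatch between sums and matrix")
    if len(sums) < 3:
        raise ValueError("need >=3 samples for correlation")
    x = np.log2(sums.values + 1.0) if log_scale else sums.values.astype(float)
    if x.std() == 0:
        raise ValueError("summed family expression is constant")
    xc = x - x.mean()
    Y = mrna_expr.values
    Yc = Y - Y.mean(axis=0)
    sy = Yc.std(axis=0)
    defined = sy > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Yc.T @ xc) / (len(x) * sy * xc.std())
    r[~defined] = np.nan
    out = pd.DataFrame(
        {"r": r, "n": len(x), "defined": defined}, index=mrna_expr.columns
    )
    out["role"] = (
        annotation.reindex(out.index).fillna("other")
        if annotation is not None
        else "other"
    )
    return out


def call_inverse_targets(
    profile: pd.DataFrame,
    candidate_set,
    threshold: float = DEFAULT_INVERSE_THRESHOLD,
) -> list[str]:
    """Candidates with Pearson r strictly below ``threshold``."""
    candidates = sorted(set(candidate_set))
    missing = [c for c in candidates if c not in profile.index]
    if missing:
        raise KeyError(f"candidates absent from profile: {missing}")
    r = profile.loc[candidates, "r"]
    return sorted(r.index[r < threshold])


def correlation_ecdf(profile: pd.DataFrame) -> pd.DataFrame:
    """ECDF of defined correlations; undefined-r genes excluded, count noted."""
    r = profile["r"].dropna().values
    if len(r) == 0:
        raise ValueError("no defined correlations")
    n_undef = int(profile["r"].isna().sum())
    x = np.sort(r)
    curve = pd.DataFrame({"r": x, "cdf": np.arange(1, len(x) + 1) / len(x)})
    curve.attrs["n_undefined"] = n_undef
    return curve


def rank_cancers_by_ts_correlation(
    profiles: dict[str, pd.DataFrame], ts_panel
) -> pd.DataFrame:
    """Cancers ordered by mean TS-panel correlation, most negative first.

    Panel genes missing from a profile are dropped with a warning; an empty
    effective panel for a cancer is an error.  Ties break on the cancer
    label.
    """
    panel = list(ts_panel)
    rows = []
    for cancer in sorted(profiles):
        prof = profiles[cancer]
        present = [g for g in panel if g in prof.index]
        dropped = sorted(set(panel) - set(present))
        if dropped:
            warnings.warn(f"{cancer}: panel genes missing, dropped: {dropped}")
        if not present:
            raise ValueError(f"{cancer}: no panel gene present in profile")
        rows.append((cancer, float(prof.loc[present, "r"].mean()), len(present)))
    out = pd.DataFrame(rows, columns=["cancer_type", "mean_ts_r", "n_panel"])
    return out.sort_values(
        ["mean_ts_r", "cancer_type"], kind="mergesort"
    ).reset_index(drop=True)


def _color_bin(r: float, edges) -> str:
    if np.isnan(r):
        return "NA"
    labels = ["strong_negative", "negative", "neutral", "positive", "strong_positive"]
    return labels[int(np.searchsorted(edges, r, side="right"))]


def export_network(
    profile: pd.DataFrame,
    curation: pd.DataFrame,
    bins=DEFAULT_COLOR_BINS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Node table (gene, role, r, color_bin) + edge list from a curation file.

    ``curation`` needs columns gene, role, partner, relation; one row per
    drawn edge (partner/relation may be empty for isolated nodes).  Nodes
    absent from the profile are emitted with r = NA after a warning.
    """
    required = {"gene", "role", "partner", "relation"}
    if not required.issubset(curation.columns):
        raise ValueError(f"curation file must have columns {sorted(required)}")
    nodes = (
        curation[["gene", "role"]].drop_duplicates("gene").reset_index(drop=True)
    )
    missing = [g for g in nodes["gene"] if g not in profile.index]
    if missing:
        warnings.warn(f"curated node(s) absent from profile: {missing}")
    nodes["r"] = [
        float(profile.loc[g, "r"]) if g in profile.index else np.nan
        for g in nodes["gene"]
    ]
    nodes["color_bin"] = [_color_bin(r, bins) for r in nodes["r"]]
    edges = curation.dropna(subset=["partner"])
    edges = edges[edges["partner"].astype(str).str.len() > 0][
        ["gene", "partner", "relation"]
    ].reset_index(drop=True)
    return nodes, edges


def median_family_rpm(
    mirna_expr_by_cancer: dict[str, pd.DataFrame], family
) -> pd.Series:
    """Per-cancer median over samples of the summed family RPM."""
    from .cohort import sum_family_expression

    out = {
        cancer: float(sum_family_expression(expr, family).median())
        for cancer, expr in sorted(mirna_expr_by_cancer.items())
    }
    return pd.Series(out, name="median_family_rpm")
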