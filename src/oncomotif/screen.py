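"""Enrichment/depletion statistics for a pooled miRNA overexpression screen.

The screen transduces a library of miRNA expression vectors (miR-Vecs) into a
cell population, splits it into conditions (baseline Ctrl0, 30-day untreated
Ctrl30, 30-day drug-treated Gef30) in biological triplicate, and sequences
the recovered inserts.  Vectors enriched in Ctrl30 vs Ctrl0 mark miRNAs that
increase proliferation; vectors depleted in Gef30 vs Ctrl30 mark miRNAs that
sensitize to the drug.

Analysis chain: total-read (RPM) normalization -> raw-count minimum-read
filter -> per-vector two-sample t-test on log2(RPM + pseudocount) ->
volcano-style classification at a log2-fold and p cutoff -> intersection of
hit sets across contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_CONDITIONS = ("Ctrl0", "Ctrl30", "Gef30")
DEFAULT_MIN_READS = 300
DEFAULT_PSEUDOCOUNT = 0.5
DEFAULT_LFC_THRESHOLD = 1.5
DEFAULT_P_THRESHOLD = 0.05


@dataclass
class ScreenCountTable:
    """Integer miR-Vec x sample read counts with a condition/replicate design.

    ``counts``: DataFrame, rows = vector ids (unique), columns = sample names.
    ``design``: maps each column name to a condition label.  Columns named
    ``Condition_rep#`` are parsed automatically when no design is given.
    """

    counts: pd.DataFrame
    design: dict[str, str]

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dupes = self.counts.index[self.counts.index.duplicated()].unique()
            raise ValueError(f"duplicate vector ids: {list(dupes)}")
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        missing = [c for c in self.counts.columns if c not in self.design]
        if missing:
            raise ValueError(f"columns missing from design: {missing}")
        totals = self.counts.sum(axis=0)
        zero = totals.index[totals == 0].tolist()
        if zero:
            raise ValueError(f"zero-total sample column(s): {zero}")
        reps = pd.Series(self.design).value_counts()
        thin = reps.index[reps < 2].tolist()
        if thin:
            raise ValueError(f"condition(s) with fewer than 2 replicates: {thin}")

    @classmethod
    def from_frame(cls, counts: pd.DataFrame, design: dict[str, str] | None = None):
        if design is None:
            design = {c: c.rsplit("_rep", 1)[0] for c in counts.columns}
        return cls(counts=counts, design=design)

    def condition_columns(self, condition: str) -> list[str]:
        cols = [c for c in self.counts.columns if self.design[c] == condition]
        if not cols:
            raise KeyError(f"unknown condition label: {condition!r}")
        return cols

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for c in self.counts.columns:
            cond = self.design[c]
            if cond not in seen:
                seen.append(cond)
        return seen


def normalize_counts(table: ScreenCountTable) -> pd.DataFrame:
    """Scale every sample column to reads-per-million (column sum 1e6)."""
    totals = table.counts.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValueError(f"zero-total sample column(s): {zero}")
    return table.counts / totals * 1e6


def filter_min_reads(
    table: ScreenCountTable, threshold: int = DEFAULT_MIN_READS
) -> pd.Series:
    """Flag vectors sequenced >= ``threshold`` times in every replicate of at
    least one condition.  The rule operates on raw counts, before any
    normalization.  Returns a boolean Series indexed by vector id."""
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    passed = pd.Series(False, index=table.counts.index)
    for cond in table.conditions:
        cols = table.condition_columns(cond)
        passed |= (table.counts[cols] >= threshold).all(axis=1)
    passed.name = "passed_filter"
    return passed


def welch_rows(
    a: np.ndarray, b: np.ndarray, equal_var: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise two-sided two-sample t-test p-values, with analytic limits for
    degenerate rows where both groups have zero variance (p=1 if the means
    agree, p=0 otherwise).  Returns (delta_means, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    delta = b.mean(axis=1) - a.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(b, a, axis=1, equal_var=equal_var)
        p = np.asarray(res.pvalue, dtype=float)
    degenerate = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    p[degenerate & (delta == 0)] = 1.0
    p[degenerate & (delta != 0)] = 0.0
    return delta, p


def enrichment_test(
    norm: pd.DataFrame,
    table: ScreenCountTable,
    contrast: tuple[str, str],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-vector log2 ratio and t-test p for contrast (A, B), reported as B/A.

    Replicate values enter as log2(RPM + pseudocount); log2_ratio is
    mean(log2 B) - mean(log2 A); p from a two-sided two-sample t-test over
    replicates (Welch by default, pooled-variance Student with
    ``equal_var=True``).  Rows where both groups are exactly constant carry
    the analytic limit p (see :func:`welch_rows`) and a ``zero_variance``
    flag so they can be excluded downstream.
    """
    cond_a, cond_b = contrast
    cols_a = table.condition_columns(cond_a)
    cols_b = table.condition_columns(cond_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError(f"contrast {contrast} needs >=2 replicates per condition")
    la = np.log2(norm[cols_a].values + pseudocount)
    lb = np.log2(norm[cols_b].values + pseudocount)
    delta, p = welch_rows(la, lb, equal_var=equal_var)
    zero_var = (la.var(axis=1) == 0) & (lb.var(axis=1) == 0)
    return pd.DataFrame(
        {
            "log2_ratio": delta,
            "p_value": p,
            "zero_variance": zero_var,
            "mean_log2_a": la.mean(axis=1),
            "mean_log2_b": lb.mean(axis=1),
        },
        index=norm.index,
    )


def classify_hits(
    results: pd.DataFrame,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> pd.Series:
    """Volcano classification: enriched iff log2_ratio >= lfc and p < alpha,
    depleted iff log2_ratio <= -lfc and p < alpha, else neutral.  Fold cutoffs
    are inclusive, the p cutoff strict, matching the cutoff phrasing
    "1.5 log2, P<0.05"."""
    if lfc_threshold < 0 or p_threshold < 0:
        raise ValueError("thresholds must be nonnegative")
    lfc = results["log2_ratio"]
    p = results["p_value"]
    cls = pd.Series("neutral", index=results.index, name="class")
    cls[(lfc >= lfc_threshold) & (p < p_threshold)] = "enriched"
    cls[(lfc <= -lfc_threshold) & (p < p_threshold)] = "depleted"
    return cls


def intersect_hits(proliferation_hits, sensitization_hits) -> list[str]:
    """Order-stable (sorted by vector id) intersection of two hit sets."""
    return sorted(set(proliferation_hits) & set(sensitization_hits))


def analyze_screen(
    table: ScreenCountTable,
    contrasts: list[tuple[str, str]] | None = None,
    min_reads: int = DEFAULT_MIN_READS,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Full chain: normalize, filter, test and classify every contrast.

    Default contrasts are (Ctrl0, Ctrl30) — proliferation — and
    (Ctrl30, Gef30) — drug sensitization.  Classes are assigned only on
    vectors passing the raw-count filter; filtered-out vectors keep their
    statistics but class NA.  Output columns are suffixed ``_B_vs_A``.
    """
    if contrasts is None:
        conds = table.conditions
        contrasts = [(conds[i], conds[i + 1]) for i in range(len(conds) - 1)]
    norm = normalize_counts(table)
    passed = filter_min_reads(table, threshold=min_reads)
    out = pd.DataFrame({"passed_filter": passed})
    for cond_a, cond_b in contrasts:
        res = enrichment_test(
            norm, table, (cond_a, cond_b), pseudocount=pseudocount,
            equal_var=equal_var,
        )
        cls = classify_hits(res, lfc_threshold, p_threshold)
        cls = cls.where(passed, other=pd.NA)
        tag = f"{cond_b}_vs_{cond_a}"
        out[f"log2_ratio_{tag}"] = res["log2_ratio"]
        out[f"p_value_{tag}"] = res["p_value"]
        out[f"neg_log10_p_{tag}"] = -np.log10(res["p_value"].clip(lower=1e-300))
        out[f"class_{tag}"] = cls
    return out


# --- phenotype summary formulas -------------------------------------------


@dataclass(frozen=True)
class CellCyclePhases:
    """Cell-cycle phase readout (percent or fraction units, used consistently)."""

    g0g1: float
    s: float
    g2m: float

    def __post_init__(self) -> None:
        if min(self.g0g1, self.s, self.g2m) < 0:
            raise ValueError("phase values must be nonnegative")


def proliferation_index(phases: CellCyclePhases) -> float:
    """(S + G2/M) / G0G1 — the ratio of cycling to resting cells."""
    if phases.g0g1 == 0:
        raise ZeroDivisionError("G0/G1 fraction is zero; index undefined")
    return (phases.s + phases.g2m) / phases.g0g1


@dataclass(frozen=True)
class QpcrMeasurement:
    """One replicate's quantitation cycles for target and reference RNA."""

    cq_target: float
    cq_reference: float

    def __post_init__(self) -> None:
        for v in (self.cq_target, self.cq_reference):
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"Cq must be finite and positive, got {v}")

    @property
    def delta_cq(self) -> float:
        return self.cq_target - self.cq_reference


def delta_delta_cq(
    measurements: list[QpcrMeasurement], reference_mean_dcq: float
) -> tuple[list[float], float]:
    """Per-replicate delta-Cq (target minus reference Cq) and the summary
    delta-delta-Cq, computed as mean(delta-Cq) / reference mean delta-Cq
    (ratio normalization to the non-targeting control)."""
    if not measurements:
        raise ValueError("no replicate measurements")
    if reference_mean_dcq == 0:
        raise ZeroDivisionError("reference mean delta-Cq is zero")
    dcqs = [m.delta_cq for m in measurements]
    return dcqs, float(np.mean(dcqs)) / reference_mean_dcq
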