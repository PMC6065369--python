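"""Volcano screen of a curated gene list across grouped expression datasets.

For each gene in a curated list (e.g. 285 actin cytoskeletal regulators),
expression is compared between two sample groups (e.g. ER+ vs ER- tumors):
fold change is the ratio of group means (reported as log2) and significance
comes from Welch's two-sample test on log-scale intensities.  A gene is a
hit when |fold change| is at least twofold (in either direction) and
p <= 0.05; no multiple-testing correction is applied by default, matching
the per-gene threshold rule, with Benjamini-Hochberg available as an
option.  Recurrence of hits across independent datasets ranks candidate
regulators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ExpressionMatrix", "VolcanoResult", "volcano_screen",
           "cross_dataset_tally"]


@dataclass
class ExpressionMatrix:
    """Genes x samples intensity table with per-sample group labels.

    values: DataFrame indexed by gene, columns are samples (linear-scale
    intensities, strictly positive).  groups: Series mapping sample ->
    group label (exactly two groups for a screen).  gene_list: curated
    subset to screen; genes missing from the matrix are reported, not
    fatal.
    """

    values: pd.DataFrame
    groups: pd.Series
    gene_list: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not set(self.values.columns) <= set(self.groups.index):
            raise ValueError("every sample column needs a group label")

    @property
    def missing_genes(self) -> list[str]:
        return [g for g in self.gene_list if g not in self.values.index]

    def group_names(self) -> list[str]:
        return list(pd.unique(self.groups[self.values.columns]))


@dataclass
class VolcanoResult:
    """Per-gene screen output, sorted by descending significance."""

    table: pd.DataFrame  # gene, log2_fc, p, hit, direction, flagged
    fc_threshold: float
    p_threshold: float
    missing_genes: list[str] = field(default_factory=list)

    @property
    def hits(self) -> pd.DataFrame:
        return self.table[self.table["hit"]]


def volcano_screen(expr: ExpressionMatrix, fc_threshold: float = 2.0,
                   p_threshold: float = 0.05,
                   min_samples_per_group: int = 2,
                   group_order: tuple[str, str] | None = None,
                   fdr: bool = False) -> VolcanoResult:
    """Two-group differential screen with fold-change and p thresholds.

    Fold change per gene is mean(group1) / mean(group2) on the linear
    scale, reported as log2; p is Welch's unequal-variance t test on log2
    intensities.  `group_order` fixes (numerator, denominator); by default
    groups are taken in order of first appearance.  A gene is a hit iff
    |log2 fc| >= log2(fc_threshold) and p <= p_threshold.  Genes with zero
    variance in both groups get p = NaN and a `flagged` mark rather than
    being dropped.  With fdr=True the p threshold is applied to
    Benjamini-Hochberg adjusted values.
    """
    names = list(group_order) if group_order else expr.group_names()
    if len(names) != 2 or len(set(names)) != 2:
        raise ValueError(f"need exactly two groups, got {names}")
    if not set(names) <= set(expr.groups[expr.values.columns]):
        raise ValueError(f"unknown group in {names}")
    g1 = [s for s in expr.values.columns if expr.groups[s] == names[0]]
    g2 = [s for s in expr.values.columns if expr.groups[s] == names[1]]
    if len(g1) < min_samples_per_group or len(g2) < min_samples_per_group:
        raise ValueError("each group needs at least "
                         f"{min_samples_per_group} samples")
    genes = [g for g in (expr.gene_list or list(expr.values.index))
             if g in expr.values.index]
    sub = expr.values.loc[genes]
    a = sub[g1].to_numpy(dtype=float)
    b = sub[g2].to_numpy(dtype=float)
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("intensities must be strictly positive")

    log2fc = np.log2(a.mean(axis=1) / b.mean(axis=1))
    la, lb = np.log2(a), np.log2(b)
    var_zero = (la.var(axis=1) == 0) & (lb.var(axis=1) == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        _, p = stats.ttest_ind(la, lb, axis=1, equal_var=False)
    p = np.where(var_zero, np.nan, p)

    p_eff = p.copy()
    if fdr:
        ok = ~np.isnan(p)
        p_eff[ok] = _bh_adjust(p[ok])
    hit = (~np.isnan(p_eff)) & (p_eff <= p_threshold) & \
        (np.abs(log2fc) >= np.log2(fc_threshold))
    table = pd.DataFrame({
        "gene": genes,
        "log2_fc": log2fc,
        "p": p,
        "p_adj": p_eff if fdr else p,
        "hit": hit,
        "direction": np.where(log2fc > 0, "up", np.where(log2fc < 0, "down", "none")),
        "flagged": var_zero,
    })
    table = table.sort_values("p", na_position="last", kind="mergesort")
    table = table.reset_index(drop=True)
    return VolcanoResult(table=table, fc_threshold=fc_threshold,
                         p_threshold=p_threshold,
                         missing_genes=expr.missing_genes)


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def cross_dataset_tally(results: list[VolcanoResult]) -> pd.DataFrame:
    """Per-gene hit recurrence across k independent datasets.

    Counts in how many datasets each gene passed both thresholds; ranked by
    recurrence, ties broken by mean -log10 p across the datasets where the
    gene was tested.
    """
    if not results:
        raise ValueError("need at least one dataset result")
    counts: dict[str, int] = {}
    neglogp: dict[str, list[float]] = {}
    for res in results:
        for _, row in res.table.iterrows():
            g = row["gene"]
            counts.setdefault(g, 0)
            neglogp.setdefault(g, [])
            if row["hit"]:
                counts[g] += 1
            if not np.isnan(row["p"]) and row["p"] > 0:
                neglogp[g].append(-np.log10(row["p"]))
    df = pd.DataFrame({
        "gene": list(counts),
        "recurrence": [counts[g] for g in counts],
        "mean_neglog10_p": [float(np.mean(neglogp[g])) if neglogp[g] else 0.0
                            for g in counts],
    })
    df = df.sort_values(["recurrence", "mean_neglog10_p"],
                        ascending=[False, False], kind="mergesort")
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)
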