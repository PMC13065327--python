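"""Group comparisons and summary statistics on normalised abundances.

Covers the boxplot-style comparisons (two-sided Wilcoxon rank-sum with
Bonferroni adjustment over the comparisons drawn on one panel), per-site
bar-plot t-tests, per-protein phospho-abundance sums across conditions,
maximum per-site ranges across conditions, and the ranked non-kinetochore
protein lists used as GO-enrichment input.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffenrich import adjust_pvalues
from .model import AnnotationTable, PhosphoMatrix, SampleDesign

logger = logging.getLogger(__name__)


def wilcoxon_group_compare(
    values: Mapping, comparisons: Sequence[tuple], exact_max_n: int = 10
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum test for each listed pair of groups.

    Uses the exact null distribution when both group sizes are
    <= ``exact_max_n`` and there are no ties across the pooled sample;
    otherwise the normal approximation with tie and continuity correction.
    P-values are Bonferroni-adjusted over the listed comparisons.
    """
    rows = []
    for key_a, key_b in comparisons:
        a = np.asarray(values[key_a], dtype=float)
        b = np.asarray(values[key_b], dtype=float)
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        if a.size == 0 or b.size == 0:
            raise ValueError(f"empty group in comparison ({key_a}, {key_b})")
        pooled = np.concatenate([a, b])
        tie_free = np.unique(pooled).size == pooled.size
        exact = tie_free and a.size <= exact_max_n and b.size <= exact_max_n
        method = "exact" if exact else "asymptotic"
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method=method, use_continuity=not exact
        )
        rows.append(
            {
                "group_a": key_a,
                "group_b": key_b,
                "n_a": a.size,
                "n_b": b.size,
                "w_stat": float(res.statistic),
                "p_value": float(res.pvalue),
                "method": method,
            }
        )
    out = pd.DataFrame(rows)
    out["p_adjusted"] = adjust_pvalues(out["p_value"], method="bonferroni")
    return out


def ttest_site_compare(
    values: Mapping, comparisons: Sequence[tuple]
) -> pd.DataFrame:
    """Two-sided pooled-variance t-test per listed pair of conditions for a
    single site's per-replicate abundances; Bonferroni over the panel.
    Pairs with fewer than 2 non-missing values in a group are reported
    untested (NaN statistics)."""
    rows = []
    for key_a, key_b in comparisons:
        a = np.asarray(values.get(key_a, ()), dtype=float)
        b = np.asarray(values.get(key_b, ()), dtype=float)
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        row = {"group_a": key_a, "group_b": key_b, "n_a": a.size, "n_b": b.size}
        if a.size < 2 or b.size < 2:
            row.update(t_stat=np.nan, p_value=np.nan)
        else:
            res = stats.ttest_ind(a, b, equal_var=True)
            t = 0.0 if a.mean() == b.mean() else float(res.statistic)
            p = 1.0 if a.mean() == b.mean() else float(res.pvalue)
            row.update(t_stat=t, p_value=p)
        rows.append(row)
    out = pd.DataFrame(rows)
    out["p_adjusted"] = adjust_pvalues(out["p_value"], method="bonferroni")
    return out


def condition_means(
    matrix, design: SampleDesign, fraction: str, tag: str = "tag"
) -> pd.DataFrame:
    """Row x condition table of means over that condition's non-missing
    replicate columns; NaN where a condition has no detections."""
    cols_by_cond = {
        key[0]: [c for c in cols if c in matrix.data.columns]
        for key, cols in design.replicate_groups(fraction).items()
        if key[1] == tag
    }
    out = {
        cond: matrix.data[cols].mean(axis=1, skipna=True)
        for cond, cols in cols_by_cond.items()
        if cols
    }
    return pd.DataFrame(out)


def protein_phospho_sum(
    phospho: PhosphoMatrix,
    design: SampleDesign,
    tag: str = "tag",
    proteins: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Total phospho-site abundance per protein and condition.

    Cell (protein, condition) is the sum over the protein's sites of the
    mean across that condition's non-missing replicates; a site undetected
    in a condition contributes nothing (no zeros fabricated under the
    no-imputation rule). Adds an all-stage ``total`` column and a ``rank``
    by descending total; proteins with no detected sites score 0 and rank
    last.
    """
    means = condition_means(phospho, design, "PE", tag=tag)
    by_protein = means.groupby(phospho.site_proteins.to_numpy()).sum(min_count=1)
    if proteins is not None:
        by_protein = by_protein.reindex(proteins)
    by_protein = by_protein.fillna(0.0)
    by_protein["total"] = by_protein.sum(axis=1)
    by_protein = by_protein.sort_values("total", ascending=False)
    by_protein["rank"] = np.arange(1, len(by_protein) + 1)
    by_protein.index.name = "protein"
    return by_protein


def phospho_site_max_range(
    phospho: PhosphoMatrix, design: SampleDesign, tag: str = "tag"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-site range of per-condition means, and the per-protein summary.

    A site's range is max - min of its per-condition means over conditions
    with a defined mean; sites detected in fewer than two conditions are
    excluded (counted and logged). The protein table carries the median of
    its sites' ranges, ranked descending.
    """
    means = condition_means(phospho, design, "PE", tag=tag)
    n_cond = means.notna().sum(axis=1)
    excluded = int((n_cond < 2).sum())
    if excluded:
        logger.info("%d site(s) detected in <2 conditions excluded from ranges",
                    excluded)
    defined = means[n_cond >= 2]
    site_table = pd.DataFrame(
        {
            "protein": phospho.site_proteins.loc[defined.index],
            "range": defined.max(axis=1) - defined.min(axis=1),
            "n_conditions": n_cond[defined.index],
        }
    )
    site_table.index.name = "site"
    protein_table = (
        site_table.groupby("protein")["range"]
        .agg(median_range="median", n_sites="size")
        .sort_values("median_range", ascending=False)
    )
    protein_table["rank"] = np.arange(1, len(protein_table) + 1)
    protein_table.attrs["n_excluded_sites"] = excluded
    return site_table, protein_table


def ranked_list_builder(
    results: Sequence[pd.DataFrame],
    annotation: AnnotationTable,
    top_n: int = 50,
) -> list[str]:
    """Ordered protein list for GO input from a focal stage's pairwise
    comparisons.

    For each comparison table: exclude annotated kinetochore proteins and
    untested rows, rank by descending log2 fold change, take the top
    ``top_n`` (all, with a warning, if fewer are available); concatenate
    the lists and deduplicate preserving first occurrence.
    """
    combined: list[str] = []
    for res in results:
        sub = res.dropna(subset=["log2_fold_change"])
        sub = sub[[not annotation.is_kinetochore(p) for p in sub.index]]
        sub = sub.sort_values("log2_fold_change", ascending=False, kind="stable")
        if len(sub) < top_n:
            logger.warning("only %d rows available for top-%d list", len(sub), top_n)
        combined.extend(sub.index[:top_n].tolist())
    return list(dict.fromkeys(combined))
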