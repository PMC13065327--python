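"""Pairwise differential-enrichment statistics behind the volcano plots.

Per-row two-sample contrasts on log2 intensities: tag vs no-tag IPs within
a condition (specific enrichment over background) and stage vs stage on
bait-scaled values (stoichiometry changes). The default test is an
empirical-Bayes moderated t: per-row pooled variances ``s_g^2`` with
residual df ``d_g`` are shrunk toward a prior ``s_0^2`` with prior df
``d_0``,

    s_tilde^2 = (d_0 s_0^2 + d_g s_g^2) / (d_0 + d_g),
    t = (mean_A - mean_B) / (s_tilde * sqrt(1/n_A + 1/n_B)),  df = d_g + d_0,

with ``(d_0, s_0^2)`` estimated from the ensemble of row variances by
moment matching on the scaled-F model (matching the mean and variance of
``log s_g^2`` via digamma/trigamma, the classic limma estimator). Ordinary
pooled and Welch t are available as alternatives. Rows with fewer than two
non-missing values in either group are reported untested (NaN statistics)
rather than dropped, preserving row accounting.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .model import AnnotationTable, IntensityMatrix

logger = logging.getLogger(__name__)

RESULT_COLUMNS = ["log2_fold_change", "t_stat", "p_value", "p_adjusted", "n_a", "n_b"]


def log2_transform(matrix: IntensityMatrix) -> IntensityMatrix:
    """Elementwise log2; missing propagated; non-positive values raise."""
    vals = matrix.data.to_numpy()
    if np.nanmin(vals, initial=1.0) <= 0:
        raise ValueError("log2_transform requires strictly positive values")
    out = np.log2(matrix.data)
    return matrix.with_data(out, provenance=matrix.provenance + "+log2",
                            log_scale=True)


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (y > 0)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_scaled_f(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Estimate (prior df d0, prior variance s0^2) for the moderated t.

    Under the hierarchical model, d_g * s_g^2 / (d_0-shrunk variance)
    follows a scaled F; the estimator matches the first two moments of
    ``log s_g^2`` using digamma/trigamma corrections. Rows with
    non-positive variance or zero df are excluded from the fit. Returns
    ``d0 = inf`` when the observed spread of log-variances is no larger
    than sampling noise (complete shrinkage).
    """
    ok = np.isfinite(s2) & (s2 > 0) & (df > 0)
    s2, df = s2[ok], df[ok]
    n = s2.size
    if n == 0:
        raise ValueError("no rows with positive variance to fit")
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(e.mean())
    if n < 2:
        return np.inf, float(np.exp(e_mean))
    e_var = float(((e - e_mean) ** 2).sum() / (n - 1))
    e_var -= float(np.mean(special.polygamma(1, df / 2.0)))
    if e_var <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * trigamma_inverse(e_var)
    s0_2 = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_2


def differential_test(
    matrix: IntensityMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    method: str = "moderated_t",
    prior_df: float | None = None,
    adjust: str = "bonferroni",
) -> pd.DataFrame:
    """Per-row two-sample contrast A vs B on a log2-scale matrix.

    Returns a table indexed by row id with columns ``log2_fold_change``
    (mean_A - mean_B), ``t_stat``, ``p_value``, ``p_adjusted``, ``n_a``,
    ``n_b``. The multiple-testing family is the rows tested within this
    contrast. ``prior_df`` overrides the estimated d0 for the moderated t
    (0 reproduces the ordinary pooled t exactly).
    """
    if method not in ("moderated_t", "ordinary_t", "welch_t"):
        raise ValueError(f"unknown test method: {method!r}")
    group_a, group_b = list(group_a), list(group_b)
    for name, cols in (("A", group_a), ("B", group_b)):
        absent = [c for c in cols if c not in matrix.data.columns]
        if absent:
            raise ValueError(f"group {name}: column(s) not in matrix: {absent}")
        if len(cols) < 2:
            raise ValueError(f"group {name} has fewer than 2 samples")

    A = matrix.data[group_a].to_numpy(float)
    B = matrix.data[group_b].to_numpy(float)
    n_a, mean_a, var_a = _group_stats(A)
    n_b, mean_b, var_b = _group_stats(B)
    tested = (n_a >= 2) & (n_b >= 2)
    fc = mean_a - mean_b

    t_stat = np.full(len(fc), np.nan)
    p_value = np.full(len(fc), np.nan)

    if method == "welch_t":
        with np.errstate(invalid="ignore", divide="ignore"):
            se2 = var_a / n_a + var_b / n_b
            t_raw = fc / np.sqrt(se2)
            df = se2**2 / (
                (var_a / n_a) ** 2 / (n_a - 1) + (var_b / n_b) ** 2 / (n_b - 1)
            )
        t_stat[tested] = t_raw[tested]
        p_value[tested] = _two_sided_p(t_raw[tested], df[tested])
    else:
        df = (n_a + n_b - 2).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            s2 = ((n_a - 1) * var_a + (n_b - 1) * var_b) / df
        if method == "moderated_t":
            if prior_df is None:
                d0, s0_2 = fit_scaled_f(s2[tested], df[tested])
            elif prior_df == 0:
                d0, s0_2 = 0.0, 1.0
            else:
                d0 = float(prior_df)
                _, s0_2 = fit_scaled_f(s2[tested], df[tested])
            with np.errstate(invalid="ignore", divide="ignore"):
                if np.isinf(d0):
                    s2_tilde = np.full_like(s2, s0_2)
                    df_mod = np.full_like(df, np.inf)
                else:
                    s2_tilde = (d0 * s0_2 + df * s2) / (d0 + df)
                    df_mod = df + d0
        else:
            s2_tilde, df_mod = s2, df
        with np.errstate(invalid="ignore", divide="ignore"):
            t_raw = fc / np.sqrt(s2_tilde * (1.0 / n_a + 1.0 / n_b))
        t_raw = np.where(fc == 0, 0.0, t_raw)  # 0/0 for identical groups
        t_stat[tested] = t_raw[tested]
        p_value[tested] = _two_sided_p(t_raw[tested], df_mod[tested])

    p_adjusted = adjust_pvalues(p_value, method=adjust)
    out = pd.DataFrame(
        {
            "log2_fold_change": np.where(tested, fc, np.nan),
            "t_stat": t_stat,
            "p_value": p_value,
            "p_adjusted": p_adjusted,
            "n_a": n_a,
            "n_b": n_b,
        },
        index=matrix.data.index,
    )
    logger.info("differential test (%s): %d of %d rows tested",
                method, int(tested.sum()), len(out))
    return out


def _group_stats(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-row count, mean and unbiased variance over non-missing values,
    without warning on empty/short rows (mean NaN for n=0, var NaN for n<2)."""
    n = np.sum(~np.isnan(X), axis=1)
    total = np.nansum(X, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n > 0, total / np.maximum(n, 1), np.nan)
        ss = np.nansum((X - mean[:, None]) ** 2, axis=1)
        var = np.where(n >= 2, ss / np.maximum(n - 1, 1), np.nan)
    return n, mean, var


def _two_sided_p(t: np.ndarray, df: np.ndarray) -> np.ndarray:
    p = np.full(np.shape(t), np.nan)
    finite_df = np.isfinite(df)
    p = np.where(finite_df, 2.0 * stats.t.sf(np.abs(t), np.where(finite_df, df, 1.0)),
                 2.0 * stats.norm.sf(np.abs(t)))
    return np.minimum(p, 1.0)


def adjust_pvalues(p: Sequence[float] | np.ndarray, method: str = "bonferroni"):
    """Multiple-testing adjustment preserving input order; NaN entries are
    excluded from the family and returned as NaN. Methods: ``bonferroni``
    (min(1, m*p)) and ``BH`` step-up."""
    p = np.asarray(p, dtype=float)
    if np.nanmin(p, initial=0.0) < 0 or np.nanmax(p, initial=0.0) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.sum():
        sm_method = {"bonferroni": "bonferroni", "BH": "fdr_bh"}.get(method)
        if sm_method is None:
            raise ValueError(f"unknown adjustment method: {method!r}")
        out[ok] = multipletests(p[ok], method=sm_method)[1]
    return out


def foldchange_heatmap_table(
    results_by_condition: Mapping[str, pd.DataFrame],
    annotation: AnnotationTable,
) -> pd.DataFrame:
    """Protein x condition table of tag-vs-no-tag log2 fold changes,
    restricted to annotated kinetochore proteins; NaN where untested."""
    cols = {}
    for condition, res in results_by_condition.items():
        cols[condition] = res["log2_fold_change"]
    table = pd.DataFrame(cols)
    keep = [p for p in table.index if annotation.is_kinetochore(p)]
    return table.loc[keep]
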