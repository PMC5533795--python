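"""Per-cohort differential scoring of candidate genes.

Each candidate gene is scored with a two-sample Welch-type t statistic
contrasting tumor against normal expression,

    t_g = (X̄_g1 − X̄_g2) / sqrt(S²_g1/n_1 + S²_g2/n_2),

with group means X̄_gi and unbiased (n−1 denominator) group variances S²_gi.
Group 1 is tumor, group 2 normal, so t > 0 means higher expression in tumor.
Two-sided p-values use the t reference distribution with Welch–Satterthwaite
degrees of freedom and are corrected across the candidate set with the
Benjamini–Hochberg step-up procedure.  Genes passing the adjusted-p cutoff are
the cohort's "diagnostic diff-genes" and seed the downstream network search.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats


class UndefinedStatisticError(ValueError):
    """Both group variances are zero: the t statistic is undefined."""


def welch_t(x1, x2) -> float:
    """Welch two-sample t statistic (group 1 minus group 2).

    Both samples need at least two observations.  When both sample variances
    are exactly zero the statistic is undefined and
    :class:`UndefinedStatisticError` is raised rather than returning ±inf.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.size < 2 or x2.size < 2:
        raise ValueError("each group needs at least 2 observations")
    v1 = x1.var(ddof=1)
    v2 = x2.var(ddof=1)
    if v1 == 0.0 and v2 == 0.0:
        raise UndefinedStatisticError("both group variances are zero")
    return float((x1.mean() - x2.mean()) / np.sqrt(v1 / x1.size + v2 / x2.size))


def welch_df(v1: float, n1: int, v2: float, n2: int) -> float:
    """Welch–Satterthwaite effective degrees of freedom."""
    a, b = v1 / n1, v2 / n2
    num = (a + b) ** 2
    den = a**2 / (n1 - 1) + b**2 / (n2 - 1)
    if den == 0.0:
        raise UndefinedStatisticError("zero variances: df undefined")
    return float(num / den)


def t_to_p(t: float, n1: int, n2: int, v1: float | None = None, v2: float | None = None) -> float:
    """Two-sided p-value for a t statistic.

    With the group variances supplied the reference distribution uses
    Welch–Satterthwaite degrees of freedom; without them the equal-variance
    df ``n1 + n2 − 2`` is used.  Symmetric in the sign of ``t``.
    """
    if not np.isfinite(t):
        raise ValueError("t must be finite")
    if v1 is None or v2 is None:
        df = n1 + n2 - 2
    else:
        df = welch_df(v1, n1, v2, n2)
    return float(2.0 * stats.t.sf(abs(t), df))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    For sorted p(1) ≤ … ≤ p(m):  adj(i) = min_{j≥i} min(1, p(j)·m/j).
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def score_genes(dataset, candidate_genes) -> pd.DataFrame:
    """Score every candidate gene in one cohort.

    Returns a DataFrame indexed by gene with columns ``t``, ``p``, ``p_adj``,
    ``mean_tumor``, ``mean_normal``, ``var_tumor``, ``var_normal``,
    ``n_tumor``, ``n_normal`` and a boolean ``degenerate`` flag for genes
    whose statistic is undefined (both variances zero); such genes keep NaN
    statistics rather than being silently dropped.  Candidates absent from
    the matrix are reported via a warning and skipped.  BH adjustment is
    applied within the candidate set.
    """
    candidates = [str(g).upper() for g in candidate_genes]
    present = [g for g in candidates if g in dataset.values.index]
    absent = sorted(set(candidates) - set(present))
    if absent:
        warnings.warn(
            f"{dataset.name}: {len(absent)} candidate genes absent from the "
            f"matrix (e.g. {absent[:3]}); skipped",
            stacklevel=2,
        )
    tumor, normal = dataset.group_matrices()
    n1, n2 = tumor.shape[1], normal.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError(
            f"{dataset.name}: fewer than 2 samples in a group "
            f"(tumor={n1}, normal={n2}); cohort rejected"
        )
    x1 = tumor.loc[present].to_numpy(dtype=float)
    x2 = normal.loc[present].to_numpy(dtype=float)
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    v1, v2 = x1.var(axis=1, ddof=1), x2.var(axis=1, ddof=1)
    se = np.sqrt(v1 / n1 + v2 / n2)
    degenerate = se == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(degenerate, np.nan, (m1 - m2) / np.where(degenerate, 1.0, se))
        a, b = v1 / n1, v2 / n2
        df = (a + b) ** 2 / (a**2 / (n1 - 1) + b**2 / (n2 - 1))
        p = np.where(degenerate, np.nan, 2.0 * stats.t.sf(np.abs(t), df))
    p_adj = np.full(len(present), np.nan)
    ok = ~degenerate
    if ok.any():
        p_adj[ok] = bh_adjust(p[ok])
    if degenerate.any():
        warnings.warn(
            f"{dataset.name}: {int(degenerate.sum())} genes with zero variance "
            "in both groups; statistic undefined, flagged",
            stacklevel=2,
        )
    table = pd.DataFrame(
        {
            "t": t,
            "p": p,
            "p_adj": p_adj,
            "mean_tumor": m1,
            "mean_normal": m2,
            "var_tumor": v1,
            "var_normal": v2,
            "n_tumor": n1,
            "n_normal": n2,
            "degenerate": degenerate,
        },
        index=pd.Index(present, name="gene"),
    )
    table.attrs["cohort"] = dataset.name
    table.attrs["absent_candidates"] = absent
    return table


def select_diagnostic_genes(table: pd.DataFrame, alpha: float = 0.05) -> list:
    """Genes with BH-adjusted p below ``alpha``, ranked by descending \\|t\\|."""
    sig = table[(table["p_adj"] < alpha) & ~table["degenerate"]]
    sig = sig.reindex(sig["t"].abs().sort_values(ascending=False, kind="stable").index)
    return list(sig.index)


def write_score_table(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, sep="\t", index_label="gene", float_format="%.6g")


def read_score_table(path: str) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", index_col="gene")
    table["degenerate"] = table["degenerate"].astype(bool)
    return table
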