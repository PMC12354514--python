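"""Paired model comparison and population-level summaries.

Per-leaf RMSE and AIC values of the three variants are compared with the
two-sided Wilcoxon signed-rank test (alpha = 0.05, no multiplicity
correction across the three pairs).  Population summaries report, per
variant, the percentage of leaves whose curvatures fall below the critical
curvature and whose per-parameter |P_b| falls below 1%, always together
with the denominator actually used (converged, diagnosable leaves only).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .superformula import SGEVariant

__all__ = [
    "WilcoxonResult",
    "wilcoxon_signed_rank",
    "BatchSummary",
    "summarize_batch",
]

_PARAM_NAMES = ("a", "n1", "n2", "n3")


class WilcoxonResult(NamedTuple):
    statistic: float  # W+ = sum of ranks of positive differences
    p_value: float
    n_used: int       # pairs remaining after zero-difference removal
    method: str       # "exact" | "approx" | "degenerate"
    all_zero: bool


def _exact_signed_rank_pvalue(w_plus: float, ranks: np.ndarray) -> float:
    """Two-sided exact p-value by dynamic programming over sign patterns.

    Midranks are multiples of 1/2, so doubling makes them integers; the DP
    convolves the distribution of 2*W+ over all 2^n equiprobable sign
    assignments, which handles ties exactly.
    """
    r2 = np.rint(2.0 * ranks).astype(np.int64)
    total = int(r2.sum())
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(pmf)
        shifted[r:] = pmf[: total + 1 - r]
        pmf = pmf + shifted
    pmf /= pmf.sum()
    w2 = int(np.rint(2.0 * w_plus))
    lower = pmf[: w2 + 1].sum()
    upper = pmf[w2:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def wilcoxon_signed_rank(
    x, y, zero_method: str = "wilcox", exact_threshold: int = 25
) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test for paired samples.

    Zero differences are discarded (classical convention; ``zero_method=
    "pratt"`` delegates to scipy's Pratt handling instead).  Ties receive
    midranks.  The exact null distribution is used for ``n_used <=
    exact_threshold`` (tie-exact via dynamic programming); otherwise the
    normal approximation with continuity and tie corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D paired samples")
    d = x - y
    if zero_method == "pratt":
        from scipy.stats import wilcoxon as _sp_wilcoxon

        if np.all(d == 0):
            return WilcoxonResult(0.0, 1.0, 0, "degenerate", True)
        res = _sp_wilcoxon(x, y, zero_method="pratt", correction=True)
        return WilcoxonResult(float(res.statistic), float(res.pvalue),
                              int(np.sum(d != 0)), "approx", False)
    if zero_method != "wilcox":
        raise ValueError(f"unknown zero_method: {zero_method!r}")

    d = d[d != 0]
    n = len(d)
    if n == 0:
        return WilcoxonResult(0.0, 1.0, 0, "degenerate", True)
    if n < 6:
        raise ValueError(
            f"need >= 6 non-zero paired differences, got {n}"
        )
    ranks = rankdata(np.abs(d))
    w_plus = float(np.sum(ranks[d > 0]))

    if n <= exact_threshold:
        p = _exact_signed_rank_pvalue(w_plus, ranks)
        return WilcoxonResult(w_plus, p, n, "exact", False)

    mean = n * (n + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_corr = float(np.sum(counts**3 - counts)) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_corr
    diff = w_plus - mean
    # continuity correction toward the mean
    diff -= 0.5 * np.sign(diff)
    z = diff / np.sqrt(var)
    p = float(min(1.0, 2.0 * norm.sf(abs(z))))
    return WilcoxonResult(w_plus, p, n, "approx", False)


@dataclass(frozen=True)
class BatchSummary:
    """Population-level aggregation of fits and diagnostics.

    ``proportions`` rows carry percentages WITH their denominators;
    ``pairwise_tests`` covers the 3 variant pairs x 2 metrics (RMSE, AIC);
    ``metric_summary`` holds medians and quartiles of RMSE/AIC per variant.
    """

    per_leaf: pd.DataFrame
    proportions: pd.DataFrame
    pairwise_tests: pd.DataFrame
    metric_summary: pd.DataFrame
    denominators: dict = field(default_factory=dict)
    alpha: float = 0.05


def _proportion(flags: pd.Series) -> tuple[float, int]:
    flags = flags.dropna()
    n = len(flags)
    if n == 0:
        return float("nan"), 0
    return 100.0 * float(flags.astype(bool).sum()) / n, n


def summarize_batch(
    per_leaf: pd.DataFrame, alpha: float = 0.05
) -> BatchSummary:
    """Aggregate a per-leaf (fit x diagnostics) table.

    Expects one row per leaf x variant with at least ``leaf_id``,
    ``variant``, ``converged``, ``rmse``, ``aic`` and, where diagnostics
    ran, ``planar_ok``, ``uniform_ok`` and ``close_<param>`` flags.
    Proportions use converged, diagnosable rows only; empty cells are
    reported as missing, never as 0.
    """
    df = per_leaf.copy()
    if df.empty:
        raise ValueError("empty per-leaf table")
    variants = [v.value for v in (SGEVariant.SGE1, SGEVariant.SGE2,
                                  SGEVariant.SGE3)
                if v.value in set(df["variant"])]
    if not variants:
        raise ValueError("no recognised variants in table")
    conv = df[df["converged"].astype(bool)]
    for v in variants:
        if len(conv[conv["variant"] == v]) < 2:
            raise ValueError(f"need >= 2 converged leaves for {v}")

    prop_rows = []
    denominators = {}
    for v in variants:
        sub = conv[conv["variant"] == v]
        row = {"variant": v, "n_total": int((df["variant"] == v).sum()),
               "n_converged": len(sub)}
        for col, label in (
            ("planar_ok", "pct_gammaN_lt_Kc"),
            ("uniform_ok", "pct_gammaT_lt_Kc"),
        ):
            if col in sub:
                pct, n = _proportion(sub[col])
            else:
                pct, n = float("nan"), 0
            row[label] = pct
            row[f"{label}_n"] = n
            denominators[(v, label)] = n
        for name in _PARAM_NAMES:
            col = f"close_{name}"
            if col in sub and name in SGEVariant.coerce(v).parameter_names:
                pct, n = _proportion(sub[col])
            else:
                pct, n = float("nan"), 0
            row[f"pct_Pb_{name}_lt_1"] = pct
            row[f"pct_Pb_{name}_lt_1_n"] = n
            denominators[(v, f"Pb_{name}")] = n
        prop_rows.append(row)
    proportions = pd.DataFrame(prop_rows)

    test_rows = []
    for va, vb in itertools.combinations(variants, 2):
        a_tab = conv[conv["variant"] == va].set_index("leaf_id")
        b_tab = conv[conv["variant"] == vb].set_index("leaf_id")
        common = a_tab.index.intersection(b_tab.index)
        for metric in ("rmse", "aic"):
            try:
                res = wilcoxon_signed_rank(
                    a_tab.loc[common, metric].to_numpy(),
                    b_tab.loc[common, metric].to_numpy(),
                )
                row = {"statistic": res.statistic, "p_value": res.p_value,
                       "n_pairs": res.n_used, "method": res.method,
                       "significant": bool(res.p_value < alpha)}
            except ValueError:
                # too few non-zero pairs: report the cell as missing
                row = {"statistic": float("nan"), "p_value": float("nan"),
                       "n_pairs": len(common), "method": "insufficient",
                       "significant": False}
            test_rows.append({"variant_a": va, "variant_b": vb,
                              "metric": metric, **row})
    pairwise = pd.DataFrame(test_rows)

    metric_rows = []
    for v in variants:
        sub = conv[conv["variant"] == v]
        for metric in ("rmse", "aic"):
            q = sub[metric].quantile([0.25, 0.5, 0.75])
            metric_rows.append({
                "variant": v, "metric": metric, "n": len(sub),
                "q25": float(q[0.25]), "median": float(q[0.5]),
                "q75": float(q[0.75]),
            })
    metric_summary = pd.DataFrame(metric_rows)

    return BatchSummary(
        per_leaf=df,
        proportions=proportions,
        pairwise_tests=pairwise,
        metric_summary=metric_summary,
        denominators=denominators,
        alpha=alpha,
    )


def plot_metric_distributions(summary: BatchSummary, metric: str = "rmse",
                              ax=None):
    """Box-style distribution plot of a fit metric per variant."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    conv = summary.per_leaf[summary.per_leaf["converged"].astype(bool)]
    variants = sorted(conv["variant"].unique())
    data = [conv.loc[conv["variant"] == v, metric].dropna() for v in variants]
    ax.boxplot(data, tick_labels=variants)
    ax.set_ylabel(metric.upper())
    return ax


def plot_proportions(summary: BatchSummary, column: str = "pct_gammaT_lt_Kc",
                     ax=None):
    """Bar chart of a proportion column per variant."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    tab = summary.proportions
    ax.bar(tab["variant"], tab[column])
    ax.set_ylabel(column)
    ax.set_ylim(0, 100)
    return ax
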