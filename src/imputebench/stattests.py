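"""Exact paired comparison of the stacking ensemble against other methods.

For each evaluation metric and missing mechanism, the ensemble's six
per-proportion scores are paired with each competitor's and compared by a
one-sided exact Wilcoxon signed-rank test (alternative: the ensemble tends
to score higher).  With seven comparisons per metric x mechanism family,
raw p values are adjusted by the Benjamini-Hochberg false-discovery-rate
step-up within the family.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "wilcoxon_exact_one_sided",
    "bh_adjust",
    "compare_el",
]

METRIC_COLUMNS = ("sensitivity", "auc", "kappa")


@dataclasses.dataclass(frozen=True)
class TestResult:
    mechanism: str
    metric: str
    comparison: str           # "EL_vs_<method>"
    p_raw: float
    p_adj: float
    significant: bool


def wilcoxon_exact_one_sided(x, y) -> float:
    """Exact one-sided Wilcoxon signed-rank p value (alternative x > y).

    Zero differences are dropped before ranking; tied absolute differences
    receive midranks.  The p value is the proportion of all 2^n sign
    assignments of the (possibly tied) ranks whose positive-rank sum is at
    least the observed one — exact even in the presence of ties, for the
    small series lengths (n <= 20) this package compares.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be aligned 1-d series")
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 1.0  # all differences zero
    if n > 20:
        raise ValueError("exact enumeration supported for n <= 20 only")
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    # all 2^n sign assignments as a bit matrix
    assignments = (
        (np.arange(2**n)[:, None] >> np.arange(n)) & 1
    ).astype(float)
    w_all = assignments @ ranks
    return float(np.mean(w_all >= w_obs - 1e-9))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, original order preserved."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        raise ValueError("empty p-value list")
    if np.any(pvals <= 0) or np.any(pvals > 1):
        raise ValueError("p values must lie in (0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


def compare_el(results: pd.DataFrame, reference_method: str = "EL",
               alpha: float = 0.05) -> pd.DataFrame:
    """Compare the ensemble with every other method, per metric x mechanism.

    ``results`` is the long-format grid with columns ``mechanism``,
    ``proportion``, ``method`` and one column per metric.  Within each
    metric x mechanism family the seven EL-vs-other raw p values are
    BH-adjusted jointly and flagged at the ``alpha`` level.
    """
    required = {"mechanism", "proportion", "method", *METRIC_COLUMNS}
    if not required.issubset(results.columns):
        raise ValueError(f"results grid missing columns "
                         f"{sorted(required - set(results.columns))}")
    methods = [m for m in results["method"].unique() if m != reference_method]
    if reference_method not in set(results["method"]):
        raise ValueError(f"no rows for reference method {reference_method!r}")

    rows: list[TestResult] = []
    for mechanism, block in results.groupby("mechanism", sort=False):
        pivot = {
            metric: block.pivot_table(index="proportion", columns="method",
                                      values=metric, sort=True)
            for metric in METRIC_COLUMNS
        }
        for metric in METRIC_COLUMNS:
            table = pivot[metric]
            if table[reference_method].isna().any():
                raise ValueError("missing reference method values")
            raws = []
            for method in methods:
                if table[method].isna().any():
                    raise ValueError(f"missing values for method {method!r}")
                raws.append(wilcoxon_exact_one_sided(
                    table[reference_method].to_numpy(),
                    table[method].to_numpy(),
                ))
            adjusted = bh_adjust(raws)
            for method, p_raw, p_adj in zip(methods, raws, adjusted):
                rows.append(TestResult(
                    mechanism=str(mechanism),
                    metric=metric,
                    comparison=f"{reference_method}_vs_{method}",
                    p_raw=float(p_raw),
                    p_adj=float(p_adj),
                    significant=bool(p_adj < alpha),
                ))
    return pd.DataFrame([dataclasses.asdict(r) for r in rows])
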