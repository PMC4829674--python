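"""Group comparisons of methylation-pattern frequencies.

Two-tailed independent two-sample tests per cell type x metric x group
pair.  Groups that pass a Shapiro-Wilk normality check (alpha = 0.05, both
groups) are compared with a pooled-variance Student's t-test; otherwise a
Mann-Whitney U test is used (exact when both groups have n <= 20 and the
data are tie-free, normal approximation with continuity correction
otherwise).  Summary-statistics t-tests (from mean/SD/n) are provided for
checking published group summaries, in both pooled and Welch variants.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SummaryStats",
    "ComparisonResult",
    "normality_flag",
    "compare_groups",
    "ttest_from_summary",
    "compare_all",
    "DEFAULT_PAIRS",
    "METRICS",
]

NORMALITY_ALPHA = 0.05
EXACT_MW_MAX_N = 20

METRICS = ("pct_mC", "pct_mCmC", "pct_uCmC", "pct_mCuC", "pct_uCuC", "pct_partial")

# (label, group(s) a, group(s) b); "patients" pools active + inactive
DEFAULT_PAIRS = (
    ("active_vs_control", ("active",), ("control",)),
    ("inactive_vs_control", ("inactive",), ("control",)),
    ("active_vs_inactive", ("active",), ("inactive",)),
    ("patients_vs_control", ("active", "inactive"), ("control",)),
)


@dataclass(frozen=True)
class SummaryStats:
    """Printed group summary: mean and SD in percent, sample count."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")
        if self.n < 2:
            raise ValueError("n must be at least 2")


@dataclass(frozen=True)
class ComparisonResult:
    method: str  # student_t | welch_t | mann_whitney | degenerate
    statistic: float
    p: float
    n1: int
    n2: int
    df: float | None = None
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p-value out of [0, 1]")


def normality_flag(values) -> bool:
    """True iff Shapiro-Wilk at alpha = 0.05 does not reject normality.

    A zero-variance sample cannot be tested and is reported non-normal.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("normality check needs at least 3 values")
    if np.ptp(x) == 0:
        return False
    return bool(stats.shapiro(x).pvalue >= NORMALITY_ALPHA)


def compare_groups(x, y) -> ComparisonResult:
    """Two-tailed comparison of two independent samples.

    Pooled-variance t-test when both samples look normal, Mann-Whitney U
    otherwise.  Two identical constant samples are a degenerate case
    reported with p = 1 and a ``degenerate`` flag.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size < 3:
        raise ValueError("each group needs at least 3 values")

    if np.ptp(x) == 0 and np.ptp(y) == 0 and x[0] == y[0]:
        return ComparisonResult(
            method="degenerate", statistic=0.0, p=1.0, n1=x.size, n2=y.size,
            flags=frozenset({"degenerate"}),
        )

    if normality_flag(x) and normality_flag(y):
        res = stats.ttest_ind(x, y, equal_var=True)
        df = x.size + y.size - 2
        return ComparisonResult(
            method="student_t", statistic=float(res.statistic),
            p=float(res.pvalue), n1=x.size, n2=y.size, df=float(df),
        )

    combined = np.concatenate([x, y])
    has_ties = np.unique(combined).size < combined.size
    if x.size <= EXACT_MW_MAX_N and y.size <= EXACT_MW_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return ComparisonResult(
        method="mann_whitney", statistic=float(res.statistic),
        p=float(min(res.pvalue, 1.0)), n1=x.size, n2=y.size,
    )


def ttest_from_summary(
    a: SummaryStats, b: SummaryStats, variant: str = "pooled"
) -> ComparisonResult:
    """Two-sample t-test from group means, SDs and sizes.

    ``pooled``: classic Student's t with df = n1 + n2 - 2.
    ``welch``: unequal-variance t with Satterthwaite df.
    """
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    equal_var = variant == "pooled"
    res = stats.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=equal_var
    )
    if equal_var:
        df = float(a.n + b.n - 2)
    else:
        va, vb = a.sd**2 / a.n, b.sd**2 / b.n
        df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    method = "student_t" if equal_var else "welch_t"
    return ComparisonResult(
        method=method, statistic=float(res.statistic), p=float(res.pvalue),
        n1=a.n, n2=b.n, df=df,
    )


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def compare_all(
    dataset: pd.DataFrame,
    pairs=DEFAULT_PAIRS,
    correction: str = "none",
) -> pd.DataFrame:
    """All group comparisons over a per-sample frequency table.

    For each assay x cell type x metric (overall %mC, the four patterns and
    the combined partial-methylation frequency uCmC + mCuC) the listed group
    pairs are compared with :func:`compare_groups`.  No multiple-testing
    correction is applied by default; ``correction="bh"`` adds a
    Benjamini-Hochberg adjusted column.
    """
    df = dataset.copy()
    groups = set(df["group"].unique())
    needed = {g for _, ga, gb in pairs for g in (*ga, *gb)}
    missing = sorted(needed - groups)
    if missing:
        raise ValueError(f"dataset is missing groups: {missing}")
    df["pct_partial"] = df["pct_uCmC"] + df["pct_mCuC"]

    rows = []
    for (assay, cell_type), sub in df.groupby(["assay", "cell_type"], sort=False):
        for metric, (label, ga, gb) in itertools.product(METRICS, pairs):
            x = sub.loc[sub["group"].isin(ga), metric].to_numpy()
            y = sub.loc[sub["group"].isin(gb), metric].to_numpy()
            res = compare_groups(x, y)
            rows.append(
                {
                    "assay": assay,
                    "cell_type": cell_type,
                    "metric": metric,
                    "comparison": label,
                    "method": res.method,
                    "statistic": res.statistic,
                    "df": res.df,
                    "p": res.p,
                    "n1": res.n1,
                    "n2": res.n2,
                }
            )
    table = pd.DataFrame(rows)
    if correction == "bh":
        table["p_adj_bh"] = _bh_adjust(table["p"].to_numpy())
    elif correction != "none":
        raise ValueError(f"unknown correction {correction!r}")
    return table
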