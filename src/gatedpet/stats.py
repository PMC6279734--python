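"""Group summaries and significance tests for cohort comparisons.

Classic (pooled-variance) two-tailed Student's t-tests, the test of
choice for very small groups (n = 6 per strain here): ``ttest_independent``
for two independent cohorts, ``ttest_paired`` for dependent measurements,
and a summary-statistics form for when only group means and SDs are
available (published tables print nothing else).  Welch's correction is
available behind a flag.  No multiple-testing correction is applied
across parameters; reports say so in their footer.

scipy.stats provides the distributions and reference implementations;
zero-variance degenerate inputs are handled explicitly (equal means ->
t = 0, p = 1; unequal means with zero variance -> error).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .curves import CardiacFunctionResult
from .errors import DataError

__all__ = [
    "GroupSummary", "TTestResult",
    "ttest_independent", "ttest_independent_summary", "ttest_paired",
    "summarize", "compare_cohorts",
]

NO_CORRECTION_NOTE = ("p-values are per-parameter two-tailed Student's t-tests; "
                      "no multiple-testing correction applied")


@dataclass(frozen=True)
class GroupSummary:
    """n, mean and sample SD (n-1 denominator) of one parameter in one group."""

    parameter: str
    n: int
    mean: float
    sd: float

    def __post_init__(self):
        if self.n < 2:
            raise DataError("group summary requires n >= 2")
        if self.sd < 0:
            raise DataError("SD must be non-negative")

    def __str__(self):
        return f"{self.parameter}: {self.mean:.4g} ± {self.sd:.4g} (n={self.n})"


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    kind: str  # "independent" | "paired"

    def __post_init__(self):
        if not (0.0 < self.p <= 1.0):
            raise DataError(f"p-value out of range: {self.p}")
        if self.df <= 0:
            raise DataError("degrees of freedom must be positive")

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p < alpha


def _finish(t: float, df: float, kind: str) -> TTestResult:
    p = 2.0 * sps.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=float(df), p=float(max(p, np.nextafter(0, 1))),
                       kind=kind)


def ttest_independent(a: Sequence[float], b: Sequence[float],
                      welch: bool = False) -> TTestResult:
    """Two-tailed independent-samples Student's t (pooled variance).

    ``welch=True`` uses Welch's unequal-variance form instead.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise DataError("each group needs n >= 2")
    if np.var(a, ddof=1) == 0.0 and np.var(b, ddof=1) == 0.0:
        if np.mean(a) == np.mean(b):
            return TTestResult(t=0.0, df=len(a) + len(b) - 2, p=1.0,
                               kind="independent")
        raise DataError("zero variance in both groups with unequal means: "
                        "t statistic undefined")
    res = sps.ttest_ind(a, b, equal_var=not welch)
    df = res.df if hasattr(res, "df") else len(a) + len(b) - 2
    return _finish(res.statistic, df, "independent")


def ttest_independent_summary(mean_a: float, sd_a: float, n_a: int,
                              mean_b: float, sd_b: float, n_b: int,
                              welch: bool = False) -> TTestResult:
    """Independent t-test from group summary statistics (means, SDs, ns)."""
    if n_a < 2 or n_b < 2:
        raise DataError("each group needs n >= 2")
    if sd_a < 0 or sd_b < 0:
        raise DataError("SDs must be non-negative")
    if sd_a == 0.0 and sd_b == 0.0:
        if mean_a == mean_b:
            return TTestResult(t=0.0, df=n_a + n_b - 2, p=1.0,
                               kind="independent")
        raise DataError("zero variance in both groups with unequal means: "
                        "t statistic undefined")
    res = sps.ttest_ind_from_stats(mean_a, sd_a, n_a, mean_b, sd_b, n_b,
                                   equal_var=not welch)
    if welch:
        v_a, v_b = sd_a ** 2 / n_a, sd_b ** 2 / n_b
        df = (v_a + v_b) ** 2 / (v_a ** 2 / (n_a - 1) + v_b ** 2 / (n_b - 1))
    else:
        df = n_a + n_b - 2
    return _finish(res.statistic, df, "independent")


def ttest_paired(a: Sequence[float], b: Sequence[float]) -> TTestResult:
    """Two-tailed paired Student's t: one-sample t on differences, df = n-1."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise DataError("paired samples must have equal length")
    if len(a) < 2:
        raise DataError("paired test needs n >= 2")
    d = a - b
    if np.var(d, ddof=1) == 0.0:
        if np.all(d == 0.0):
            return TTestResult(t=0.0, df=len(a) - 1, p=1.0, kind="paired")
        raise DataError("constant non-zero paired differences: "
                        "t statistic undefined")
    res = sps.ttest_rel(a, b)
    return _finish(res.statistic, len(a) - 1, "paired")


def summarize(results: Sequence[CardiacFunctionResult],
              parameter: str) -> GroupSummary:
    """Mean +- sample SD of one functional parameter across subjects."""
    vals = np.array([getattr(r, parameter) for r in results], dtype=float)
    return GroupSummary(parameter=parameter, n=len(vals),
                        mean=float(np.mean(vals)),
                        sd=float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0)


def compare_cohorts(results_a: Sequence[CardiacFunctionResult],
                    results_b: Sequence[CardiacFunctionResult],
                    alpha: float = 0.05,
                    parameters: Sequence[str] = ("ef", "pfr", "third_mfr",
                                                 "tpfr", "hr", "edv", "esv"),
                    labels=("A", "B"), welch: bool = False) -> pd.DataFrame:
    """Parameter-by-parameter group comparison of two cohorts.

    Returns a DataFrame with per-group mean +- SD, the pooled t statistic,
    two-tailed p (4 significant figures when serialized) and a
    significance flag at ``alpha``; attrs carry the no-correction note.
    """
    if len(results_a) < 2 or len(results_b) < 2:
        raise DataError("cohort comparison needs >= 2 subjects per group")
    rows = []
    for par in parameters:
        sa = summarize(results_a, par)
        sb = summarize(results_b, par)
        tt = ttest_independent(
            [getattr(r, par) for r in results_a],
            [getattr(r, par) for r in results_b], welch=welch)
        rows.append({
            "parameter": par,
            f"mean_{labels[0]}": sa.mean, f"sd_{labels[0]}": sa.sd,
            f"n_{labels[0]}": sa.n,
            f"mean_{labels[1]}": sb.mean, f"sd_{labels[1]}": sb.sd,
            f"n_{labels[1]}": sb.n,
            "t": tt.t, "df": tt.df, "p": float(f"{tt.p:.4g}"),
            "significant": tt.significant(alpha),
        })
    df = pd.DataFrame(rows)
    df.attrs["alpha"] = alpha
    df.attrs["note"] = NO_CORRECTION_NOTE
    return df
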