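"""Cohort statistics and EF-category reclassification.

Mirrors the statistical treatment of small CMR cohorts: continuous variables
are gated through Shapiro–Wilk and Lilliefors (Kolmogorov–Smirnov with
estimated parameters) normality tests at α = 0.05 and summarized as mean ± SD
when both pass, otherwise as median (IQR) — when the two tests disagree the
non-parametric summary is used (conservative).  Comparisons are two-sided
one-sample *t*-tests against unity (for SFVC/SFAC columns, where 1 means "no
change from diastole") and paired-samples *t*-tests; associations use
Pearson's correlation.  No multiple-testing correction is applied.

:func:`reclassify` cross-tabulates the EF category (<40%, 40–50%, >50%) under
the guidelines convention against the contour convention; because contouring
removes non-ejecting tissue from both phases, contour EF exceeds guidelines EF
whenever trabecular volume and stroke volume are positive, so reclassification
can only move subjects toward higher categories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

from .metrics import ef_category

__all__ = ["StatReport", "summarize", "compare", "correlate", "reclassify",
           "EF_CATEGORIES"]

ALPHA = 0.05
EF_CATEGORIES = ("below_40", "40_to_50", "above_50")


@dataclass(frozen=True)
class StatReport:
    """One statistical result: sample size, both summaries, the selected one,
    and (when a test ran) its name, statistic and p-value."""

    comparison: str
    n: int
    mean: float
    sd: float
    median: float
    iqr: tuple[float, float]
    normal: bool | None = None
    summary_kind: str = "mean_sd"  # which summary the normality gate selected
    test: str | None = None
    statistic: float | None = None
    p_value: float | None = None
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.p_value is not None and not (0 <= self.p_value <= 1 or np.isnan(self.p_value)):
            raise ValueError("p-value outside [0, 1]")

    @property
    def estimate(self) -> str:
        if self.summary_kind == "mean_sd":
            return f"{self.mean:.2f} ± {self.sd:.2f}"
        return f"{self.median:.2f} ({self.iqr[0]:.2f}–{self.iqr[1]:.2f})"


def _normality(values: np.ndarray) -> tuple[bool | None, tuple[str, ...]]:
    flags: list[str] = []
    if values.size < 3:
        return None, ("too few values for normality testing",)
    if np.ptp(values) == 0:
        return None, ("degenerate sample: zero variance",)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p_sw = sps.shapiro(values).pvalue
        if values.size >= 4:  # Lilliefors is undefined below n = 4
            p_ks = lilliefors(values, dist="norm")[1]
        else:
            p_ks = p_sw
            flags.append("Kolmogorov–Smirnov gate needs n >= 4; Shapiro–Wilk only")
    normal = bool(p_sw > ALPHA and p_ks > ALPHA)
    if (p_sw > ALPHA) != (p_ks > ALPHA):
        flags.append("normality tests disagree; non-parametric summary used")
    return normal, tuple(flags)


def summarize(values, comparison: str = "") -> StatReport:
    """Normality-gated descriptive summary of one variable."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("no finite values to summarize")
    normal, flags = _normality(v)
    q1, q3 = (np.percentile(v, [25, 75]) if v.size > 1 else (v[0], v[0]))
    return StatReport(
        comparison=comparison or "summary",
        n=int(v.size),
        mean=float(np.mean(v)),
        sd=float(np.std(v, ddof=1)) if v.size > 1 else 0.0,
        median=float(np.median(v)),
        iqr=(float(q1), float(q3)),
        normal=normal,
        summary_kind="mean_sd" if normal else "median_iqr",
        flags=flags,
    )


def compare(values_a, values_b=None, mode: str = "paired", comparison: str = "") -> StatReport:
    """One-sample-vs-unity or paired-samples two-sided *t*-test.

    ``one_sample_vs_unity`` tests the mean of ``values_a`` against 1 (the
    no-change value of a systolic fractional change); ``paired`` tests the
    per-subject difference of two columns against 0.
    """
    a = np.asarray(values_a, dtype=float)
    if mode == "one_sample_vs_unity":
        if a.size < 2:
            raise ValueError("one-sample test needs n >= 2")
        res = sps.ttest_1samp(a, popmean=1.0)
        diff = a - 1.0
        test = "one-sample t-test vs 1"
    elif mode == "paired":
        if values_b is None:
            raise ValueError("paired mode needs two columns")
        b = np.asarray(values_b, dtype=float)
        if a.shape != b.shape:
            raise ValueError(f"paired columns differ in length: {a.size} vs {b.size}")
        if a.size < 2:
            raise ValueError("paired test needs n >= 2")
        res = sps.ttest_rel(a, b)
        diff = a - b
        test = "paired-samples t-test"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    stat = float(res.statistic)
    p = float(res.pvalue)
    if np.isnan(stat) and np.ptp(diff) == 0:
        # identical pairs / exactly-unity sample: no evidence of difference
        stat, p = 0.0, 1.0
    base = summarize(diff, comparison=comparison or mode)
    return StatReport(
        comparison=base.comparison, n=base.n, mean=base.mean, sd=base.sd,
        median=base.median, iqr=base.iqr, normal=base.normal,
        summary_kind=base.summary_kind, test=test, statistic=stat, p_value=p,
        flags=base.flags,
    )


def correlate(x, y, comparison: str = "") -> StatReport:
    """Pearson correlation with R² and a two-sided p-value.

    The report's ``mean`` field carries r and ``sd`` carries R².
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError("columns differ in length")
    if xa.size < 3:
        raise ValueError("correlation needs n >= 3")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("zero variance in a column; correlation undefined")
    res = sps.pearsonr(xa, ya)
    r = float(res.statistic)
    return StatReport(
        comparison=comparison or "pearson",
        n=int(xa.size),
        mean=r, sd=r**2,
        median=r, iqr=(r, r),
        test="Pearson correlation",
        statistic=r,
        p_value=float(res.pvalue),
    )


def reclassify(
    table: pd.DataFrame,
    guidelines_col: str = "ef_guidelines",
    contour_col: str = "ef_contour",
) -> dict:
    """EF-category cross-tabulation: guidelines convention vs contour.

    Subjects missing either EF are excluded and logged.  Returns the 3×3
    contingency table (rows = guidelines category, columns = contour
    category), the marginals, and the fraction changing category.
    """
    missing = table.index[
        table[guidelines_col].isna() | table[contour_col].isna()
    ].tolist()
    ok = table.dropna(subset=[guidelines_col, contour_col])
    counts = pd.DataFrame(0, index=list(EF_CATEGORIES), columns=list(EF_CATEGORIES))
    for _, row in ok.iterrows():
        g = ef_category(float(row[guidelines_col]))
        c = ef_category(float(row[contour_col]))
        counts.loc[g, c] += 1
    n = int(counts.to_numpy().sum())
    moved = n - int(np.trace(counts.to_numpy()))
    return {
        "table": counts,
        "n": n,
        "guidelines_marginals": counts.sum(axis=1).to_dict(),
        "contour_marginals": counts.sum(axis=0).to_dict(),
        "fraction_reclassified": moved / n if n else float("nan"),
        "excluded": missing,
    }
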