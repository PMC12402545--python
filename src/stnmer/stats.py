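"""Two-group and multi-band statistical comparisons of trajectory metrics.

The comparison policy mirrors standard intraoperative-electrophysiology
reporting: test each sample for normality (Shapiro-Wilk at alpha=0.05),
use an unpaired t-test when both samples pass and a two-sided
Mann-Whitney U test otherwise. For the Mann-Whitney the reported
statistic follows the smaller-U convention (min of the two one-sided
U's), and p-values are exact when the combined sample is small and
tie-free. Multi-band comparisons apply a Bonferroni-adjusted alpha
(alpha / number of bands, e.g. 0.05/4 = 0.0125) alongside the raw one.
ANOVA / Kruskal-Wallis are exposed for three or more groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ComparisonResult",
    "choose_test",
    "compare",
    "multiband_compare",
    "compare_many_groups",
    "summarize_sample",
]


@dataclass
class ComparisonResult:
    """Outcome of one statistical comparison between labelled groups."""

    metric: str
    test: str                    # t_unpaired | mann_whitney_u | anova | kruskal_wallis
    n_a: int
    n_b: int
    statistic: float
    p_value: float
    alpha: float = 0.05
    adjusted_alpha: float | None = None
    normality_p: tuple[float, float] | None = None  # Shapiro p per sample

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    @property
    def significant_adjusted(self) -> bool:
        alpha = self.adjusted_alpha if self.adjusted_alpha is not None else self.alpha
        return self.p_value < alpha


def _clean(sample) -> np.ndarray:
    x = np.asarray(sample, dtype=float)
    return x[np.isfinite(x)]


def choose_test(sample_a, sample_b, alpha: float = 0.05) -> str:
    """Normality-gated test selection.

    Shapiro-Wilk on each sample at the given alpha; if both look
    normal the unpaired t-test is chosen, otherwise the Mann-Whitney U.
    """
    a, b = _clean(sample_a), _clean(sample_b)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 observations per sample")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return "mann_whitney_u"  # zero-range sample: normality undefined
    pa = sps.shapiro(a).pvalue
    pb = sps.shapiro(b).pvalue
    return "t_unpaired" if (pa > alpha and pb > alpha) else "mann_whitney_u"


def _mann_whitney(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U with the smaller-U convention.

    Exact p-value when the combined sample has <= 20 tie-free
    observations, otherwise the normal approximation with continuity
    and tie correction.
    """
    combined = np.concatenate([a, b])
    ties = len(np.unique(combined)) < len(combined)
    method = "exact" if (not ties and len(combined) <= 20) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    u_a = float(res.statistic)
    u_min = min(u_a, len(a) * len(b) - u_a)
    return u_min, float(res.pvalue)


def compare(
    sample_a,
    sample_b,
    test: str | None = None,
    alpha: float = 0.05,
    metric: str = "",
) -> ComparisonResult:
    """Two-sided two-group comparison.

    ``test`` may be ``'t_unpaired'``, ``'mann_whitney_u'`` or ``None``
    (normality-gated selection via :func:`choose_test`).
    """
    a, b = _clean(sample_a), _clean(sample_b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 observations per sample")
    normality = None
    if test is None:
        test = choose_test(a, b, alpha)
        if np.ptp(a) > 0 and np.ptp(b) > 0:
            normality = (float(sps.shapiro(a).pvalue), float(sps.shapiro(b).pvalue))
    if test == "t_unpaired":
        if np.var(a) == 0 and np.var(b) == 0:
            raise ValueError(
                "both samples have zero variance; the t statistic is undefined"
            )
        res = sps.ttest_ind(a, b)
        stat, p = float(res.statistic), float(res.pvalue)
    elif test == "mann_whitney_u":
        stat, p = _mann_whitney(a, b)
    else:
        raise ValueError(f"unknown test {test!r}")
    return ComparisonResult(
        metric=metric, test=test, n_a=len(a), n_b=len(b),
        statistic=stat, p_value=p, alpha=alpha, normality_p=normality,
    )


def multiband_compare(
    table: pd.DataFrame,
    bands: tuple[str, ...] = ("delta", "theta", "alpha", "gamma"),
    group_col: str = "group",
    alpha: float = 0.05,
    column_template: str = "mean_power_{band}",
    test: str | None = None,
) -> list[ComparisonResult]:
    """Per-band two-group comparison with Bonferroni-adjusted alpha.

    ``adjusted_alpha = alpha / len(bands)`` (0.0125 for the four
    non-beta bands at alpha 0.05); both raw and adjusted significance
    are available on the results.
    """
    groups = table[group_col].unique()
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, found {list(groups)}")
    adjusted = alpha / len(bands)
    results = []
    for band in bands:
        col = column_template.format(band=band)
        if col not in table.columns:
            raise ValueError(f"missing column {col!r}")
        a = table.loc[table[group_col] == groups[0], col]
        b = table.loc[table[group_col] == groups[1], col]
        res = compare(a, b, test=test, alpha=alpha, metric=col)
        res.adjusted_alpha = adjusted
        results.append(res)
    return results


def compare_many_groups(
    samples: list, test: str = "kruskal_wallis", alpha: float = 0.05,
    metric: str = "",
) -> ComparisonResult:
    """ANOVA or Kruskal-Wallis across three or more groups."""
    cleaned = [_clean(s) for s in samples]
    if len(cleaned) < 3:
        raise ValueError("use compare() for fewer than 3 groups")
    if test == "anova":
        res = sps.f_oneway(*cleaned)
    elif test == "kruskal_wallis":
        res = sps.kruskal(*cleaned)
    else:
        raise ValueError(f"unknown test {test!r}")
    return ComparisonResult(
        metric=metric, test=test, n_a=len(cleaned[0]), n_b=len(cleaned[1]),
        statistic=float(res.statistic), p_value=float(res.pvalue), alpha=alpha,
    )


def summarize_sample(x) -> dict[str, float]:
    """Mean +/- SEM and mean +/- SD summaries, both labelled.

    Normally distributed metrics are conventionally reported as mean
    +/- SEM and non-normal ones as mean +/- SD; both are emitted so the
    report can label whichever applies.
    """
    x = _clean(x)
    return {
        "n": float(len(x)),
        "mean": float(np.mean(x)),
        "sd": float(np.std(x, ddof=1)) if len(x) > 1 else float("nan"),
        "sem": float(sps.sem(x)) if len(x) > 1 else float("nan"),
        "median": float(np.median(x)),
    }
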