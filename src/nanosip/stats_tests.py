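"""Statistical battery for treatment comparisons of isotope data.

Centerpiece is the Van der Waerden normal-scores k-sample test: ranks from a
Kruskal–Wallis-style pooled ranking are converted to quantiles of the
standard normal distribution, A_ij = Φ⁻¹(R_ij/(N+1)), and the statistic

    T = Σ_j n_j·Ā_j² / s²,   s² = Σ A² / (N−1)

is referred to χ² with k−1 degrees of freedom (or to its exact permutation
distribution for small samples).  The normal-scores transform makes the test
robust to non-normality and heteroscedasticity while retaining near-ANOVA
power.  Supporting cast: Holm-adjusted pairwise tests with a compact letter
display, an ANCOVA slope-homogeneity F-test, the one-sample t-test, and
Pearson correlation.

Ties are handled with mid-ranks throughout.
"""

from __future__ import annotations

import itertools
import math
import string
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupedSamples",
    "TestResult",
    "LetterDisplay",
    "van_der_waerden",
    "pairwise_letters",
    "ancova_slopes",
    "one_sample_t",
    "pearson_corr",
]


@dataclass(frozen=True)
class GroupedSamples:
    """Real-valued observations with a categorical group label per value."""

    values: np.ndarray
    group: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        group = np.asarray(self.group)
        if values.shape != group.shape or values.ndim != 1:
            raise ValueError("values and group must be 1-D and equal length")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "group", group)

    def split(self) -> dict[str, np.ndarray]:
        return {
            str(g): self.values[self.group == g]
            for g in pd.unique(self.group)
        }


@dataclass
class TestResult:
    statistic: float
    df: float | tuple[float, float]
    p_value: float
    method: str
    group_summaries: pd.DataFrame | None = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError("p-value outside [0, 1]")


@dataclass
class LetterDisplay:
    """Compact letter display: groups sharing a letter are not significantly
    different in the Holm-adjusted pairwise tests at level alpha."""

    letters: dict[str, str]
    alpha: float
    correction: str
    pairwise_p: pd.DataFrame | None = None


def _normal_scores(values: np.ndarray) -> np.ndarray:
    n = len(values)
    ranks = sps.rankdata(values, method="average")
    return sps.norm.ppf(ranks / (n + 1))


def _vdw_statistic(values: np.ndarray, group: np.ndarray) -> tuple[float, int]:
    """Normal-scores statistic T and number of groups k."""
    scores = _normal_scores(values)
    n = len(values)
    s2 = np.sum(scores**2) / (n - 1)
    labels = pd.unique(group)
    if s2 == 0:
        return 0.0, len(labels)
    t = 0.0
    for g in labels:
        sel = scores[group == g]
        t += len(sel) * sel.mean() ** 2
    return t / s2, len(labels)


def van_der_waerden(
    samples: GroupedSamples,
    method: str = "auto",
    max_permutation_n: int = 10,
) -> TestResult:
    """Van der Waerden normal-scores k-sample test.

    ``method`` is ``"chisq"`` (χ²_{k−1} reference distribution),
    ``"permutation"`` (exact enumeration of all distinct group assignments —
    small samples only), or ``"auto"`` which uses the exact distribution when
    the total sample size is at most ``max_permutation_n``.  With all values
    identical the statistic is 0 and p = 1, flagged degenerate.
    """
    values, group = samples.values, samples.group
    n = len(values)
    labels = pd.unique(group)
    k = len(labels)
    if k < 2:
        raise ValueError("need at least two groups")
    if n < 3:
        raise ValueError("need at least three observations in total")
    if any((group == g).sum() == 0 for g in labels):
        raise ValueError("every group must be nonempty")

    if np.ptp(values) == 0:
        return TestResult(0.0, k - 1, 1.0, "van_der_waerden/degenerate",
                          degenerate=True)

    t_obs, _ = _vdw_statistic(values, group)

    if method == "auto":
        method = "permutation" if n <= max_permutation_n else "chisq"

    if method == "chisq":
        p = float(sps.chi2.sf(t_obs, k - 1))
        label = "van_der_waerden/chisq"
    elif method == "permutation":
        # enumerate distinct assignments of observations to group slots
        t_null = []
        for perm in _distinct_label_permutations(group):
            t_perm, _ = _vdw_statistic(values, perm)
            t_null.append(t_perm)
        t_null = np.asarray(t_null)
        p = float(np.mean(t_null >= t_obs - 1e-12))
        label = "van_der_waerden/permutation"
    else:
        raise ValueError(f"unknown method {method!r}")

    summary = (
        pd.DataFrame({"value": values, "group": group})
        .groupby("group")["value"]
        .agg(["count", "mean", "median"])
        .reset_index()
    )
    return TestResult(t_obs, k - 1, p, label, group_summaries=summary)


def _distinct_label_permutations(group: np.ndarray):
    """All distinct rearrangements of the group-label vector."""
    seen = set()
    for perm in itertools.permutations(group):
        if perm not in seen:
            seen.add(perm)
            yield np.asarray(perm)


def pairwise_letters(
    samples: GroupedSamples,
    alpha: float = 0.05,
    correction: str = "holm",
) -> LetterDisplay:
    """All pairwise Van der Waerden tests with multiplicity correction and a
    compact letter display (insert-absorb algorithm)."""
    groups = samples.split()
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")

    pairs = list(itertools.combinations(labels, 2))
    raw_p = []
    for a, b in pairs:
        sub = GroupedSamples(
            values=np.concatenate([groups[a], groups[b]]),
            group=np.asarray([a] * len(groups[a]) + [b] * len(groups[b])),
        )
        raw_p.append(van_der_waerden(sub, method="chisq").p_value)

    adj_p = multipletests(raw_p, alpha=alpha, method=correction)[1] if pairs else []
    pmat = pd.DataFrame(np.ones((len(labels), len(labels))), index=labels, columns=labels)
    for (a, b), p in zip(pairs, adj_p):
        pmat.loc[a, b] = pmat.loc[b, a] = p

    distinct = {(a, b) for (a, b), p in zip(pairs, adj_p) if p < alpha}
    letters = _compact_letter_display(labels, distinct)
    return LetterDisplay(letters=letters, alpha=alpha, correction=correction,
                         pairwise_p=pmat)


def _compact_letter_display(
    labels: Sequence[str], distinct: set[tuple[str, str]]
) -> dict[str, str]:
    """Insert-absorb compact letter display.

    ``distinct`` holds unordered pairs judged significantly different.  Each
    letter denotes a set of groups that are mutually non-distinct; two groups
    share a letter iff they are not significantly different.
    """
    def is_distinct(a: str, b: str) -> bool:
        return (a, b) in distinct or (b, a) in distinct

    # start with one letter covering everything, then split on violations
    sets: list[set[str]] = [set(labels)]
    for a, b in sorted(distinct):
        new_sets: list[set[str]] = []
        for s in sets:
            if a in s and b in s:
                new_sets.append(s - {a})
                new_sets.append(s - {b})
            else:
                new_sets.append(s)
        # absorb: drop sets contained in another
        sets = [
            s for s in new_sets
            if not any(s < t for t in new_sets)
        ]
        # dedupe
        uniq: list[set[str]] = []
        for s in sets:
            if s not in uniq:
                uniq.append(s)
        sets = uniq

    sets.sort(key=lambda s: sorted(labels.index(x) for x in s))
    letters = {lab: "" for lab in labels}
    alphabet = string.ascii_lowercase
    for i, s in enumerate(sets):
        ch = alphabet[i % len(alphabet)] * (1 + i // len(alphabet))
        for lab in s:
            letters[lab] += ch
    return letters


def ancova_slopes(
    x: np.ndarray, y: np.ndarray, group: np.ndarray
) -> TestResult:
    """Slope-homogeneity F-test from a full-interaction ANCOVA.

    Fits y ~ group * x (covariate centered for conditioning) and returns the
    Type-II F-test of the group×covariate interaction.  A significant result
    means the regression slopes of y on x differ between groups.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    group = np.asarray(group)
    labels = pd.unique(group)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    for g in labels:
        sel = group == g
        if sel.sum() < 3:
            raise ValueError(f"group {g!r} has fewer than 3 points")
        if np.ptp(x[sel]) == 0:
            raise ValueError(f"group {g!r} has zero covariate variance")

    df = pd.DataFrame({"x": x - x.mean(), "y": y, "group": group})
    model = smf.ols("y ~ C(group) * x", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    row = table.loc["C(group):x"]
    df_num = float(row["df"])
    df_den = float(table.loc["Residual", "df"])
    return TestResult(
        statistic=float(row["F"]),
        df=(df_num, df_den),
        p_value=float(row["PR(>F)"]),
        method="ancova_interaction_F/typeII",
    )


def one_sample_t(values: np.ndarray, mu: float) -> TestResult:
    """Two-sided one-sample t-test of the mean against mu."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need at least two observations")
    if np.ptp(values) == 0:
        degenerate = True
        if values[0] == mu:
            return TestResult(0.0, len(values) - 1, 1.0, "one_sample_t",
                              degenerate=degenerate)
        return TestResult(math.inf, len(values) - 1, 0.0, "one_sample_t",
                          degenerate=degenerate)
    res = sps.ttest_1samp(values, mu)
    return TestResult(float(res.statistic), len(values) - 1,
                      float(res.pvalue), "one_sample_t")


def pearson_corr(x: np.ndarray, y: np.ndarray) -> TestResult:
    """Pearson correlation with its t-based two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("x and y must share length >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return TestResult(math.nan, len(x) - 2, math.nan, "pearson",
                          degenerate=True)
    r, p = sps.pearsonr(x, y)
    return TestResult(float(r), len(x) - 2, float(p), "pearson")
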