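"""Group-level statistical screening of coupling features.

For each feature: test per-group normality (Lilliefors-corrected
Kolmogorov-Smirnov), pick one-way ANOVA when every group looks Gaussian and
the Kruskal-Wallis H test otherwise, then run the three pairwise post hoc
comparisons with Bonferroni correction at alpha = 0.05.
"""

from __future__ import annotations

from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as spstats
from statsmodels.stats.diagnostic import lilliefors

from .synthetic import GROUPS

__all__ = [
    "choose_test",
    "compare_groups",
    "significance_summary",
]

#: Pairwise group comparisons, in decreasing-severity order.
PAIRWISE_COMPARISONS = tuple(combinations(GROUPS, 2))


def _group_values(values: np.ndarray, labels: np.ndarray,
                  groups: Sequence[str]) -> list[np.ndarray]:
    return [values[labels == g] for g in groups]


def choose_test(values, labels, alpha: float = 0.05,
                normality: str = "lilliefors") -> str:
    """Pick the omnibus test for one feature: ``"anova"`` iff every group
    passes the normality screen at ``alpha``, else ``"kruskal"``.

    ``normality="lilliefors"`` (default) uses the Kolmogorov-Smirnov
    statistic with the Lilliefors small-sample correction, appropriate when
    the Gaussian parameters are estimated from the data; ``"ks"`` compares
    against the fitted Gaussian without correction (anti-conservative, kept
    for comparability with software that reports plain KS).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = [g for g in pd.unique(labels)]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for sample in _group_values(values, labels, groups):
        if len(sample) < 3:
            raise ValueError("each group needs at least 3 observations")
        if sample.std() == 0:
            return "kruskal"
        if normality == "lilliefors":
            _, p = lilliefors(sample, dist="norm")
        elif normality == "ks":
            _, p = spstats.kstest(sample, "norm",
                                  args=(sample.mean(), sample.std(ddof=1)))
        else:
            raise ValueError(f"unknown normality method {normality!r}")
        if p < alpha:
            return "kruskal"
    return "anova"


def _stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def compare_groups(features: pd.DataFrame, labels=None, alpha: float = 0.05,
                   normality: str = "lilliefors") -> pd.DataFrame:
    """Screen every feature for group differences.

    ``features`` is a feature matrix (optionally carrying ``subject_id`` /
    ``group`` columns, in which case ``labels`` may be omitted).  For each
    feature the omnibus test (chosen by :func:`choose_test`) is followed by
    the three pairwise post hoc tests -- the two-sample t test for the
    ANOVA branch, two-sided Mann-Whitney U for the Kruskal-Wallis branch --
    each Bonferroni-adjusted for the per-feature family of 3 comparisons:
    ``p_adj = min(1, 3 * p_raw)``.

    Returns one row per feature x comparison with columns ``feature``,
    ``comparison``, ``test``, ``omnibus_p``, ``raw_p``, ``p_adj``,
    ``significant`` (``p_adj < alpha``) and ``stars`` (``*`` < 0.05,
    ``**`` < 0.01).  Constant features are reported as untestable.
    """
    features = features.copy()
    if labels is None:
        if "group" not in features.columns:
            raise ValueError("labels not given and no 'group' column present")
        labels = features["group"].to_numpy()
    else:
        labels = np.asarray(labels)
    feature_cols = [c for c in features.columns
                    if c not in ("subject_id", "group")]
    present = [g for g in GROUPS if (labels == g).sum() > 0]
    comparisons = [c for c in PAIRWISE_COMPARISONS
                   if c[0] in present and c[1] in present]
    n_comp = len(comparisons)

    rows = []
    for col in feature_cols:
        values = features[col].to_numpy(dtype=float)
        keep = np.isfinite(values)
        vals, labs = values[keep], labels[keep]
        samples = _group_values(vals, labs, present)
        if vals.std() == 0 or any(len(s) < 3 for s in samples):
            for a, b in comparisons:
                rows.append({"feature": col, "comparison": f"{a} vs {b}",
                             "test": "untestable", "omnibus_p": np.nan,
                             "raw_p": np.nan, "p_adj": np.nan,
                             "significant": False, "stars": ""})
            continue
        test = choose_test(vals, labs, alpha=alpha, normality=normality)
        if test == "anova":
            _, omnibus_p = spstats.f_oneway(*samples)
        else:
            _, omnibus_p = spstats.kruskal(*samples)
        for a, b in comparisons:
            xa, xb = vals[labs == a], vals[labs == b]
            if test == "anova":
                _, raw_p = spstats.ttest_ind(xa, xb)
            else:
                _, raw_p = spstats.mannwhitneyu(xa, xb,
                                                alternative="two-sided")
            p_adj = min(1.0, n_comp * float(raw_p))
            rows.append({"feature": col, "comparison": f"{a} vs {b}",
                         "test": test, "omnibus_p": float(omnibus_p),
                         "raw_p": float(raw_p), "p_adj": p_adj,
                         "significant": p_adj < alpha, "stars": _stars(p_adj)})
    return pd.DataFrame(rows)


def significance_summary(report: pd.DataFrame) -> pd.DataFrame:
    """Pivot a :func:`compare_groups` report into a feature x comparison
    table of significance stars (empty = not significant)."""
    return report.pivot(index="feature", columns="comparison",
                        values="stars").fillna("")
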