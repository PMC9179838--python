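"""Clustering-quality, concordance, and survival statistics.

Evaluation tools shared by the pipeline and its tests: silhouette widths
for cluster stability, the adjusted Rand index for partition agreement,
chi-squared tests for subtype-distribution shifts, the paired Wilcoxon
signed-rank test for comparing batch-correction schemes on the same
samples, and Kaplan-Meier / log-rank machinery for survival stratification
of discovered subtypes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from sklearn.metrics import adjusted_rand_score, silhouette_samples

from .expr_data import ExpressionMatrix


@dataclass
class SilhouetteResult:
    """Per-sample silhouette widths s(i) = (b-a)/max(a,b) and their mean.

    Singleton clusters get s(i) = 0 by convention.
    """

    scores: pd.Series
    average_width: float


@dataclass
class TestResult:
    statistic: float
    p: float
    test_name: str
    df: int | None = None
    extra: dict | None = None


@dataclass
class SurvivalCurve:
    """Kaplan-Meier product-limit estimate for one group.

    ``event_times`` are the distinct times with >= 1 observed event;
    ``survival`` holds S(t) just after each of those times.  Censored
    samples leave the risk set after their censoring time.
    """

    event_times: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])


def silhouette(m: ExpressionMatrix | np.ndarray, labels) -> SilhouetteResult:
    """Euclidean silhouette over the clustering feature space.

    Accepts an ExpressionMatrix (samples are its columns) or a samples x
    features array.
    """
    if isinstance(m, ExpressionMatrix):
        X = m.values.to_numpy().T
        index = m.sample_ids
    else:
        X = np.asarray(m)
        index = pd.RangeIndex(X.shape[0])
    labels = np.asarray(pd.Series(labels))
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette needs >= 2 clusters")
    s = silhouette_samples(X, labels, metric="euclidean")
    scores = pd.Series(s, index=index, name="silhouette")
    return SilhouetteResult(scores=scores, average_width=float(s.mean()))


def compare_schemes(s_a: pd.Series, s_b: pd.Series) -> TestResult:
    """Paired two-sided Wilcoxon signed-rank on per-sample silhouettes.

    Both inputs must cover the same samples (pairing by sample id).  The
    exact null distribution is used for small n without ties; otherwise the
    normal approximation with continuity correction.  All-zero differences
    (identical score vectors) return p = 1 with a warning.
    """
    s_a, s_b = pd.Series(s_a), pd.Series(s_b)
    if set(s_a.index) != set(s_b.index):
        raise ValueError("compare_schemes requires paired per-sample scores")
    diffs = (s_b - s_a.reindex(s_b.index)).to_numpy()
    extra = {"mean_a": float(s_a.mean()), "mean_b": float(s_b.mean())}
    if np.all(diffs == 0):
        warnings.warn("all paired differences are zero; returning p = 1", stacklevel=2)
        return TestResult(0.0, 1.0, "wilcoxon_signed_rank", extra=extra)
    res = stats.wilcoxon(diffs, alternative="two-sided", correction=True, method="auto")
    return TestResult(float(res.statistic), float(res.pvalue), "wilcoxon_signed_rank", extra=extra)


def adjusted_rand(l1, l2) -> float:
    """Adjusted Rand index between two labelings of the same samples."""
    l1, l2 = np.asarray(pd.Series(l1)), np.asarray(pd.Series(l2))
    if l1.shape != l2.shape:
        raise ValueError("label vectors must cover the same samples")
    return float(adjusted_rand_score(l1, l2))


def chi_squared_table(table: np.ndarray | pd.DataFrame) -> TestResult:
    """Pearson chi-squared (no continuity correction) on a contingency table."""
    table = np.asarray(table, dtype=float)
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("contingency table needs >= 2 rows and columns")
    if table.sum() == 0:
        raise ValueError("contingency table is empty")
    stat, p, df, _ = stats.chi2_contingency(table, correction=False)
    return TestResult(float(stat), float(p), "chi_squared", df=int(df))


def subtype_distribution_test(labels_a, labels_b) -> TestResult:
    """Chi-squared homogeneity test on two subtype label distributions.

    Builds the 2 x L table of label counts under parameterizations A and B
    (identical count vectors give statistic 0, p = 1).
    """
    ca = pd.Series(labels_a).value_counts()
    cb = pd.Series(labels_b).value_counts()
    levels = sorted(set(ca.index) | set(cb.index))
    table = np.vstack([ca.reindex(levels, fill_value=0), cb.reindex(levels, fill_value=0)])
    keep = table.sum(axis=0) > 0
    return chi_squared_table(table[:, keep])


def km_curve(times, events, group_labels=None) -> dict[str, SurvivalCurve]:
    """Kaplan-Meier product-limit estimate per group.

    ``times`` in months, ``events`` in {0, 1} (0 = censored).  With no
    ``group_labels`` a single group named "all" is fitted.
    """
    times = pd.Series(times, dtype=float).reset_index(drop=True)
    events = pd.Series(events, dtype=float).reset_index(drop=True)
    if (times < 0).any():
        raise ValueError("times must be non-negative")
    if not events.isin([0.0, 1.0]).all():
        raise ValueError("events must be 0/1")
    if group_labels is None:
        group_labels = pd.Series(["all"] * len(times))
    group_labels = pd.Series(group_labels).reset_index(drop=True)

    out: dict[str, SurvivalCurve] = {}
    for grp in pd.unique(group_labels):
        mask = (group_labels == grp).to_numpy()
        if mask.sum() == 0:
            raise ValueError(f"empty group {grp!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], event_observed=events[mask])
        table = kmf.event_table
        has_event = table["observed"] > 0
        t = table.index.to_numpy()[has_event]
        out[str(grp)] = SurvivalCurve(
            event_times=t.astype(float),
            at_risk=table["at_risk"].to_numpy()[has_event].astype(int),
            events=table["observed"].to_numpy()[has_event].astype(int),
            survival=kmf.survival_function_at_times(t).to_numpy(),
        )
    return out


def logrank(times, events, group_labels) -> TestResult:
    """k-group log-rank test (chi-squared with k-1 df)."""
    times = pd.Series(times, dtype=float).reset_index(drop=True)
    events = pd.Series(events, dtype=float).reset_index(drop=True)
    groups = pd.Series(group_labels).reset_index(drop=True)
    k = groups.nunique()
    if k < 2:
        raise ValueError("log-rank needs >= 2 groups")
    if events.sum() == 0:
        raise ValueError("log-rank needs >= 1 event")
    res = multivariate_logrank_test(times, groups, events)
    return TestResult(float(res.test_statistic), float(res.p_value), "logrank", df=k - 1)
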