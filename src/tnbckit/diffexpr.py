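"""One-vs-rest and two-group differential expression on log2 expression.

Per gene, a two-sample t-test (Welch by default) compares a group against
the rest of the cohort; p-values are Benjamini-Hochberg adjusted within
each contrast, and a gene is called significant only when the adjusted p
falls below ``alpha`` AND its linear fold change is at least ``fc_min``
in either direction (FC >= fc_min or FC <= 1/fc_min).  Because the input
is log2-scale, log2fc is simply the difference of group means and
fold_change = 2**log2fc.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expr_data import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class DEContrast:
    """A two-group contrast: ``group`` vs ``rest`` sample ids (disjoint, >= 2 each)."""

    group_samples: list[str]
    rest_samples: list[str]
    alpha: float = 0.05
    fc_min: float = 1.5
    test: str = "welch_t"

    def __post_init__(self) -> None:
        if len(self.group_samples) < 2 or len(self.rest_samples) < 2:
            raise ValueError("each side of the contrast needs >= 2 samples")
        if set(self.group_samples) & set(self.rest_samples):
            raise ValueError("group and rest sample sets must be disjoint")
        if self.test not in ("welch_t", "student_t"):
            raise ValueError(f"unknown test {self.test!r}")
        if self.fc_min < 1:
            raise ValueError("fc_min must be >= 1")


def de_test(m: ExpressionMatrix, c: DEContrast) -> pd.DataFrame:
    """Per-gene differential expression for one contrast.

    Returns a DataFrame indexed by gene with columns log2fc, fold_change,
    p, p_adj, direction, significant.  Genes with zero variance in both
    groups get p = 1 when the means are equal (no evidence either way) and
    p = 0 when they differ (an exact separation on constant values).
    """
    G = m.values[c.group_samples].to_numpy()
    R = m.values[c.rest_samples].to_numpy()
    mean_g = G.mean(axis=1)
    mean_r = R.mean(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # 0/0 handled below
        t, p = stats.ttest_ind(G, R, axis=1, equal_var=(c.test == "student_t"))
    degenerate = np.isnan(p)
    if degenerate.any():
        equal = np.isclose(mean_g, mean_r)
        p = np.where(degenerate & equal, 1.0, p)
        p = np.where(degenerate & ~equal, 0.0, p)
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    log2fc = mean_g - mean_r
    fc = 2.0**log2fc
    significant = (p_adj < c.alpha) & ((fc >= c.fc_min) | (fc <= 1.0 / c.fc_min))
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "fold_change": fc,
            "p": p,
            "p_adj": p_adj,
            "direction": np.where(log2fc >= 0, "up", "down"),
            "significant": significant,
        },
        index=m.gene_ids,
    )


def one_vs_rest_all(
    m: ExpressionMatrix,
    labels: pd.Series,
    alpha: float = 0.05,
    fc_min: float = 1.5,
    test: str = "welch_t",
) -> dict[str, pd.DataFrame]:
    """One-vs-rest contrast per subtype, BH-adjusted within each contrast.

    Subtypes with a single sample are skipped with a warning.
    """
    labels = labels.reindex(m.sample_ids)
    if labels.isna().any():
        raise ValueError("labels missing for some samples")
    if labels.nunique() < 2:
        raise ValueError("need >= 2 subtypes")
    out: dict[str, pd.DataFrame] = {}
    for subtype, members in labels.groupby(labels):
        group = list(members.index.astype(str))
        rest = [s for s in m.sample_ids.astype(str) if s not in set(group)]
        if len(group) < 2:
            msg = f"subtype {subtype!r} has a single sample; contrast skipped"
            logger.warning(msg)
            warnings.warn(msg, stacklevel=2)
            continue
        c = DEContrast(group, rest, alpha=alpha, fc_min=fc_min, test=test)
        out[str(subtype)] = de_test(m, c)
    return out


def overlap_with_gene_set(de: pd.DataFrame, gene_set: list[str]) -> tuple[int, int]:
    """(number of significant genes intersecting gene_set, number significant)."""
    sig = set(de.index[de["significant"]].astype(str))
    return len(sig & set(map(str, gene_set))), len(sig)
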