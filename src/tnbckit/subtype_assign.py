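"""Centroid-based subtype classification and related labeling rules.

A sample is assigned to the subtype whose signature centroid its expression
profile correlates with best (Pearson, computed over the signature genes
after an optional cohort-level gene-wise scaling).  Supporting rules:

* an UNCLASSIFIED outcome when the best correlation is weak, the margin to
  the runner-up is too small, or the top correlations tie exactly —
  published centroid tools silently accept the bare argmax, which hides
  genuinely ambiguous samples;
* the mRNA-based ER-positive filter (sample flagged when its ESR1 value
  exceeds an upper-quartile threshold);
* the collapse of the six-subtype TNBC scheme {BL1, BL2, M, MSL, IM, LAR}
  onto the revised four subtypes {BL1, BL2, M, LAR} by re-assigning IM and
  MSL samples to their next-best retained centroid;
* the identical / partial / different agreement classes for a sample
  labeled under three parameterizations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .expr_data import ExpressionMatrix, ScalingSpec, scale_genes

logger = logging.getLogger(__name__)

UNCLASSIFIED = "UNCLASSIFIED"

LEHMANN_SIX = ("BL1", "BL2", "M", "MSL", "IM", "LAR")
LEHMANN_FOUR = ("BL1", "BL2", "M", "LAR")


@dataclass
class CentroidSignature:
    """Signature gene list with per-subtype centroid values.

    centroids
        DataFrame, genes x subtypes (column per subtype).
    scaling
        Gene-wise scaling applied to test cohorts before correlation (the
        published centroids were derived from scaled data, so test data
        must be brought onto the same scale).
    """

    centroids: pd.DataFrame
    scaling: ScalingSpec = field(default_factory=ScalingSpec)

    def __post_init__(self) -> None:
        if self.centroids.index.has_duplicates:
            raise ValueError("duplicate genes in signature")
        if self.centroids.shape[1] < 2:
            raise ValueError("signature needs >= 2 subtype centroids")
        const = self.centroids.nunique(axis=0) <= 1
        if const.any():
            raise ValueError(f"constant centroid columns: {list(self.centroids.columns[const])}")

    @property
    def subtype_names(self) -> list[str]:
        return list(self.centroids.columns.astype(str))

    @property
    def gene_ids(self) -> list[str]:
        return list(self.centroids.index.astype(str))

    @classmethod
    def read(cls, path: str | Path, scaling: ScalingSpec | None = None) -> "CentroidSignature":
        """Read a TSV with a gene_id column then one column per subtype."""
        table = pd.read_csv(path, sep="\t")
        if "gene_id" not in table.columns:
            raise ValueError(f"{path}: signature file needs a 'gene_id' column")
        table = table.set_index("gene_id")
        return cls(table.astype(float), scaling or ScalingSpec())

    def write(self, path: str | Path) -> None:
        out = self.centroids.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")


@dataclass
class AssignmentResult:
    """Per-sample outcome of centroid correlation."""

    sample_id: str
    correlations: dict[str, float]
    label: str
    margin: float
    er_positive: bool | None = None
    collapsed_label: str | None = None
    reason: str | None = None  # why UNCLASSIFIED, when applicable


def correlate_centroids(m: ExpressionMatrix, sig: CentroidSignature) -> pd.DataFrame:
    """Pearson correlation of every sample with every centroid.

    The cohort is scaled gene-wise per ``sig.scaling`` first; correlations
    are computed over the signature genes present in the matrix (missing
    signature genes are dropped pairwise and the dropped fraction logged;
    more than 50% missing is an error, fewer than 3 shared genes too).
    Samples with a constant profile over the signature genes get NaN
    correlations (downstream they become UNCLASSIFIED).

    Returns a samples x subtypes DataFrame of correlation coefficients.
    """
    shared = [g for g in sig.gene_ids if g in set(m.gene_ids.astype(str))]
    frac_missing = 1.0 - len(shared) / len(sig.gene_ids)
    if frac_missing > 0:
        logger.info("%.1f%% of signature genes absent from matrix", 100 * frac_missing)
    if frac_missing > 0.5:
        raise ValueError(
            f"{frac_missing:.0%} of signature genes missing from the matrix (> 50%)"
        )
    if len(shared) < 3:
        raise ValueError("fewer than 3 signature genes shared with the matrix")

    scaled = scale_genes(m.subset_genes(shared), sig.scaling)
    X = scaled.values.to_numpy()  # genes x samples
    C = sig.centroids.loc[shared].to_numpy()  # genes x subtypes

    Xc = X - X.mean(axis=0, keepdims=True)
    Cc = C - C.mean(axis=0, keepdims=True)
    xn = np.linalg.norm(Xc, axis=0)
    cn = np.linalg.norm(Cc, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ Cc) / np.outer(xn, cn)
    r[xn == 0, :] = np.nan  # constant sample profile: correlation undefined
    return pd.DataFrame(r, index=m.sample_ids, columns=sig.subtype_names)


def assign_subtype(
    corrs: pd.Series | dict[str, float],
    min_r: float = 0.1,
    min_margin: float = 0.0,
    sample_id: str = "",
) -> AssignmentResult:
    """Label one sample from its centroid-correlation vector.

    label = argmax correlation; UNCLASSIFIED when the best correlation is
    below ``min_r``, the margin over the runner-up is below ``min_margin``,
    an exact tie occurs at the top, or fewer than 2 correlations are finite.
    """
    corrs = pd.Series(corrs, dtype=float)
    finite = corrs.dropna()
    if len(finite) < 2:
        return AssignmentResult(
            sample_id, corrs.to_dict(), UNCLASSIFIED, 0.0, reason="undefined_correlations"
        )
    ordered = finite.sort_values(ascending=False, kind="stable")
    best, second = float(ordered.iloc[0]), float(ordered.iloc[1])
    margin = best - second
    if best == second:
        return AssignmentResult(sample_id, corrs.to_dict(), UNCLASSIFIED, 0.0, reason="tie")
    if best < min_r:
        return AssignmentResult(
            sample_id, corrs.to_dict(), UNCLASSIFIED, margin, reason="low_correlation"
        )
    if margin < min_margin:
        return AssignmentResult(
            sample_id, corrs.to_dict(), UNCLASSIFIED, margin, reason="low_margin"
        )
    return AssignmentResult(sample_id, corrs.to_dict(), str(ordered.index[0]), margin)


def assign_all(
    m: ExpressionMatrix,
    sig: CentroidSignature,
    min_r: float = 0.1,
    min_margin: float = 0.0,
    er_filter: str = "off",
    er_gene: str = "ESR1",
) -> pd.DataFrame:
    """Assign every sample; returns a tidy table.

    Columns: label, margin, one correlation column per subtype, er_positive
    (when the ER filter is on), reason (for UNCLASSIFIED samples).
    """
    corr = correlate_centroids(m, sig)
    results = [
        assign_subtype(corr.loc[s], min_r=min_r, min_margin=min_margin, sample_id=str(s))
        for s in corr.index
    ]
    out = corr.copy()
    out.insert(0, "label", [r.label for r in results])
    out.insert(1, "margin", [r.margin for r in results])
    out["reason"] = [r.reason for r in results]
    if er_filter != "off":
        out["er_positive"] = er_positive_filter(m, er_gene=er_gene, reference=er_filter)
    return out


def er_positive_filter(
    m: ExpressionMatrix,
    er_gene: str = "ESR1",
    reference: str = "within_sample",
) -> pd.Series:
    """Flag putatively ER-positive samples from ESR1 mRNA expression.

    ``within_sample`` (default): a sample is flagged when its ESR1 value
    strictly exceeds the upper quartile of all gene values within that
    sample — scale-free across platforms.  ``across_sample``: flagged when
    its ESR1 value exceeds the upper quartile of ESR1 across samples.
    Quartiles use linear interpolation.
    """
    if er_gene not in m.gene_ids:
        raise ValueError(f"ER gene {er_gene!r} absent from the matrix")
    er = m.values.loc[er_gene]
    if reference == "within_sample":
        q3 = m.values.quantile(0.75, axis=0)
        flags = er > q3
    elif reference == "across_sample":
        flags = er > float(np.quantile(er.to_numpy(), 0.75))
    else:
        raise ValueError(f"unknown reference {reference!r}")
    return flags.rename("er_positive")


def collapse_lehmann(res: AssignmentResult) -> AssignmentResult:
    """Collapse a six-subtype TNBC assignment onto the four retained subtypes.

    BL1/BL2/M/LAR labels pass through; IM and MSL samples move to the
    retained subtype with the highest correlation; an exact tie among the
    retained centroids propagates as UNCLASSIFIED; an UNCLASSIFIED input
    stays UNCLASSIFIED.
    """
    missing = [s for s in LEHMANN_SIX if s not in res.correlations]
    if missing:
        raise ValueError(f"missing correlations for subtypes {missing}")
    if res.label == UNCLASSIFIED:
        res.collapsed_label = UNCLASSIFIED
        return res
    if res.label in LEHMANN_FOUR:
        res.collapsed_label = res.label
        return res
    retained = pd.Series({s: res.correlations[s] for s in LEHMANN_FOUR}, dtype=float)
    ordered = retained.sort_values(ascending=False, kind="stable")
    if float(ordered.iloc[0]) == float(ordered.iloc[1]):
        res.collapsed_label = UNCLASSIFIED
        res.reason = "tie"
    else:
        res.collapsed_label = str(ordered.index[0])
    return res


def agreement_class(l1: str, l2: str, l3: str) -> str:
    """Agreement of three subtype labels for one sample.

    ``identical`` when all three agree, ``different`` when all three
    disagree pairwise, ``partial`` when exactly two distinct labels occur.
    """
    for lab in (l1, l2, l3):
        if lab is None or (isinstance(lab, float) and np.isnan(lab)):
            raise ValueError("agreement_class requires three non-missing labels")
    n_distinct = len({l1, l2, l3})
    return {1: "identical", 2: "partial", 3: "different"}[n_distinct]
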