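"""Additive batch-effect removal by per-gene linear-model residualization.

Microarray cohorts pooled from several datasets or platforms carry additive
per-gene location offsets that dominate unsupervised clustering if left in
place.  ``remove_batch`` fits, per gene, a least-squares model of expression
on batch (plus optional covariates whose effects are preserved) and
subtracts only the fitted batch terms, leaving the per-gene grand mean
unchanged.  ``correct_by_scheme`` implements the two pooling strategies
compared in cross-platform work: one joint correction over everything
(``pooled``) versus independent corrections within each platform
(``per_platform``).

Only location (additive) effects are removed; per-platform scale
differences are deliberately untouched — that limitation is exactly what
makes the per-platform scheme preferable when platforms differ in spread.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expr_data import ExpressionMatrix, merge_datasets

logger = logging.getLogger(__name__)


@dataclass
class BatchDesign:
    """Batch assignment (and optional preserved covariates) for correction.

    batch_of
        Mapping sample id -> batch level covering every sample.
    covariates_to_preserve
        Optional mapping sample id -> categorical level whose effect must
        NOT be removed (it enters the model so the batch coefficients are
        estimated net of it, but its fitted contribution stays in the data).
    """

    batch_of: dict[str, str]
    covariates_to_preserve: dict[str, str] | None = field(default=None)

    def levels(self) -> list[str]:
        return sorted(set(self.batch_of.values()))


def _design_from_matrix(m: ExpressionMatrix, batch_key: str = "batch") -> BatchDesign:
    return BatchDesign(batch_of=m.sample_meta[batch_key].astype(str).to_dict())


def remove_batch(
    m: ExpressionMatrix,
    design: BatchDesign | None = None,
    batch_key: str = "batch",
) -> ExpressionMatrix:
    """Subtract fitted per-gene batch terms from log expression.

    With a batch-only design this centers every batch of every gene onto
    the gene's grand mean, so per-gene batch means become equal and the
    grand mean is preserved exactly.  With preserved covariates a full
    least-squares fit (sum-to-zero batch encoding) is used and only the
    batch portion of the fit is subtracted.  A single batch level returns
    the input unchanged.
    """
    if design is None:
        design = _design_from_matrix(m, batch_key)
    batch = pd.Series(
        [design.batch_of[s] for s in m.sample_ids], index=m.sample_ids, dtype=str
    )
    levels = sorted(batch.unique())
    if len(levels) == 1:
        return m.copy()
    counts = batch.value_counts()
    small = counts[counts < 2]
    if not small.empty:
        raise ValueError(f"batches with <2 samples: {list(small.index)}")

    X = m.values.to_numpy()
    if design.covariates_to_preserve is None:
        # Saturated one-way model: batch term = batch mean - grand mean.
        grand = X.mean(axis=1, keepdims=True)
        corrected = X.copy()
        for lev in levels:
            cols = np.flatnonzero((batch == lev).to_numpy())
            bmean = X[:, cols].mean(axis=1, keepdims=True)
            corrected[:, cols] -= bmean - grand
        return m.with_values(corrected)

    # Full design: intercept + sum-coded batch + dummy-coded covariate.
    covar = pd.Series(
        [design.covariates_to_preserve[s] for s in m.sample_ids],
        index=m.sample_ids,
        dtype=str,
    )
    n = m.n_samples
    B = np.zeros((n, len(levels) - 1))
    for j, lev in enumerate(levels[:-1]):
        B[(batch == lev).to_numpy(), j] = 1.0
    B[(batch == levels[-1]).to_numpy(), :] = -1.0  # sum-to-zero contrast
    C = pd.get_dummies(covar, drop_first=True).to_numpy(dtype=float)
    D = np.column_stack([np.ones(n), B, C])
    rank = np.linalg.matrix_rank(D)
    if rank < D.shape[1]:
        raise ValueError(
            "singular design: batch is confounded with the preserved covariate "
            f"(rank {rank} < {D.shape[1]} columns)"
        )
    beta, *_ = np.linalg.lstsq(D, X.T, rcond=None)
    batch_cols = slice(1, 1 + B.shape[1])
    fitted_batch = B @ beta[batch_cols, :]
    return m.with_values(X - fitted_batch.T)


def correct_by_scheme(
    ms: list[ExpressionMatrix],
    scheme: str,
    min_genes: int = 500,
) -> list[ExpressionMatrix]:
    """Merge and batch-correct a set of datasets under a pooling scheme.

    ``pooled``
        Merge every dataset (across platforms) and run one correction with
        dataset as the batch factor; returns a singleton list.
    ``per_platform``
        Group datasets by platform, merge and correct within each platform,
        and return one corrected matrix per platform (platforms are kept
        separate downstream, e.g. as discovery/validation arms).  A platform
        holding a single dataset passes through uncorrected with a warning
        (no batch variation to estimate).
    """
    if scheme not in ("pooled", "per_platform"):
        raise ValueError(f"unknown scheme {scheme!r}")
    if scheme == "pooled":
        merged = merge_datasets(ms, min_genes=min_genes) if len(ms) > 1 else ms[0].copy()
        return [remove_batch(merged)]

    groups: dict[str, list[ExpressionMatrix]] = {}
    order: list[str] = []
    for m in ms:
        plats = m.sample_meta["platform"].astype(str).unique()
        if len(plats) != 1:
            raise ValueError("each input dataset must sit on a single platform")
        plat = plats[0]
        if plat not in groups:
            groups[plat] = []
            order.append(plat)
        groups[plat].append(m)
    out: list[ExpressionMatrix] = []
    for plat in order:
        group = groups[plat]
        if len(group) == 1:
            msg = (
                f"platform {plat!r} holds a single dataset; "
                "returned uncorrected (no batch variation to estimate)"
            )
            logger.warning(msg)
            warnings.warn(msg, stacklevel=2)
            out.append(group[0].copy())
        else:
            merged = merge_datasets(group, min_genes=min_genes)
            out.append(remove_batch(merged))
    return out
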