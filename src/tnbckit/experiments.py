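"""Desk-scale replications of the pipeline's methodological comparisons.

Each function runs one self-contained experiment on a synthetic cohort
drawn from the pre-registered fixtures: subtype-number recovery by
consensus clustering, the pooled vs per-platform batch-correction
comparison, centroid-classifier recovery, differential-expression
calibration, and survival stratification power/calibration.  They are the
workhorses of the acceptance checks and of ``scripts/acceptance.py``.

All randomness flows from the ``seed`` argument.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .batch_correct import correct_by_scheme, remove_batch
from .consensus_cluster import run_consensus, select_features
from .diffexpr import DEContrast, de_test
from .expr_data import ExpressionMatrix
from .outcome_eval import TestResult, adjusted_rand, compare_schemes, logrank, silhouette
from .subtype_assign import assign_all
from .synthetic_data import (
    CohortSpec,
    discovery_like_spec,
    make_signature_from_truth,
    simulate_cohort,
    simulate_from_signature,
    simulate_survival,
    two_platform_spec,
)


@dataclass
class KRecoveryResult:
    chosen_k: int
    ari: float
    A: dict[int, float]
    delta: dict[int, float]


def k_recovery_experiment(
    seed: int,
    n_iter: int = 250,
    k_range=range(2, 9),
    top_fraction: float = 0.10,
) -> KRecoveryResult:
    """Discovery-shaped cohort -> batch correction -> consensus clustering.

    Returns the chosen k and the adjusted Rand index of the labels at the
    true k (6) against the planted subtypes.
    """
    spec = discovery_like_spec(seed=seed)
    m, truth = simulate_cohort(spec)
    corrected = remove_batch(m)
    genes = select_features(corrected, top_fraction)
    run = run_consensus(
        corrected.subset_genes(genes), k_range=k_range, n_iter=n_iter, seed=seed
    )
    ari = adjusted_rand(truth.subtype_of, run.labels_series(6))
    return KRecoveryResult(chosen_k=run.chosen_k, ari=ari, A=run.A, delta=run.delta)


@dataclass
class SchemeComparisonResult:
    mean_width_pooled: float
    mean_width_per_platform: float
    wilcoxon: TestResult


def scheme_comparison_experiment(
    seed: int, top_fraction: float = 0.10, k: int = 6
) -> SchemeComparisonResult:
    """Pooled vs per-platform correction on the two-platform fixture.

    Both schemes are evaluated with the same downstream recipe: select the
    top-variance genes, cluster with k-means at the known subtype count,
    and score per-sample silhouette widths in that feature space.  The
    per-platform scheme scores each platform in its own space; samples are
    then paired across schemes for the Wilcoxon signed-rank comparison.
    """
    spec = two_platform_spec(seed=seed)
    m, truth = simulate_cohort(spec)
    datasets = [
        m.subset_samples(truth.batch_of.index[truth.batch_of == b])
        for b in truth.batch_of.unique()
    ]

    def scheme_scores(scheme: str) -> pd.Series:
        import logging
        import warnings

        # the validation platform holds one dataset by design: the
        # pass-through warning is expected here, not actionable
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            logger = logging.getLogger("tnbckit.batch_correct")
            level = logger.level
            logger.setLevel(logging.ERROR)
            try:
                arms = correct_by_scheme(datasets, scheme)
            finally:
                logger.setLevel(level)
        parts = []
        for i, arm in enumerate(arms):
            genes = select_features(arm, top_fraction)
            sub = arm.subset_genes(genes)
            km = KMeans(n_clusters=k, n_init=5, random_state=seed + i).fit(
                sub.values.to_numpy().T
            )
            parts.append(silhouette(sub, km.labels_).scores)
        return pd.concat(parts)

    pooled = scheme_scores("pooled")
    per_platform = scheme_scores("per_platform")
    test = compare_schemes(pooled, per_platform)
    return SchemeComparisonResult(
        mean_width_pooled=float(pooled.mean()),
        mean_width_per_platform=float(per_platform.mean()),
        wilcoxon=test,
    )


@dataclass
class ClassifierRecoveryResult:
    accuracy: float
    n_samples: int
    noiseless_accuracy: float
    noiseless_min_r: float


def classifier_recovery_experiment(
    seed: int,
    n_subtypes: int = 4,
    signature_genes: int = 80,
    n_samples: int = 1000,
    noise_sd: float = 0.5,
) -> ClassifierRecoveryResult:
    """Centroid-classifier recovery on an 80-gene synthetic signature.

    A reference cohort supplies per-subtype centroids over 80 signature
    genes; fresh samples are drawn as centroid + Gaussian noise and
    assigned by Pearson correlation.  Also reports the noiseless control
    (accuracy must be perfect with correlation 1).
    """
    per = signature_genes // n_subtypes
    spec = CohortSpec(
        subtype_sizes={f"T{i + 1}": 50 for i in range(n_subtypes)},
        n_genes=signature_genes,
        module_genes_per_subtype=per,
        module_effect=2.0,
        noise_sd=0.5,
        seed=seed,
    )
    ref, truth = simulate_cohort(spec)
    sig = make_signature_from_truth(truth, ref)
    assert len(sig.gene_ids) == signature_genes

    n_per = n_samples // n_subtypes
    m, labels = simulate_from_signature(sig, n_per_subtype=n_per, noise_sd=noise_sd, seed=seed + 1)
    table = assign_all(m, sig, min_r=0.0)
    accuracy = float((table["label"] == labels).mean())

    m0, labels0 = simulate_from_signature(sig, n_per_subtype=25, noise_sd=0.0, seed=seed + 2)
    table0 = assign_all(m0, sig, min_r=0.0)
    acc0 = float((table0["label"] == labels0).mean())
    best_r = table0[sig.subtype_names].max(axis=1)
    return ClassifierRecoveryResult(
        accuracy=accuracy,
        n_samples=n_per * n_subtypes,
        noiseless_accuracy=acc0,
        noiseless_min_r=float(best_r.min()),
    )


@dataclass
class DECalibrationResult:
    sensitivity: float
    false_positives: int
    null_significant_fraction: float


def de_calibration_experiment(
    seed: int,
    n_genes: int = 1000,
    n_planted: int = 50,
    shift: float = 1.17,
    n_per_group: int = 20,
    noise_sd: float = 0.3,
) -> DECalibrationResult:
    """Planted-shift recovery and global-null calibration of the DE caller."""
    rng = np.random.default_rng(seed)
    gene_ids = [f"g{i:04d}" for i in range(n_genes)]
    samples = [f"s{j}" for j in range(2 * n_per_group)]
    base = rng.normal(7.0, noise_sd, size=(n_genes, 2 * n_per_group))
    base[:n_planted, :n_per_group] += shift
    m = ExpressionMatrix(pd.DataFrame(base, index=gene_ids, columns=samples))
    out = de_test(m, DEContrast(samples[:n_per_group], samples[n_per_group:]))
    hits = set(out.index[out["significant"]])
    planted = set(gene_ids[:n_planted])
    sensitivity = len(hits & planted) / n_planted
    false_positives = len(hits - planted)

    null = rng.normal(7.0, noise_sd, size=(n_genes, 2 * n_per_group))
    m_null = ExpressionMatrix(pd.DataFrame(null, index=gene_ids, columns=samples))
    out_null = de_test(m_null, DEContrast(samples[:n_per_group], samples[n_per_group:]))
    null_fraction = float(out_null["significant"].mean())
    return DECalibrationResult(sensitivity, false_positives, null_fraction)


def survival_null_pvalue(seed: int, n_per_group: int = 100, hazard: float = 0.02) -> float:
    """Log-rank p under equal hazards (two groups); should be U[0,1].

    Groups of 100 keep the chi-squared approximation of the log-rank
    statistic accurate; at markedly smaller event counts the approximation
    is mildly anticonservative.
    """
    spec = CohortSpec(
        subtype_sizes={"A": n_per_group, "B": n_per_group},
        n_genes=10,
        module_genes_per_subtype=2,
        hazards={"A": hazard, "B": hazard},
        censor_rate=0.3,
        seed=seed,
    )
    _, truth = simulate_cohort(spec)
    surv = simulate_survival(truth, spec)
    return logrank(surv["survival_time"], surv["event"], truth.subtype_of).p


def survival_power_pvalue(
    seed: int, n_per_group: int = 30, hazard_lo: float = 0.01, ratio: float = 4.0
) -> float:
    """Log-rank p under a hazard-ratio alternative."""
    spec = CohortSpec(
        subtype_sizes={"A": n_per_group, "B": n_per_group},
        n_genes=10,
        module_genes_per_subtype=2,
        hazards={"A": hazard_lo, "B": hazard_lo * ratio},
        censor_rate=0.3,
        seed=seed,
    )
    _, truth = simulate_cohort(spec)
    surv = simulate_survival(truth, spec)
    return logrank(surv["survival_time"], surv["event"], truth.subtype_of).p
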