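# tnbckit

Consensus-clustering discovery and centroid-based assignment of
triple-negative breast cancer (TNBC) molecular subtypes from log-scale
gene-expression matrices.

TNBC lacks the receptors targeted by standard breast-cancer therapies and
is biologically heterogeneous; expression-based subtypes (luminal androgen
receptor, mesenchymal, immunomodulatory, basal-like immunosuppressed, and
intermediate states) stratify prognosis and suggest treatment avenues.
Published subtyping studies disagree, however, and much of the
disagreement traces to methodological choices: tissue preservation (FFPE
vs fresh-frozen), how batch effects are removed across microarray
platforms, which genes and scaling are fed to the classifier, and how the
number of clusters is called.  `tnbckit` packages that whole workflow as
tested, seed-reproducible components so each choice can be made — and its
consequences measured — explicitly.

## What it does

* **Data handling** — dense log2 genes × samples matrices (TSV or GCT 1.2)
  with per-sample annotations; probe-to-gene collapsing (highest-mean
  probe); dataset merging on shared genes; gene-wise `none` / `standard` /
  `robust` scaling (robust = affine map of the [0.025, 0.975] quantile
  interval onto [−1, 1]).
* **Batch correction** — per-gene additive (location-only)
  residualization, `pooled` across platforms or `per_platform` with
  independent arms.
* **Subtype discovery** — Monti-style consensus k-means over subsamples
  (consensus matrix M_k), with the number of clusters chosen from the
  relative change Δ(k) of the area under the CDF of consensus indices.
* **Subtype assignment** — Pearson correlation against user-supplied
  centroid signatures, with UNCLASSIFIED guard rails (minimum correlation,
  minimum margin, ties), the mRNA ER-positive upper-quartile filter, the
  six-to-four subtype collapse, and identical/partial/different agreement
  classes across parameterizations.
* **Characterization** — one-vs-rest Welch-t differential expression
  (BH-FDR < 0.05 and fold change ≥ 1.5), silhouette / adjusted Rand /
  chi-squared concordance statistics, Kaplan–Meier curves and the log-rank
  test.
* **Synthetic cohorts** — a generator that plants subtypes, gene modules,
  batch/platform/FFPE artifacts, and subtype-linked exponential survival,
  so the full pipeline is testable offline.

The core selection statistic: with A(k) the area under the empirical CDF
of consensus-matrix entries, Δ(2) = A(2) and
Δ(k) = (A(k) − A(k−1)) / A(k−1); the chosen k is the largest k with
Δ(k) ≥ 0.05 (threshold configurable).  See `docs/methods.md` for the full
model, conventions, and known limitations.

## Worked example

```python
from tnbckit import (simulate_cohort, simulate_survival, remove_batch,
                     select_features, run_consensus, adjusted_rand,
                     one_vs_rest_all, logrank)
from tnbckit.synthetic_data import discovery_like_spec

spec = discovery_like_spec(seed=1)           # 457 samples, 6 subtypes, 3 batches
cohort, truth = simulate_cohort(spec)
corrected = remove_batch(cohort)             # dataset-as-batch correction
genes = select_features(corrected, top_fraction=0.10)
run = run_consensus(corrected.subset_genes(genes), k_range=range(2, 9),
                    n_iter=250, seed=1)
print(f"chosen k = {run.chosen_k}")
print("delta:", {k: round(v, 3) for k, v in run.delta.items()})
labels = run.labels_series()
print(f"ARI vs planted subtypes = {adjusted_rand(truth.subtype_of, labels):.3f}")

de = one_vs_rest_all(corrected, labels)
print("significant genes per cluster:",
      {c: int(t['significant'].sum()) for c, t in de.items()})

surv = simulate_survival(truth, spec)
lr = logrank(surv["survival_time"], surv["event"], labels)
print(f"log-rank chi2 = {lr.statistic:.2f} (df={lr.df}), p = {lr.p:.2e}")
```

Output:

```
chosen k = 6
delta: {2: 0.369, 3: 0.542, 4: 0.218, 5: 0.122, 6: 0.065, 7: 0.02, 8: 0.013}
ARI vs planted subtypes = 1.000
significant genes per cluster: {'1': 30, '2': 31, '3': 30, '4': 30, '5': 31, '6': 30}
log-rank chi2 = 65.64 (df=5), p = 8.26e-13
```

Reading the numbers: Δ(k) stays above the 0.05 threshold up to k = 6 and
collapses beyond it, so the elbow rule selects six clusters; the labels at
k = 6 reproduce the planted subtypes exactly (ARI 1.0); each cluster's
one-vs-rest contrast recovers its planted 30-gene module (the occasional
31st gene is a borderline neighbor); and because the generator ties hazard
rates to subtypes, the discovered clusters stratify survival strongly.

A command-line interface mirrors the library
(`tnbckit simulate | correct | cluster | assign | de | evaluate | survive |
run-all`); `tnbckit run-all --config run.yaml` executes the whole
discovery/validation workflow from one YAML file and writes labels, the
A/Δ table, DE tables, assignment tables, and a manifest that reproduces
the run bit-for-bit.

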