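"""Synthetic expression cohorts with the structure the pipeline assumes.

The generator plants everything the analysis later tries to recover:
latent subtypes each marked by a disjoint gene module with an additive
log2 shift, per-gene x per-batch offsets, per-platform affine (location +
scale) transforms, an FFPE-like shift restricted to a random gene subset,
and subtype-dependent exponential survival with independent exponential
censoring.  The emitted :class:`~tnbckit.expr_data.ExpressionMatrix` is
what the pipeline sees; the parallel :class:`SyntheticTruth` (planted
labels, module memberships, the artifact-free matrix) exists only for
evaluation — the pipeline never reads it.

Model, per gene g and sample s:

    x_gs = mu_g + delta * 1[g in module(subtype(s))] + b_{g,batch(s)} + eps_gs
    mu_g ~ Normal(baseline_mean, baseline_gene_sd^2)
    b_gB ~ Normal(0, offset_sd_B^2),   eps_gs ~ Normal(0, noise_sd^2)

then per-platform  x <- location_shift + scale_factor * x,  then the FFPE
shift on affected genes of FFPE samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expr_data import ExpressionMatrix, ScalingSpec
from .subtype_assign import CentroidSignature


@dataclass
class BatchSpec:
    """One batch (typically one source dataset)."""

    n_samples: int
    offset_sd: float = 0.0  # SD of the per-gene additive batch offset
    platform: str = "platformA"
    preservation: str = "FF"


@dataclass
class PlatformSpec:
    """Affine per-sample transform applied after the additive model."""

    location_shift: float = 0.0
    scale_factor: float = 1.0


@dataclass
class FFPESpec:
    """Preservation artifact: an additive shift on a random gene subset."""

    affected_gene_fraction: float = 0.1
    shift: float = 1.0


@dataclass
class CohortSpec:
    """Full description of a synthetic cohort.

    subtype_sizes maps subtype name -> sample count; batches map batch
    name -> :class:`BatchSpec` (sizes must sum to the same total).  Samples
    are allocated to batches stratified by subtype (default), keeping
    batch and subtype approximately independent as in multi-center
    collections; ``batch_assignment="random"`` permutes instead.
    ``module_effect`` is the log2 shift delta of a subtype's module genes
    (the fold-change calling boundary of the DE stage is log2 1.5 = 0.585,
    so delta = 2 is a strong, clearly separable subtype signal).
    Hazards are exponential event rates per month.
    """

    subtype_sizes: dict[str, int]
    n_genes: int = 1000
    module_genes_per_subtype: int = 30
    module_effect: float = 2.0
    baseline_mean: float = 7.0
    baseline_gene_sd: float = 1.5
    noise_sd: float = 0.5
    batches: dict[str, BatchSpec] = field(default_factory=dict)
    platforms: dict[str, PlatformSpec] = field(default_factory=dict)
    ffpe: FFPESpec | None = None
    hazards: dict[str, float] = field(default_factory=dict)
    censor_rate: float = 0.0
    batch_assignment: str = "stratified"
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return sum(self.subtype_sizes.values())

    def validate(self) -> None:
        if not self.subtype_sizes:
            raise ValueError("need at least one subtype")
        if any(n <= 0 for n in self.subtype_sizes.values()):
            raise ValueError("subtype sizes must be positive")
        n_module = self.module_genes_per_subtype * len(self.subtype_sizes)
        if n_module > self.n_genes:
            raise ValueError(
                f"{n_module} module genes exceed n_genes={self.n_genes}; modules are disjoint"
            )
        for val, name in [
            (self.baseline_gene_sd, "baseline_gene_sd"),
            (self.noise_sd, "noise_sd"),
        ]:
            if val < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.batches:
            total = sum(b.n_samples for b in self.batches.values())
            if total != self.n_samples:
                raise ValueError(
                    f"batch sizes sum to {total}, subtype sizes to {self.n_samples}"
                )
            for name, b in self.batches.items():
                if b.offset_sd < 0:
                    raise ValueError(f"batch {name!r}: offset_sd must be >= 0")
        if self.hazards:
            missing = set(self.subtype_sizes) - set(self.hazards)
            if missing:
                raise ValueError(f"hazards missing for subtypes {sorted(missing)}")
            if any(h <= 0 for h in self.hazards.values()):
                raise ValueError("hazards must be > 0")
        if not (0.0 <= self.censor_rate < 1.0):
            raise ValueError("censor_rate must lie in [0, 1)")
        if self.ffpe is not None and not (0.0 < self.ffpe.affected_gene_fraction <= 1.0):
            raise ValueError("affected_gene_fraction must lie in (0, 1]")
        if self.batch_assignment not in ("stratified", "random"):
            raise ValueError(f"unknown batch_assignment {self.batch_assignment!r}")


@dataclass
class SyntheticTruth:
    """Planted structure of a simulated cohort (evaluation only)."""

    subtype_of: pd.Series
    batch_of: pd.Series
    platform_of: pd.Series
    preservation_of: pd.Series
    module_of: pd.Series  # gene -> subtype name or None
    clean_matrix: pd.DataFrame  # baseline + module + noise, no artifacts
    hazards: dict[str, float]

    def module_genes(self, subtype: str | None = None) -> list[str]:
        if subtype is None:
            return list(self.module_of.dropna().index.astype(str))
        return list(self.module_of.index[self.module_of == subtype].astype(str))


def simulate_cohort(spec: CohortSpec) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Draw one cohort; bit-identical for identical spec (incl. seed)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    G, n = spec.n_genes, spec.n_samples
    gene_ids = pd.Index([f"G{i + 1:05d}" for i in range(G)], name="gene_id")
    sample_ids = pd.Index([f"S{i + 1:04d}" for i in range(n)], name="sample_id")
    subtypes = list(spec.subtype_sizes)

    # disjoint module gene sets, one per subtype
    mgs = spec.module_genes_per_subtype
    module_pool = rng.choice(G, size=mgs * len(subtypes), replace=False)
    module_of = pd.Series([None] * G, index=gene_ids, dtype=object)
    module_rows: dict[str, np.ndarray] = {}
    for i, st in enumerate(subtypes):
        rows = np.sort(module_pool[i * mgs : (i + 1) * mgs])
        module_rows[st] = rows
        module_of.iloc[rows] = st

    subtype_of = pd.Series(
        np.repeat(subtypes, [spec.subtype_sizes[st] for st in subtypes]),
        index=sample_ids,
        name="subtype",
    )

    # batch allocation: stratified keeps composition balanced across batches
    batches = spec.batches or {"batch1": BatchSpec(n_samples=n)}
    batch_names = list(batches)
    if spec.batch_assignment == "random":
        order = rng.permutation(n)
    else:
        order = np.concatenate(
            [rng.permutation(np.flatnonzero((subtype_of == st).to_numpy())) for st in subtypes]
        )
        # interleave subtype blocks so contiguous batch slices stay balanced
        order = order[_interleave_index(n, [spec.subtype_sizes[st] for st in subtypes])]
    batch_of = pd.Series(index=sample_ids, dtype=object, name="batch")
    start = 0
    for name in batch_names:
        cnt = batches[name].n_samples
        batch_of.iloc[order[start : start + cnt]] = name
        start += cnt
    platform_of = batch_of.map({b: batches[b].platform for b in batch_names}).rename("platform")
    preservation_of = batch_of.map(
        {b: batches[b].preservation for b in batch_names}
    ).rename("preservation")

    # additive model
    mu = rng.normal(spec.baseline_mean, spec.baseline_gene_sd, size=G)
    clean = np.tile(mu[:, None], (1, n))
    for st in subtypes:
        cols = np.flatnonzero((subtype_of == st).to_numpy())
        clean[np.ix_(module_rows[st], cols)] += spec.module_effect
    noise = rng.normal(0.0, spec.noise_sd, size=(G, n)) if spec.noise_sd > 0 else 0.0
    clean = clean + noise

    # Batch offsets are identifiable only up to a per-gene constant, so they
    # are centered (weighted by batch size) to make clean_matrix the
    # canonical artifact-free representative that additive correction targets.
    x = clean.copy()
    if len(batch_names) > 1 and any(batches[b].offset_sd > 0 for b in batch_names):
        offsets = np.column_stack(
            [
                rng.normal(0.0, batches[b].offset_sd, size=G)
                if batches[b].offset_sd > 0
                else np.zeros(G)
                for b in batch_names
            ]
        )
        weights = np.array([batches[b].n_samples for b in batch_names], dtype=float)
        weights /= weights.sum()
        offsets -= (offsets * weights).sum(axis=1, keepdims=True)
        for j, name in enumerate(batch_names):
            cols = np.flatnonzero((batch_of == name).to_numpy())
            x[:, cols] += offsets[:, j][:, None]

    platforms = spec.platforms or {}
    for pname in pd.unique(platform_of):
        p = platforms.get(pname, PlatformSpec())
        cols = np.flatnonzero((platform_of == pname).to_numpy())
        x[:, cols] = p.location_shift + p.scale_factor * x[:, cols]

    if spec.ffpe is not None:
        n_aff = max(1, int(round(spec.ffpe.affected_gene_fraction * G)))
        affected = rng.choice(G, size=n_aff, replace=False)
        ffpe_cols = np.flatnonzero((preservation_of == "FFPE").to_numpy())
        if ffpe_cols.size:
            x[np.ix_(affected, ffpe_cols)] += spec.ffpe.shift

    meta = pd.DataFrame(
        {
            "dataset_id": batch_of,
            "batch": batch_of,
            "platform": platform_of,
            "preservation": preservation_of,
        }
    )
    matrix = ExpressionMatrix(pd.DataFrame(x, index=gene_ids, columns=sample_ids), meta)
    truth = SyntheticTruth(
        subtype_of=subtype_of,
        batch_of=batch_of,
        platform_of=platform_of,
        preservation_of=preservation_of,
        module_of=module_of,
        clean_matrix=pd.DataFrame(clean, index=gene_ids, columns=sample_ids),
        hazards=dict(spec.hazards),
    )
    return matrix, truth


def _interleave_index(n: int, block_sizes: list[int]) -> np.ndarray:
    """Order that interleaves consecutive blocks proportionally.

    Samples are sorted by their within-block quantile rank, so any
    contiguous slice holds a near-proportional mix of every block.
    """
    quantile = np.concatenate([(np.arange(size) + 0.5) / size for size in block_sizes])
    return np.argsort(quantile, kind="stable")


def simulate_survival(
    truth: SyntheticTruth, spec: CohortSpec, seed: int | None = None
) -> pd.DataFrame:
    """Exponential survival with independent exponential censoring.

    Event time ~ Exp(hazard(subtype)).  The censoring rate is set per
    subtype to c = censor_rate/(1-censor_rate) * hazard, which makes the
    expected censored fraction equal ``censor_rate`` exactly within every
    subtype.  Returns a DataFrame with survival_time (months) and event.
    By default the RNG stream is derived from spec.seed but distinct from
    the cohort stream, so the cohort is identical with or without survival.
    """
    if not truth.hazards:
        raise ValueError("spec/truth carries no hazards")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed if seed is None else seed, 0x5EED]))
    rates = truth.subtype_of.map(truth.hazards).to_numpy(dtype=float)
    event_t = rng.exponential(1.0 / rates)
    if spec.censor_rate > 0:
        c = spec.censor_rate / (1.0 - spec.censor_rate) * rates
        censor_t = rng.exponential(1.0 / c)
        time = np.minimum(event_t, censor_t)
        event = (event_t <= censor_t).astype(int)
    else:
        time, event = event_t, np.ones(len(event_t), dtype=int)
    return pd.DataFrame(
        {"survival_time": time, "event": event}, index=truth.subtype_of.index
    )


def make_signature_from_truth(
    truth: SyntheticTruth,
    m: ExpressionMatrix,
    genes: list[str] | None = None,
    scaling: ScalingSpec | None = None,
) -> CentroidSignature:
    """Centroid signature from planted labels: per-subtype means over module genes.

    ``genes`` restricts the signature (default: the union of all module
    genes).  The result is a drop-in for a published centroid file.
    """
    subtypes = list(pd.unique(truth.subtype_of))
    if len(subtypes) < 2:
        raise ValueError("need >= 2 subtypes for a signature")
    genes = genes if genes is not None else truth.module_genes()
    cols = {}
    for st in subtypes:
        samples = truth.subtype_of.index[truth.subtype_of == st]
        cols[st] = m.values.loc[genes, samples].mean(axis=1)
    centroids = pd.DataFrame(cols)
    return CentroidSignature(centroids, scaling or ScalingSpec())


def simulate_from_signature(
    sig: CentroidSignature,
    n_per_subtype: int,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[ExpressionMatrix, pd.Series]:
    """Samples drawn as centroid + Normal(0, noise_sd^2) noise, with truth labels."""
    rng = np.random.default_rng(seed)
    cols, labels = [], []
    for st in sig.subtype_names:
        c = sig.centroids[st].to_numpy()
        cols.append(c[:, None] + rng.normal(0.0, noise_sd, size=(len(c), n_per_subtype)))
        labels += [st] * n_per_subtype
    values = np.concatenate(cols, axis=1)
    sample_ids = pd.Index([f"S{i + 1:04d}" for i in range(values.shape[1])], name="sample_id")
    m = ExpressionMatrix(pd.DataFrame(values, index=sig.centroids.index, columns=sample_ids))
    return m, pd.Series(labels, index=sample_ids, name="subtype")


# ---------------------------------------------------------------------------
# Pre-registered fixtures mirroring the study's cohort shapes
# ---------------------------------------------------------------------------

#: six near-balanced subtypes, 457 samples.  The relative-area-change
#: statistic used for k selection gains ~n_i*n_j/P when two clusters split,
#: so strongly unequal cluster sizes push the Δ at the true k below any
#: fixed threshold; near-balanced prevalences keep the elbow detectable.
DISCOVERY_SUBTYPE_SIZES = {
    "BLIS": 77,
    "IM": 76,
    "LAR": 76,
    "MES": 76,
    "INT1": 76,
    "INT2": 76,
}

#: per-month exponential rates; BLIS worst, IM best (4x spread within range)
DISCOVERY_HAZARDS = {
    "BLIS": 0.030,
    "IM": 0.008,
    "LAR": 0.015,
    "MES": 0.018,
    "INT1": 0.012,
    "INT2": 0.020,
}


def discovery_like_spec(seed: int = 0, **overrides) -> CohortSpec:
    """Discovery-arm shaped cohort: 457 samples, 3 batches, one platform."""
    spec = CohortSpec(
        subtype_sizes=dict(DISCOVERY_SUBTYPE_SIZES),
        n_genes=1000,
        module_genes_per_subtype=30,
        module_effect=2.0,
        noise_sd=0.5,
        batches={
            "dsetA": BatchSpec(200, offset_sd=0.8, platform="U133Plus2"),
            "dsetB": BatchSpec(30, offset_sd=0.8, platform="U133Plus2"),
            "dsetC": BatchSpec(227, offset_sd=0.8, platform="U133Plus2"),
        },
        hazards=dict(DISCOVERY_HAZARDS),
        censor_rate=0.4,
        seed=seed,
    )
    for key, val in overrides.items():
        setattr(spec, key, val)
    spec.validate()
    return spec


def two_platform_spec(seed: int = 0, scale_ratio: float = 2.0, **overrides) -> CohortSpec:
    """Discovery + validation shaped cohort: 457 + 165 samples on two platforms.

    The second platform applies a location shift and a scale factor
    (default ratio 2), the location/scale disparity that additive batch
    correction cannot remove across platforms.
    """
    sizes = {st: round(n * 622 / 457) for st, n in DISCOVERY_SUBTYPE_SIZES.items()}
    sizes["BLIS"] += 622 - sum(sizes.values())  # rounding remainder
    spec = CohortSpec(
        subtype_sizes=sizes,
        n_genes=1000,
        module_genes_per_subtype=30,
        module_effect=2.0,
        noise_sd=0.5,
        batches={
            "dsetA": BatchSpec(200, offset_sd=0.8, platform="U133Plus2"),
            "dsetB": BatchSpec(30, offset_sd=0.8, platform="U133Plus2"),
            "dsetC": BatchSpec(227, offset_sd=0.8, platform="U133Plus2"),
            "dsetD": BatchSpec(165, offset_sd=0.8, platform="HTA20"),
        },
        platforms={
            "U133Plus2": PlatformSpec(0.0, 1.0),
            "HTA20": PlatformSpec(2.0, scale_ratio),
        },
        hazards=dict(DISCOVERY_HAZARDS),
        censor_rate=0.4,
        seed=seed,
    )
    for key, val in overrides.items():
        setattr(spec, key, val)
    spec.validate()
    return spec
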