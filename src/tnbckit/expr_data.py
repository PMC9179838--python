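"""Expression-matrix data model, file I/O, probe collapsing, merging, scaling.

The central container is :class:`ExpressionMatrix`: a dense genes x samples
matrix of log2 intensities plus a per-sample annotation table (dataset,
batch, platform, tissue preservation, optional survival columns).  All
downstream stages (batch correction, consensus clustering, centroid
assignment, differential expression, survival) consume this container.

Values are assumed to be on the log2 scale and fully observed; missingness
must be resolved (imputed or filtered) before construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: metadata columns guaranteed to exist on every ExpressionMatrix
META_COLUMNS = ("dataset_id", "batch", "platform", "preservation")
META_DEFAULT = "unspecified"
PRESERVATION_LEVELS = ("FF", "FFPE", "unknown")


class ParseError(ValueError):
    """Raised when an input file is malformed; message names the offending row/column."""


@dataclass(frozen=True)
class ScalingSpec:
    """Gene-wise scaling applied before clustering or centroid correlation.

    mode
        ``none`` (identity), ``standard`` ((x - mean)/SD, sample SD with
        n-1 denominator), or ``robust`` (affine map of the [q_lo, q_hi]
        quantile interval onto [-1, +1], no clipping).
    q_lo, q_hi
        Quantile anchors for robust scaling.  Quantiles are estimated by
        linear interpolation between order statistics.
    """

    mode: str = "none"
    q_lo: float = 0.025
    q_hi: float = 0.975

    def __post_init__(self) -> None:
        if self.mode not in ("none", "standard", "robust"):
            raise ValueError(f"unknown scaling mode {self.mode!r}")
        if not (0.0 <= self.q_lo < self.q_hi <= 1.0):
            raise ValueError(f"require 0 <= q_lo < q_hi <= 1, got ({self.q_lo}, {self.q_hi})")


@dataclass
class ProbeMap:
    """Probe -> (gene_id, gene_symbol) mapping.

    A probe targeting multiple genes keeps only the first gene listed in
    its annotation (Affymetrix ``///`` convention).
    """

    gene_of: dict[str, str] = field(default_factory=dict)
    symbol_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for probe, gene in self.gene_of.items():
            if not gene:
                raise ValueError(f"empty gene_id for probe {probe!r}")

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "ProbeMap":
        """Build from a table with columns probe_id, gene_id[, gene_symbol].

        Multi-gene annotations separated by '///' are truncated to the first
        gene.  Probes whose gene annotation is empty are dropped.
        """
        if table["probe_id"].duplicated().any():
            dup = table["probe_id"][table["probe_id"].duplicated()].iloc[0]
            raise ParseError(f"duplicate probe_id {dup!r} in probe map")
        gene_of: dict[str, str] = {}
        symbol_of: dict[str, str] = {}
        has_symbol = "gene_symbol" in table.columns
        for _, row in table.iterrows():
            gene = str(row["gene_id"]).split("///")[0].strip()
            if not gene or gene.lower() in ("nan", "na", ""):
                continue
            probe = str(row["probe_id"])
            gene_of[probe] = gene
            if has_symbol:
                symbol_of[probe] = str(row["gene_symbol"]).split("///")[0].strip()
        return cls(gene_of=gene_of, symbol_of=symbol_of)

    @classmethod
    def read(cls, path: str | Path) -> "ProbeMap":
        return cls.from_table(pd.read_csv(path, sep="\t", dtype=str))


class ExpressionMatrix:
    """Dense log2 expression, genes x samples, with per-sample annotations.

    Parameters
    ----------
    values
        DataFrame with gene ids as index and sample ids as columns; all
        entries finite.
    sample_meta
        Optional DataFrame indexed by sample id.  Missing samples or
        columns are filled with ``"unspecified"`` (``"unknown"`` for
        preservation); survival columns (``survival_time`` in months,
        ``event`` in {0, 1}) stay absent unless provided.
    """

    def __init__(self, values: pd.DataFrame, sample_meta: pd.DataFrame | None = None):
        values = values.astype(float)
        if values.index.has_duplicates:
            dup = values.index[values.index.duplicated()][0]
            raise ValueError(f"duplicate gene id {dup!r}")
        if values.columns.has_duplicates:
            dup = values.columns[values.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r}")
        if not np.isfinite(values.to_numpy()).all():
            bad = np.argwhere(~np.isfinite(values.to_numpy()))[0]
            raise ValueError(
                f"non-finite value at gene {values.index[bad[0]]!r}, "
                f"sample {values.columns[bad[1]]!r}; resolve missingness upstream"
            )
        self.values = values
        self.sample_meta = _align_meta(values.columns, sample_meta)

    # -- convenience accessors ------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.sample_meta.copy())

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(genes)], self.sample_meta.copy())

    def subset_samples(self, samples) -> "ExpressionMatrix":
        samples = list(samples)
        return ExpressionMatrix(self.values[samples], self.sample_meta.loc[samples].copy())

    def with_values(self, arr: np.ndarray) -> "ExpressionMatrix":
        """Same genes/samples/metadata, new value array (shape preserved)."""
        if arr.shape != self.values.shape:
            raise ValueError("shape change not allowed")
        vals = pd.DataFrame(arr, index=self.gene_ids, columns=self.sample_ids)
        return ExpressionMatrix(vals, self.sample_meta.copy())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<ExpressionMatrix {self.n_genes} genes x {self.n_samples} samples>"


def _align_meta(sample_ids: pd.Index, meta: pd.DataFrame | None) -> pd.DataFrame:
    out = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    if meta is not None:
        meta = meta.copy()
        if meta.index.has_duplicates:
            dup = meta.index[meta.index.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r} in metadata")
        meta = meta.reindex(sample_ids)
        for col in meta.columns:
            out[col] = meta[col]
    for col in META_COLUMNS:
        default = "unknown" if col == "preservation" else META_DEFAULT
        if col not in out.columns:
            out[col] = default
        else:
            out[col] = out[col].fillna(default).astype(str)
    if "event" in out.columns:
        non_na = out["event"].dropna()
        if not non_na.isin([0, 1, 0.0, 1.0]).all():
            raise ValueError("event column must be 0/1")
    if "survival_time" in out.columns:
        non_na = pd.to_numeric(out["survival_time"].dropna())
        if (non_na < 0).any():
            raise ValueError("survival_time must be non-negative")
    return out


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_matrix(
    path: str | Path,
    format: str | None = None,
    meta_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Read a genes x samples matrix from TSV or GCT 1.2.

    TSV: header row ``gene_id<TAB>sample1<TAB>...``, one gene per row.
    GCT: ``#1.2`` line, ``rows<TAB>cols`` line, then Name/Description
    columns before the sample columns.  An optional metadata TSV keyed by
    ``sample_id`` supplies the annotation columns; samples without a
    metadata row get default levels.
    """
    path = Path(path)
    if format is None:
        format = "gct" if path.suffix.lower() == ".gct" else "tsv"
    if format == "gct":
        with open(path) as fh:
            version = fh.readline().strip()
            if version != "#1.2":
                raise ParseError(f"{path}: expected '#1.2' header, got {version!r}")
            dims = fh.readline().split()
            if len(dims) < 2:
                raise ParseError(f"{path}: malformed dimensions line")
            n_rows, n_cols = int(dims[0]), int(dims[1])
            body = pd.read_csv(fh, sep="\t", index_col=0, dtype={0: str})
        body = body.drop(columns=["Description"], errors="ignore")
        if body.shape != (n_rows, n_cols):
            raise ParseError(
                f"{path}: header declares {n_rows}x{n_cols}, body is "
                f"{body.shape[0]}x{body.shape[1]}"
            )
    elif format == "tsv":
        body = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    else:
        raise ValueError(f"unknown format {format!r}")

    for col in body.columns:
        coerced = pd.to_numeric(body[col], errors="coerce")
        bad = coerced.isna() & body[col].notna()
        if bad.any():
            raise ParseError(
                f"{path}: non-numeric cell at gene {body.index[bad.argmax()]!r}, column {col!r}"
            )
        body[col] = coerced
    body.index.name = "gene_id"
    if body.index.has_duplicates:
        dup = body.index[body.index.duplicated()][0]
        raise ParseError(f"{path}: duplicate gene row {dup!r}")
    if body.columns.has_duplicates:
        dup = body.columns[body.columns.duplicated()][0]
        raise ParseError(f"{path}: duplicate sample column {dup!r}")

    meta = read_sample_meta(meta_path) if meta_path is not None else None
    return ExpressionMatrix(body, meta)


def read_sample_meta(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    if "sample_id" not in meta.columns:
        raise ParseError(f"{path}: metadata requires a 'sample_id' column")
    if meta["sample_id"].duplicated().any():
        dup = meta["sample_id"][meta["sample_id"].duplicated()].iloc[0]
        raise ParseError(f"{path}: duplicate sample id {dup!r} in metadata")
    return meta.set_index("sample_id")


def write_matrix(
    m: ExpressionMatrix,
    path: str | Path,
    format: str = "tsv",
    meta_path: str | Path | None = None,
) -> None:
    """Write a matrix as TSV or GCT 1.2; full float precision (repr round-trip)."""
    path = Path(path)
    if format == "tsv":
        out = m.values.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")
    elif format == "gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{m.n_genes}\t{m.n_samples}\n")
            body = m.values.copy()
            body.insert(0, "Description", m.gene_ids)
            body.index.name = "Name"
            body.to_csv(fh, sep="\t")
    else:
        raise ValueError(f"unknown format {format!r}")
    if meta_path is not None:
        meta = m.sample_meta.copy()
        meta.index.name = "sample_id"
        meta.to_csv(meta_path, sep="\t")


# ---------------------------------------------------------------------------
# Probe collapsing
# ---------------------------------------------------------------------------

def collapse_probes(m: ExpressionMatrix, pm: ProbeMap) -> ExpressionMatrix:
    """Collapse a probe-level matrix to gene level.

    For each gene the probe with the highest average expression across
    samples represents the gene; ties break to the lexicographically
    smaller probe id.  Probes absent from the map are dropped.  Output
    genes are ordered by first appearance of any of their probes.
    """
    probes = [p for p in m.gene_ids if p in pm.gene_of]
    if not probes:
        raise ValueError("no probe id of the matrix appears in the probe map")
    means = m.values.loc[probes].mean(axis=1)
    best_probe: dict[str, str] = {}
    gene_order: list[str] = []
    for probe in probes:
        gene = pm.gene_of[probe]
        if gene not in best_probe:
            best_probe[gene] = probe
            gene_order.append(gene)
        else:
            cur = best_probe[gene]
            # higher mean wins; on equal means the smaller probe id wins
            if means[probe] > means[cur] or (means[probe] == means[cur] and probe < cur):
                best_probe[gene] = probe
    rows = m.values.loc[[best_probe[g] for g in gene_order]]
    rows.index = pd.Index(gene_order, name="gene_id")
    return ExpressionMatrix(rows, m.sample_meta.copy())


# ---------------------------------------------------------------------------
# Dataset merging
# ---------------------------------------------------------------------------

def merge_datasets(ms: list[ExpressionMatrix], min_genes: int = 500) -> ExpressionMatrix:
    """Concatenate cohorts on the intersection of their gene sets.

    Genes keep the first matrix's order restricted to the intersection;
    samples are concatenated; each sample's batch level is set to its
    dataset_id so batch correction can treat dataset as batch.
    """
    if len(ms) < 2:
        raise ValueError("need at least two matrices to merge")
    common = set(ms[0].gene_ids)
    for m in ms[1:]:
        common &= set(m.gene_ids)
    if len(common) < min_genes:
        sizes = ", ".join(str(m.n_genes) for m in ms)
        raise ValueError(
            f"gene intersection has {len(common)} genes (< min_genes={min_genes}); "
            f"input gene counts: {sizes}"
        )
    genes = [g for g in ms[0].gene_ids if g in common]
    seen: set[str] = set()
    for m in ms:
        overlap = seen & set(m.sample_ids)
        if overlap:
            raise ValueError(f"duplicate sample ids across inputs: {sorted(overlap)[:5]}")
        seen |= set(m.sample_ids)
    values = pd.concat([m.values.loc[genes] for m in ms], axis=1)
    meta = pd.concat([m.sample_meta for m in ms], axis=0)
    meta["batch"] = meta["dataset_id"].astype(str)
    return ExpressionMatrix(values, meta)


# ---------------------------------------------------------------------------
# Gene-wise scaling
# ---------------------------------------------------------------------------

def scale_genes(m: ExpressionMatrix, spec: ScalingSpec) -> ExpressionMatrix:
    """Apply a gene-wise scaling scheme across the cohort.

    ``standard``: (x - mean) / SD per gene (sample SD, n-1 denominator).
    ``robust``: 2 * (x - q_lo) / (q_hi - q_lo) - 1 per gene, mapping the
    [q_lo, q_hi] quantile interval onto [-1, +1] without clipping.
    """
    if spec.mode == "none":
        return m.copy()
    X = m.values.to_numpy()
    if spec.mode == "standard":
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, ddof=1, keepdims=True)
        bad = np.where(sd.ravel() == 0)[0]
        if bad.size:
            names = list(m.gene_ids[bad[:10]])
            raise ValueError(f"zero SD for genes {names}; cannot standard-scale")
        return m.with_values((X - mu) / sd)
    # robust
    lo = np.quantile(X, spec.q_lo, axis=1, keepdims=True)  # linear interpolation
    hi = np.quantile(X, spec.q_hi, axis=1, keepdims=True)
    span = hi - lo
    bad = np.where(span.ravel() <= 0)[0]
    if bad.size:
        names = list(m.gene_ids[bad[:10]])
        raise ValueError(f"degenerate quantile range for genes {names}; cannot robust-scale")
    return m.with_values(2.0 * (X - lo) / span - 1.0)
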