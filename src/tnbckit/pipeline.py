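"""Config-driven orchestration of the discovery/validation subtyping workflow.

One YAML config describes the whole run: input matrices and metadata, the
batch-correction scheme, feature-selection fraction, consensus-clustering
settings, optional centroid signatures, DE thresholds, and survival
options.  ``run_discovery_validation`` executes

    merge/correct per scheme -> select features per arm -> union ->
    consensus cluster each arm independently -> choose k ->
    one-vs-rest DE per arm -> optional centroid assignment ->
    optional survival stratification

and writes labels, the A/Δ table, DE tables, assignment tables, and a
manifest (config hash, seed, package versions) sufficient to re-run
bit-identically.  The arms (one per platform under the per-platform
scheme) share nothing fitted except the union gene list, so discovery and
validation stay independent.

Discovered clusters carry arbitrary integer names; mapping them onto
established subtype names (BLIS/IM/LAR/MES/...) is a post-hoc, user-driven
step after inspecting the DE tables and external assignments.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .batch_correct import correct_by_scheme
from .consensus_cluster import run_consensus, select_features, union_features
from .diffexpr import one_vs_rest_all
from .expr_data import ExpressionMatrix, ScalingSpec, read_matrix
from .outcome_eval import TestResult, chi_squared_table, km_curve, logrank
from .subtype_assign import CentroidSignature, assign_all

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated configuration for one full run."""

    matrices: list[str]
    meta: list[str | None]
    seed: int
    output_dir: str
    scheme: str = "per_platform"
    top_fraction: float = 0.10
    k_min: int = 2
    k_max: int = 10
    n_iter: int = 1000
    subsample_fraction: float = 0.8
    delta_threshold: float = 0.05
    force_k: int | None = None
    signatures: dict[str, dict] = field(default_factory=dict)
    de_alpha: float = 0.05
    de_fc_min: float = 1.5
    survival: bool = False
    min_genes: int = 500

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw, base=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict, base: Path | None = None) -> "RunConfig":
        if "seed" not in raw:
            raise ValueError("config must set an explicit seed")
        if "matrices" not in raw or not raw["matrices"]:
            raise ValueError("config must list input matrices")
        base = base or Path(".")
        matrices = [str((base / p)) for p in raw["matrices"]]
        meta = raw.get("meta") or [None] * len(matrices)
        meta = [str(base / p) if p else None for p in meta]
        if len(meta) != len(matrices):
            raise ValueError("meta list must match matrices list")
        cfg = cls(
            matrices=matrices,
            meta=meta,
            seed=int(raw["seed"]),
            output_dir=str(base / raw.get("output_dir", "run_out")),
            scheme=raw.get("scheme", "per_platform"),
            top_fraction=float(raw.get("top_fraction", 0.10)),
            k_min=int(raw.get("k_min", 2)),
            k_max=int(raw.get("k_max", 10)),
            n_iter=int(raw.get("n_iter", 1000)),
            subsample_fraction=float(raw.get("subsample_fraction", 0.8)),
            delta_threshold=float(raw.get("delta_threshold", 0.05)),
            force_k=raw.get("force_k"),
            signatures=raw.get("signatures", {}),
            de_alpha=float(raw.get("de_alpha", 0.05)),
            de_fc_min=float(raw.get("de_fc_min", 1.5)),
            survival=bool(raw.get("survival", False)),
            min_genes=int(raw.get("min_genes", 500)),
        )
        for p in cfg.matrices + [m for m in cfg.meta if m]:
            if not Path(p).exists():
                raise ValueError(f"input path does not exist: {p}")
        return cfg

    def canonical(self) -> str:
        return json.dumps(self.__dict__, sort_keys=True, default=str)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()[:16]


def run_discovery_validation(cfg: RunConfig) -> dict:
    """Execute the full workflow; returns a run report (also written to disk)."""
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"arms": {}, "config_hash": cfg.config_hash(), "seed": cfg.seed}

    stage = "load"
    try:
        ms = [read_matrix(p, meta_path=mp) for p, mp in zip(cfg.matrices, cfg.meta)]

        stage = "batch_correction"
        arms = correct_by_scheme(ms, cfg.scheme, min_genes=cfg.min_genes)
        arm_names = [_arm_name(a, i) for i, a in enumerate(arms)]

        stage = "feature_selection"
        per_arm_genes = [select_features(a, cfg.top_fraction) for a in arms]
        union: list[str] = []
        for genes in per_arm_genes:
            union = union_features(union, genes)
        pd.Series(union, name="gene_id").to_csv(outdir / "union_genes.tsv", sep="\t", index=False)

        for name, arm in zip(arm_names, arms):
            arm_report: dict = {}
            arm_genes = [g for g in union if g in set(arm.gene_ids.astype(str))]

            stage = f"consensus[{name}]"
            run = run_consensus(
                arm.subset_genes(arm_genes),
                k_range=range(cfg.k_min, cfg.k_max + 1),
                n_iter=cfg.n_iter,
                subsample_fraction=cfg.subsample_fraction,
                seed=_arm_seed(cfg.seed, name),
                threshold=cfg.delta_threshold,
                force_k=cfg.force_k,
            )
            arm_report["chosen_k"] = run.chosen_k
            arm_report["A"] = {int(k): v for k, v in run.A.items()}
            arm_report["delta"] = {int(k): v for k, v in run.delta.items()}
            areas = pd.DataFrame(
                {"k": list(run.A), "A": list(run.A.values()), "delta": list(run.delta.values())}
            )
            areas.to_csv(outdir / f"areas_{name}.tsv", sep="\t", index=False)
            labels_long = pd.concat(
                [
                    pd.DataFrame(
                        {"sample_id": run.sample_ids, "k": k, "label": run.labels[k]}
                    )
                    for k in run.k_range
                ]
            )
            labels_long.to_csv(outdir / f"labels_{name}.tsv", sep="\t", index=False)
            labels = run.labels_series()

            stage = f"diffexpr[{name}]"
            de = one_vs_rest_all(arm, labels, alpha=cfg.de_alpha, fc_min=cfg.de_fc_min)
            arm_report["de_significant"] = {}
            for subtype, table in de.items():
                table.to_csv(outdir / f"de_{name}_cluster{subtype}.tsv", sep="\t")
                arm_report["de_significant"][subtype] = int(table["significant"].sum())

            stage = f"assignment[{name}]"
            arm_report["assignments"] = {}
            for sig_name, sig_cfg in cfg.signatures.items():
                sig = CentroidSignature.read(
                    sig_cfg["path"], ScalingSpec(mode=sig_cfg.get("scaling", "none"))
                )
                table = assign_all(
                    arm,
                    sig,
                    min_r=float(sig_cfg.get("min_r", 0.1)),
                    er_filter=sig_cfg.get("er_filter", "off"),
                )
                table.to_csv(outdir / f"assign_{name}_{sig_name}.tsv", sep="\t")
                external = table["label"].copy()
                if "er_positive" in table.columns:
                    # ER-filtered samples are tabulated as their own group
                    external[table["er_positive"].fillna(False).astype(bool)] = "ERP"
                xtab, test = cross_tabulate(labels, external)
                xtab.to_csv(outdir / f"crosstab_{name}_{sig_name}.tsv", sep="\t")
                arm_report["assignments"][sig_name] = {
                    "chi2": test.statistic,
                    "p": test.p,
                }

            stage = f"survival[{name}]"
            if cfg.survival and "survival_time" in arm.sample_meta.columns:
                meta = arm.sample_meta.dropna(subset=["survival_time", "event"])
                common = labels.reindex(meta.index).dropna()
                meta = meta.loc[common.index]
                curves = km_curve(meta["survival_time"], meta["event"], common)
                coords = pd.concat(
                    [
                        pd.DataFrame(
                            {
                                "group": g,
                                "time": c.event_times,
                                "at_risk": c.at_risk,
                                "events": c.events,
                                "survival": c.survival,
                            }
                        )
                        for g, c in curves.items()
                    ]
                )
                coords.to_csv(outdir / f"km_{name}.tsv", sep="\t", index=False)
                lr = logrank(meta["survival_time"], meta["event"], common)
                arm_report["logrank"] = {"statistic": lr.statistic, "p": lr.p, "df": lr.df}

            report["arms"][name] = arm_report
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest = {
        "config": json.loads(cfg.canonical()),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "tnbckit_version": __version__,
        "versions": _library_versions(),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=float))
    return report


def cross_tabulate(labels_a, labels_b) -> tuple[pd.DataFrame, TestResult]:
    """Contingency table of two labelings plus a chi-squared independence test."""
    a = pd.Series(labels_a)
    b = pd.Series(labels_b)
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise ValueError("no shared samples between labelings")
    table = pd.crosstab(a.loc[shared], b.loc[shared])
    return table, chi_squared_table(table)


def _arm_name(arm: ExpressionMatrix, i: int) -> str:
    plats = arm.sample_meta["platform"].astype(str).unique()
    return plats[0] if len(plats) == 1 else f"arm{i}"


def _arm_seed(master: int, arm_name: str) -> int:
    digest = hashlib.sha256(f"{master}:{arm_name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _library_versions() -> dict[str, str]:
    import lifelines
    import numpy
    import pandas
    import scipy
    import sklearn

    return {
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "scikit-learn": sklearn.__version__,
        "lifelines": lifelines.__version__,
    }
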