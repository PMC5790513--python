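"""End-to-end orchestration: simulate-or-ingest, per-line DE, seed
selection, phenotype clustering, signature derivation, cohort
classification, and survival / association analysis.

The pipeline consumes a :class:`PipelineConfig` (typically from YAML) and
produces a :class:`RunReport` with per-stage summaries. Every stage draws
its randomness from a named per-stage seed, so a second run with the same
config reproduces every numeric output exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc, de_counts, de_linear, io, pam, seeds, survival
from .cluster import cluster_phenotypes
from .exceptions import ConfigurationError
from .io import CohortDataset, CountExperiment, log2_median_center
from .simulate import GroundTruthManifest, SimulationConfig, simulate_study

logger = logging.getLogger("sigforge")


@dataclass
class PipelineConfig:
    """Every tuning constant of the analysis in one place.

    Thresholds default to the conventional gates: per-line DE at
    ``fdr < 0.05`` and two-fold change, in-vivo DE at ``fdr < 0.05`` and
    1.5-fold change, 1000 K-means restarts, 10-fold CV over a 30-point
    shrinkage grid, and administrative censoring at five years.
    """

    simulation: SimulationConfig | None = None
    input_paths: dict | None = None

    q: float = 0.05
    fc_gate_log2: float = 1.0          # per-line count DE: two-fold
    invivo_fc_gate: float = 1.5        # cluster DE: 1.5-fold (linear)
    n_restarts: int = 1000
    n_folds: int = 10
    grid_size: int = 30
    horizon_years: float = 5.0
    covariates: list[str] = field(default_factory=lambda: ["age", "gender"])
    reference_levels: dict[str, str] = field(default_factory=dict)
    seeds: dict[str, int] = field(
        default_factory=lambda: {"cluster": 0, "cv": 0, "mc_null": 0})
    mc_null_reps: int = 1000

    def __post_init__(self) -> None:
        for name in ("q", "fc_gate_log2", "invivo_fc_gate", "horizon_years"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        for name in ("n_restarts", "n_folds", "grid_size"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        for stage in ("cluster", "cv", "mc_null"):
            if stage not in self.seeds:
                raise ConfigurationError(f"missing per-stage seed: {stage!r}")
        if self.simulation is None and self.input_paths is None:
            raise ConfigurationError(
                "either a simulation block or input paths are required"
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(
            simulation=SimulationConfig.from_dict(sim) if sim else None,
            **raw,
        )
        return cfg


@dataclass
class RunReport:
    """Per-stage summaries of one pipeline run."""

    stages: dict = field(default_factory=dict)
    input_hashes: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str | None:
        payload = {
            "stages": self.stages,
            "input_hashes": self.input_hashes,
            "seeds": self.seeds,
        }
        text = json.dumps(payload, indent=2, default=_jsonable)
        if path is not None:
            Path(path).write_text(text)
            return None
        return text


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (pd.Series,)):
        return obj.to_dict()
    if isinstance(obj, pd.Index):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _hash_frame(df: pd.DataFrame) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(df.to_numpy()).tobytes())
    h.update(",".join(map(str, df.index)).encode())
    h.update(",".join(map(str, df.columns)).encode())
    return h.hexdigest()[:16]


def _load_inputs(config: PipelineConfig
                 ) -> tuple[list[CountExperiment], list[CohortDataset],
                            GroundTruthManifest | None]:
    if config.simulation is not None:
        return simulate_study(config.simulation)
    paths = config.input_paths or {}
    experiments = [
        io.read_count_matrix(p["counts"], p["samples"])
        for p in paths.get("cell_lines", [])
    ]
    cohorts = [
        io.read_cohort(p["expr"], p["clinical"], name=p.get("name", f"cohort{i}"))
        for i, p in enumerate(paths.get("cohorts", []))
    ]
    return experiments, cohorts, None


def run_pipeline(config: PipelineConfig,
                 outdir: str | Path | None = None) -> RunReport:
    """Execute every stage in order and return the aggregated report.

    When ``outdir`` is given, intermediate artifacts (DE tables, seed
    report, phenotype labels, signature model, classifications, survival
    tables) are written beneath it.
    """
    report = RunReport(seeds=dict(config.seeds))
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    stage = "inputs"
    try:
        experiments, cohorts, manifest = _load_inputs(config)
        if not experiments or not cohorts:
            raise ConfigurationError("need >= 1 cell line and >= 1 cohort")
        report.input_hashes = {
            **{f"cell_line_{i}": _hash_frame(e.counts)
               for i, e in enumerate(experiments)},
            **{c.name: _hash_frame(c.expr) for c in cohorts},
        }

        # ---- per-line differential expression -----------------------------
        stage = "de_counts"
        de_results = {}
        for i, exp in enumerate(experiments):
            line = exp.sample_sheet["cell_line"].iloc[0]
            res = de_counts.NBDifferentialExpression(exp).fit(
                q=config.q, fc_gate=config.fc_gate_log2)
            de_results[line] = res
            if out is not None:
                res.frame.to_csv(out / f"de_{line}.tsv", sep="\t")
        report.stages["de_counts"] = {
            line: {"n_up": len(r.up_genes), "n_down": len(r.down_genes)}
            for line, r in de_results.items()
        }

        # ---- seed selection ----------------------------------------------
        stage = "seeds"
        cohort_universe = set(cohorts[0].gene_ids)
        for c in cohorts[1:]:
            cohort_universe &= set(c.gene_ids)
        seed_report = seeds.consistency_counts(
            de_results, cohort_universe=cohort_universe)
        n_lines = seed_report.n_cell_lines
        up_sizes = [len(de_results[l].up_genes) for l in de_results]
        if all(sz > 0 for sz in up_sizes):
            mc_mean, mc_sd = seeds.mc_overlap_null(
                universe_size=len(seed_report.counts), set_sizes=up_sizes,
                k_threshold=min(3, n_lines), n_reps=config.mc_null_reps,
                seed=config.seeds["mc_null"])
            seed_report.null_summary = {
                "k_threshold": min(3, n_lines),
                "mean_overlap": mc_mean, "sd_overlap": mc_sd,
                "n_reps": config.mc_null_reps,
                "exact_expected": seeds.exact_overlap_null(
                    len(seed_report.counts), up_sizes, min(3, n_lines)),
            }
        if out is not None:
            seed_report.to_json(out / "seed_report.json")
        report.stages["seeds"] = {
            "consistency": {
                f">={m}": int(len(seed_report.lines_up_at_least(m)))
                for m in range(n_lines, max(n_lines - 4, 0), -1)
            },
            "n_seed_genes": len(seed_report.seed_set),
            "null_summary": seed_report.null_summary,
        }
        if not seed_report.seed_set:
            raise ConfigurationError("no seed genes survived the filters")

        # ---- phenotype clustering on the training cohort -------------------
        stage = "cluster"
        train = cohorts[0]
        seed_expr = log2_median_center(train.expr.loc[seed_report.seed_set])
        assignment = cluster_phenotypes(
            seed_expr, n_restarts=config.n_restarts,
            seed=config.seeds["cluster"])
        labels = assignment.labels
        if out is not None:
            assignment.write_csv(out / "phenotype_training.csv")
        report.stages["cluster"] = {
            "sizes": labels.value_counts().to_dict(),
            "inertia": assignment.cluster_inertia,
            "n_restarts": assignment.n_restarts_used,
        }

        # ---- in-vivo DE between clusters + enrichment ----------------------
        stage = "de_linear"
        mt = de_linear.ModeratedT(train.expr, labels).fit(
            q=config.q, fc_gate=config.invivo_fc_gate)
        cluster_up = set(mt.up_genes)
        tiers = {
            f"up_in_{m}_lines": set(seed_report.lines_up_exactly(m))
            for m in range(n_lines - 1, max(n_lines - 4, 0), -1)
        }
        enrich = seeds.enrichment_fraction(
            tiers, cluster_up, set(train.gene_ids))
        if out is not None:
            mt.frame.to_csv(out / "de_clusters.tsv", sep="\t")
        report.stages["de_linear"] = {
            "n_cluster_up": len(cluster_up),
            "seed_up_fraction": float(np.mean(
                [g in cluster_up for g in seed_report.seed_set])),
            "enrichment": enrich,
            "eb_prior_df": mt.d0,
        }

        # ---- signature derivation -----------------------------------------
        stage = "signature"
        model = pam.ShrunkenCentroid(seed_expr, labels)
        sig = model.fit(delta=None, threshold_grid_size=config.grid_size,
                        n_folds=config.n_folds, seed=config.seeds["cv"])
        if out is not None:
            sig.to_json(out / "signature_model.json")
        report.stages["signature"] = {
            "n_candidates": len(sig.gene_ids),
            "n_signature_genes": len(sig.selected_genes),
            "signature_genes": list(sig.selected_genes),
            "delta": sig.delta,
            "cv_accuracy": sig.cv_report.chosen_accuracy,
            "cv_errors": sig.cv_report.chosen_errors,
        }

        # ---- classify every cohort ----------------------------------------
        stage = "classify"
        classifications: dict[str, pd.DataFrame] = {}
        for c in cohorts:
            centered = log2_median_center(c.expr.loc[sig.gene_ids])
            pred = sig.classify(centered)
            classifications[c.name] = pred
            if out is not None:
                pred.to_csv(out / f"classification_{c.name}.csv")
        report.stages["classify"] = {
            name: {
                "n_high": int((p["label"] == "high").sum()),
                "n_low": int((p["label"] == "low").sum()),
                "fraction_high": float((p["label"] == "high").mean()),
            }
            for name, p in classifications.items()
        }

        # ---- survival -----------------------------------------------------
        stage = "survival"
        surv_summary = {}
        for c in cohorts:
            rec = survival.censor_at(
                c.clinical.copy(), horizon=config.horizon_years)
            hyp = classifications[c.name]["label"].rename("hypoxia")
            rec["hypoxia"] = hyp
            if rec["hypoxia"].nunique() < 2:
                surv_summary[c.name] = {"error": "single predicted class"}
                continue
            chi2, df_lr, p_lr = survival.logrank_test(rec, rec["hypoxia"])
            uni = survival.CoxModel(
                rec, ["hypoxia"], reference_levels={"hypoxia": "low"}).fit()
            multi = survival.CoxModel(
                rec, ["hypoxia"] + config.covariates,
                reference_levels={"hypoxia": "low", **config.reference_levels},
            ).fit()
            entry = {
                "logrank": {"chi2": chi2, "df": df_lr, "p": p_lr},
                "univariable": uni.frame.reset_index()
                    .rename(columns={"index": "term"}).to_dict("records"),
                "multivariable": multi.frame.reset_index()
                    .rename(columns={"index": "term"}).to_dict("records"),
            }
            if "second_signature" in rec.columns:
                comb = survival.combine_signatures(
                    rec, rec["hypoxia"], rec["second_signature"])
                entry["combined"] = {
                    "stratum_sizes": comb.strata.value_counts().to_dict(),
                    "logrank_p": comb.logrank_p,
                    "cox": comb.cox.frame.reset_index()
                        .rename(columns={"index": "term"}).to_dict("records"),
                }
            surv_summary[c.name] = entry
        report.stages["survival"] = surv_summary

        # ---- associations --------------------------------------------------
        stage = "assoc"
        assoc_summary = {}
        for c in cohorts:
            hyp = classifications[c.name]["label"]
            clin = c.clinical
            entry = {}
            if "second_signature" in clin.columns:
                tab = pd.crosstab(hyp, clin.loc[hyp.index, "second_signature"])
                if tab.shape == (2, 2) and (tab.to_numpy() > 0).all():
                    ct = assoc.chi_square(tab)
                    entry["second_signature_chi2"] = {
                        "chi2": ct.chi2, "df": ct.df, "p": ct.p}
            if "age" in clin.columns and hyp.nunique() == 2:
                a = clin.loc[hyp.index[hyp == "high"], "age"]
                b = clin.loc[hyp.index[hyp == "low"], "age"]
                t, df_w, p_w = assoc.welch_t(a, b)
                entry["age_welch_t"] = {"t": t, "df": df_w, "p": p_w}
            assoc_summary[c.name] = entry
        report.stages["assoc"] = assoc_summary

    except Exception as exc:
        logger.error("pipeline failed at stage %r: %s", stage, exc)
        report.stages.setdefault("error", {})
        report.stages["error"] = {"stage": stage, "message": str(exc)}
        if out is not None:
            report.to_json(out / "run_report.json")
        raise

    if out is not None:
        report.to_json(out / "run_report.json")
    return report
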