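"""Synthetic cell-line experiments and tumor cohorts with planted ground truth.

The generator emulates the data structure of a hypoxia-signature study:

* paired hypoxia/normoxia RNA-seq count experiments for several cell lines,
  with a *core* hypoxia program induced in every line and a *partial* program
  induced in random subsets of lines;
* tumor cohorts on a continuous log2 expression scale carrying a latent
  high/low-hypoxia phenotype (minority prevalence) that shifts the hypoxia
  program genes upward, plus per-cohort platform offsets and residual noise;
* survival times whose hazard depends multiplicatively on the latent
  phenotype (and optionally on a second binary signature label), with uniform
  plus administrative censoring;
* a ground-truth manifest recording every planted quantity so downstream
  stages can be scored.

Counts are negative binomial with the RNA-seq convention
``var = mu + alpha * mu**2``; the hypoxia effect enters as a log2 fold change
on the mean. Survival is exponential, so a proportional-hazards fit should
recover the planted hazard ratio.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .io import CohortDataset, CountExperiment


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with study-scale defaults.

    The defaults describe a desk-scale study: 2,000 genes, seven cell lines
    in triplicate, three tumor cohorts (training plus two validation) with a
    ~22% latent high-hypoxia prevalence and a planted hazard ratio of 2.5.
    """

    n_genes: int = 2000
    n_cell_lines: int = 7
    n_replicates: int = 3
    n_core_hypoxia_genes: int = 40
    n_partial_hypoxia_genes: int = 60
    #: planted log2 fold change range; lower bound >= 1 so core genes clear
    #: a two-fold gate in expectation. The default emulates canonical
    #: strongly induced hypoxia targets (6- to 32-fold)
    induction_log2fc_range: tuple[float, float] = (2.5, 5.0)
    #: per-gene baseline log2 mean count ~ Normal(loc, scale); centered on
    #: moderately expressed genes, as after routine low-count filtering
    baseline_logmean_distribution: tuple[float, float] = (6.0, 1.5)
    nb_dispersion_range: tuple[float, float] = (0.01, 0.1)
    library_size_factor_range: tuple[float, float] = (0.7, 1.4)

    cohort_sizes: tuple[int, ...] = (180, 130, 250)
    phenotype_prevalence: float = 0.22
    #: per-gene log2 shift of program genes in high-phenotype tumors: (mean, sd)
    tumor_effect_size: tuple[float, float] = (1.25, 0.25)
    cohort_shift_sd: float = 0.5
    noise_sd: float = 1.0
    #: include down-regulated programs (off: induced genes only)
    include_downregulation: bool = False

    true_hr: float = 2.5
    #: hazard ratio attached to the second signature label; 1.0 keeps the
    #: marginal phenotype hazard ratio equal to ``true_hr``
    second_hr: float = 1.0
    baseline_hazard: float = 0.10
    censoring_window: tuple[float, float] = (2.0, 12.0)
    administrative_cutoff: float = 10.0
    #: P(second label high | phenotype low), P(second label high | phenotype high)
    second_signature_probs: tuple[float, float] = (0.48, 0.76)

    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("n_genes", "n_cell_lines", "n_replicates"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        for name in ("n_core_hypoxia_genes", "n_partial_hypoxia_genes"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.n_core_hypoxia_genes + self.n_partial_hypoxia_genes > self.n_genes:
            raise ConfigurationError("planted gene programs exceed n_genes")
        lo, hi = self.induction_log2fc_range
        if lo < 1:
            raise ConfigurationError(
                "induction_log2fc_range lower bound must be >= 1 (two-fold)"
            )
        if hi < lo:
            raise ConfigurationError("induction_log2fc_range must be ordered")
        if not (0 <= self.phenotype_prevalence <= 1):
            raise ConfigurationError("phenotype_prevalence must be in [0, 1]")
        for p in self.second_signature_probs:
            if not (0 <= p <= 1):
                raise ConfigurationError("second_signature_probs must be in [0, 1]")
        if self.true_hr <= 0:
            raise ConfigurationError("true_hr must be > 0")
        if self.second_hr <= 0:
            raise ConfigurationError("second_hr must be > 0")
        if self.baseline_hazard <= 0:
            raise ConfigurationError("baseline_hazard must be > 0")
        if min(self.cohort_sizes, default=1) <= 0:
            raise ConfigurationError("cohort_sizes must be positive")
        if self.administrative_cutoff <= 0:
            raise ConfigurationError("administrative_cutoff must be > 0")
        lo, hi = self.nb_dispersion_range
        if lo <= 0 or hi < lo:
            raise ConfigurationError("nb_dispersion_range must be positive and ordered")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown simulation fields: {sorted(unknown)}")
        d = {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}
        return cls(**d)


@dataclass
class GroundTruthManifest:
    """Planted truth: which genes carry the program and who is hypoxic."""

    core_gene_ids: list[str]
    #: partial-program gene -> cell-line indices where it is induced
    partial_gene_map: dict[str, list[int]]
    #: per-gene planted log2 induction (0 for non-program genes)
    induction_log2fc: dict[str, float]
    #: per-gene log2 shift applied in high-phenotype tumors
    tumor_shift: dict[str, float]
    #: cohort index -> sample -> {"high", "low"}
    tumor_phenotype: dict[int, dict[str, str]] = field(default_factory=dict)
    #: cohort index -> sample -> (true event time, censoring time)
    survival_truth: dict[int, dict[str, tuple[float, float]]] = field(default_factory=dict)

    @property
    def program_gene_ids(self) -> list[str]:
        return self.core_gene_ids + list(self.partial_gene_map)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)

    @classmethod
    def read(cls, path) -> "GroundTruthManifest":
        with open(path) as fh:
            d = json.load(fh)
        d["tumor_phenotype"] = {int(k): v for k, v in d["tumor_phenotype"].items()}
        d["survival_truth"] = {
            int(k): {s: tuple(v) for s, v in inner.items()}
            for k, inner in d["survival_truth"].items()
        }
        return cls(**d)


# ---------------------------------------------------------------------------
# planted parameters shared by every cell line and cohort


@dataclass
class _Plant:
    gene_ids: list[str]
    baseline_log2_mean: np.ndarray        # per gene, log2 scale
    dispersion: np.ndarray                # per gene NB alpha
    beta: np.ndarray                      # genes x lines planted log2 induction
    core_idx: np.ndarray
    partial_idx: np.ndarray
    partial_lines: dict[int, np.ndarray]  # gene index -> induced line indices
    tumor_shift: np.ndarray               # per gene log2 shift in high tumors
    cohort_offsets: np.ndarray            # cohorts x genes platform offsets


def _plant_rng(config: SimulationConfig) -> np.random.Generator:
    return np.random.default_rng([config.rng_seed, 7919])


def plant_truth(config: SimulationConfig) -> _Plant:
    """Draw every gene-level planted parameter, deterministically from the
    config seed. Both the cell-line and the cohort simulators consume this."""
    rng = _plant_rng(config)
    g, l = config.n_genes, config.n_cell_lines
    gene_ids = [f"G{i:05d}" for i in range(g)]
    loc, scale = config.baseline_logmean_distribution
    baseline = rng.normal(loc, scale, size=g)
    lo, hi = config.nb_dispersion_range
    dispersion = rng.uniform(lo, hi, size=g)

    n_core, n_part = config.n_core_hypoxia_genes, config.n_partial_hypoxia_genes
    program = rng.choice(g, size=n_core + n_part, replace=False)
    core_idx = np.sort(program[:n_core])
    partial_idx = np.sort(program[n_core:])

    flo, fhi = config.induction_log2fc_range
    beta = np.zeros((g, l))
    sign = 1.0
    beta[core_idx, :] = sign * rng.uniform(flo, fhi, size=(n_core, 1))
    partial_lines: dict[int, np.ndarray] = {}
    for gi in partial_idx:
        if l == 1:
            lines = np.array([0])
        else:
            k = int(rng.integers(1, l))  # induced in 1 .. l-1 lines
            lines = np.sort(rng.choice(l, size=k, replace=False))
        partial_lines[int(gi)] = lines
        beta[gi, lines] = rng.uniform(flo, fhi)
    if config.include_downregulation:
        # mirror a smaller suppressed program by flipping signs of a random
        # quarter of the partial genes
        flip = rng.random(len(partial_idx)) < 0.25
        beta[partial_idx[flip], :] *= -1.0

    mean_shift, sd_shift = config.tumor_effect_size
    tumor_shift = np.zeros(g)
    prog_idx = np.concatenate([core_idx, partial_idx]).astype(int)
    tumor_shift[prog_idx] = rng.normal(mean_shift, sd_shift, size=len(prog_idx))

    offsets = rng.normal(0.0, config.cohort_shift_sd,
                         size=(len(config.cohort_sizes), g))
    if len(config.cohort_sizes) > 0:
        offsets[0, :] = 0.0  # training cohort defines the reference platform

    return _Plant(
        gene_ids=gene_ids,
        baseline_log2_mean=baseline,
        dispersion=dispersion,
        beta=beta,
        core_idx=core_idx,
        partial_idx=partial_idx,
        partial_lines=partial_lines,
        tumor_shift=tumor_shift,
        cohort_offsets=offsets,
    )


def make_manifest(config: SimulationConfig) -> GroundTruthManifest:
    """Manifest skeleton from the planted parameters (cohort entries are
    filled in by :func:`simulate_cohort` / :func:`simulate_study`)."""
    plant = plant_truth(config)
    ids = plant.gene_ids
    core = [ids[i] for i in plant.core_idx]
    partial = {ids[i]: [int(x) for x in lines]
               for i, lines in plant.partial_lines.items()}
    induction = {ids[i]: float(np.max(np.abs(plant.beta[i])))
                 for i in np.concatenate([plant.core_idx, plant.partial_idx]).astype(int)}
    shift = {ids[i]: float(plant.tumor_shift[i])
             for i in np.flatnonzero(plant.tumor_shift)}
    return GroundTruthManifest(
        core_gene_ids=core,
        partial_gene_map=partial,
        induction_log2fc=induction,
        tumor_shift=shift,
    )


# ---------------------------------------------------------------------------
# cell-line experiments


def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             alpha: np.ndarray) -> np.ndarray:
    """NB draws with var = mu + alpha mu^2 (gamma-Poisson mixture)."""
    shape = 1.0 / alpha
    lam = rng.gamma(shape, mean * alpha)
    return rng.poisson(lam)


def simulate_cell_line_experiment(config: SimulationConfig,
                                  line_index: int) -> CountExperiment:
    """Paired hypoxia/normoxia counts for one cell line.

    Counts are NB with mean ``s_j * mu_i * 2**(beta_i * I[hypoxia])`` where
    ``beta_i`` is the planted induction of gene ``i`` in this line and
    ``s_j`` a per-sample library-size factor. Deterministic under
    ``config.rng_seed`` and ``line_index``.
    """
    if not (0 <= line_index < config.n_cell_lines):
        raise ConfigurationError(
            f"line_index {line_index} out of range for n_cell_lines={config.n_cell_lines}"
        )
    plant = plant_truth(config)
    rng = np.random.default_rng([config.rng_seed, 104729, line_index])
    n_rep = config.n_replicates
    n_samples = 2 * n_rep
    lo, hi = config.library_size_factor_range
    size_factors = rng.uniform(lo, hi, size=n_samples)

    mu0 = 2.0 ** plant.baseline_log2_mean
    beta = plant.beta[:, line_index]
    hyp = np.array([0] * n_rep + [1] * n_rep)  # normoxia first, then hypoxia
    mean = size_factors[None, :] * mu0[:, None] * 2.0 ** (beta[:, None] * hyp[None, :])
    counts = _nb_draw(rng, mean, plant.dispersion[:, None])

    line = f"line{line_index}"
    sample_ids = [f"{line}_{c}_{r+1}" for c, reps in
                  (("normoxia", range(n_rep)), ("hypoxia", range(n_rep)))
                  for r in reps]
    counts_df = pd.DataFrame(counts, index=plant.gene_ids, columns=sample_ids,
                             dtype=np.int64)
    sheet = pd.DataFrame(
        {
            "cell_line": line,
            "condition": ["normoxia"] * n_rep + ["hypoxia"] * n_rep,
            "replicate": list(range(1, n_rep + 1)) * 2,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return CountExperiment(counts=counts_df, sample_sheet=sheet)


# ---------------------------------------------------------------------------
# tumor cohorts


def simulate_cohort(config: SimulationConfig, cohort_index: int,
                    manifest: GroundTruthManifest | None = None) -> CohortDataset:
    """One tumor cohort with a latent phenotype and phenotype-linked survival.

    Expression (log2) = gene baseline + cohort platform offset + program
    shift in high-phenotype tumors + Gaussian noise. Survival time is the
    minimum of an exponential event time with hazard
    ``baseline_hazard * true_hr**I[high] * second_hr**I[second high]``, a
    uniform censoring draw and the administrative cutoff. The phenotype is
    recorded only in the manifest, never in the clinical table.
    """
    if not (0 <= cohort_index < len(config.cohort_sizes)):
        raise ConfigurationError(
            f"cohort_index {cohort_index} out of range for "
            f"cohort_sizes={config.cohort_sizes}"
        )
    plant = plant_truth(config)
    rng = np.random.default_rng([config.rng_seed, 224737, cohort_index])
    n = config.cohort_sizes[cohort_index]
    sample_ids = [f"C{cohort_index}_T{i:04d}" for i in range(n)]

    high = rng.random(n) < config.phenotype_prevalence
    expr = (
        plant.baseline_log2_mean[:, None]
        + plant.cohort_offsets[cohort_index][:, None]
        + np.outer(plant.tumor_shift, high.astype(float))
        + rng.normal(0.0, config.noise_sd, size=(config.n_genes, n))
    )

    p_low, p_high = config.second_signature_probs
    second = rng.random(n) < np.where(high, p_high, p_low)

    hazard = (config.baseline_hazard
              * config.true_hr ** high.astype(float)
              * config.second_hr ** second.astype(float))
    event_time = rng.exponential(1.0 / hazard)
    clo, chi = config.censoring_window
    censor_time = np.minimum(rng.uniform(clo, chi, size=n),
                             config.administrative_cutoff)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)

    age = np.clip(rng.normal(60.0, 12.0, size=n), 18, 95).round(1)
    gender = np.where(rng.random(n) < 0.5, "F", "M")

    expr_df = pd.DataFrame(expr, index=plant.gene_ids, columns=sample_ids)
    clinical = pd.DataFrame(
        {
            "time_years": time,
            "event": event,
            "age": age,
            "gender": gender,
            "second_signature": np.where(second, "high", "low"),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    if manifest is not None:
        manifest.tumor_phenotype[cohort_index] = {
            s: ("high" if h else "low") for s, h in zip(sample_ids, high)
        }
        manifest.survival_truth[cohort_index] = {
            s: (float(t), float(c))
            for s, t, c in zip(sample_ids, event_time, censor_time)
        }
    return CohortDataset(expr=expr_df, clinical=clinical,
                         name=f"cohort{cohort_index}")


def simulate_study(config: SimulationConfig
                   ) -> tuple[list[CountExperiment], list[CohortDataset],
                              GroundTruthManifest]:
    """All cell-line experiments, all cohorts and the filled-in manifest."""
    manifest = make_manifest(config)
    experiments = [simulate_cell_line_experiment(config, i)
                   for i in range(config.n_cell_lines)]
    cohorts = [simulate_cohort(config, i, manifest)
               for i in range(len(config.cohort_sizes))]
    return experiments, cohorts, manifest
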