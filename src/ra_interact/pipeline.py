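"""End-to-end orchestration: simulate -> prep -> FAMD -> GA -> fit -> report.

Stages are pure functions over explicit inputs; :func:`run_pipeline` chains
them, writes every intermediate artifact (CSV/TSV/JSON with content hashes)
to the output directory, and enforces holdout discipline: the test split is
touched exactly once, by the final evaluation, and the access log proving it
is part of the report.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import prep, synthetic
from .bayes import BayesianLogit, HMCResults
from .famd import FAMD, FAMDResults
from .ga import FitnessEvaluator, GAConfig, GATrace, run_ga
from .recon import binary_effect, rank_variables, reconstruct
from .roc import auc_ci

__all__ = ["RunConfig", "RunReport", "run_pipeline"]


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    outdir: str
    seed: int = 0
    # input: either a cohort CSV or synthetic generation settings
    cohort_csv: str | None = None
    n: int = 4000
    schema: synthetic.CohortSchema = field(default_factory=synthetic.default_schema)
    truth: synthetic.GroundTruth = field(default_factory=synthetic.default_truth)
    fractions: tuple[float, float, float] = (0.5, 0.25, 0.25)
    famd_threshold: float = 1.0
    ga: GAConfig = field(default_factory=lambda: GAConfig.desk_scale())
    fitness_mode: str = "mle"
    chains: int = 8
    draws: int = 400
    warmup: int = 1000
    max_leapfrog: int = 24
    bootstrap_replicates: int = 10_000

    def __post_init__(self) -> None:
        if not self.outdir:
            raise ConfigError("an output directory is required")
        if self.cohort_csv is not None and not Path(self.cohort_csv).exists():
            raise ConfigError(f"cohort CSV {self.cohort_csv} does not exist")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        if "ga" in doc:
            doc["ga"] = GAConfig(**doc["ga"])
        if "fractions" in doc:
            doc["fractions"] = tuple(doc["fractions"])
        return cls(**doc)


@dataclass
class RunReport:
    n_total: int
    n_splits: tuple[int, int, int]
    n_first_order: int
    n_interactions: int
    n_columns: int
    n_dropped: int
    n_components: int
    n_retained: int
    retained_variance_share: float
    best_genome: np.ndarray
    n_selected: int
    validation_auc: tuple[float, float, float]
    test_auc: tuple[float, float, float]
    max_rhat: float
    summaries: pd.DataFrame
    trace: GATrace
    cache_hits: int
    test_access_log: list[str]
    posterior: HMCResults | None = None

    def summary(self) -> str:
        v, vl, vu = self.validation_auc
        t, tl, tu = self.test_auc
        lines = [
            f"cohort: {self.n_total} rows -> splits {self.n_splits}",
            f"variables: {self.n_first_order} first-order + {self.n_interactions} "
            f"interacted = {self.n_columns}",
            f"FAMD: {self.n_retained}/{self.n_components} components retained "
            f"({100 * self.retained_variance_share:.1f}% of variance)",
            f"GA: selected {self.n_selected}/{len(self.best_genome)} synthetic variables",
            f"validation smoothed AUC {v:.3f} (95% CI {vl:.3f}-{vu:.3f})",
            f"test smoothed AUC {t:.3f} (95% CI {tl:.3f}-{tu:.3f})",
            f"max R-hat {self.max_rhat:.4f}; fitness cache hits {self.cache_hits}",
            f"test split read by: {self.test_access_log}",
        ]
        return "\n".join(lines)


def _write(path: Path, writer, manifest: dict) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    writer(path)
    manifest[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seeds(seed: int) -> dict[str, int]:
    names = ["simulate", "split", "ga", "hmc", "boot_val", "boot_test"]
    state = np.random.SeedSequence(seed).generate_state(len(names))
    return {nm: int(s & 0x7FFFFFFF) for nm, s in zip(names, state)}


def run_pipeline(config: RunConfig) -> RunReport:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    seeds = _stage_seeds(config.seed)
    test_access: list[str] = []

    # -- stage: cohort -------------------------------------------------------
    if config.cohort_csv is not None:
        cohort = synthetic.Cohort.from_csv(config.cohort_csv)
    else:
        cohort = synthetic.generate_cohort(
            config.schema, config.truth, config.n, seed=seeds["simulate"]
        )
    _write(outdir / "cohort.csv", cohort.to_csv, manifest)
    (outdir / "cohort_meta.json").write_text(
        json.dumps({"seed": seeds["simulate"], "n": cohort.n})
    )

    # -- stage: split --------------------------------------------------------
    train, val, test = synthetic.split_cohort(cohort, config.fractions, seeds["split"])
    split_sizes = (train.n, val.n, test.n)

    # -- stage: prep ---------------------------------------------------------
    specs = prep.default_variable_specs()
    terms = prep.expand_interactions(specs)
    stacked = synthetic.Cohort(
        pd.concat([c.frame for c in (train, val, test)], ignore_index=True),
        outcome_name=cohort.outcome_name,
    )
    design = prep.build_design(stacked, specs, terms)
    train_idx = np.arange(train.n)
    design, dropped = prep.drop_degenerate(design, train_idx)
    design = prep.standardize(design, train_idx)
    y = stacked.frame[cohort.outcome_name].to_numpy(dtype=int)
    val_idx = np.arange(train.n, train.n + val.n)
    test_idx = np.arange(train.n + val.n, cohort.n)
    _write(outdir / "design_columns.tsv",
           lambda p: pd.Series(design.column_names).to_csv(p, sep="\t", index=False),
           manifest)

    # -- stage: FAMD ---------------------------------------------------------
    quant_names = [t.name for t, q in zip(design.terms, design.quantitative) if q]
    qual_names = [t.name for t, q in zip(design.terms, design.quantitative) if not q]
    tr_vals = design.values.iloc[train_idx]
    famd_res = FAMD(
        quantitative=tr_vals[quant_names], qualitative=tr_vals[qual_names]
    ).fit().retain(config.famd_threshold)
    famd_res.save(outdir / "famd")
    train_scores = famd_res.training_scores().to_numpy()
    val_scores = famd_res.project(design.values.iloc[val_idx]).to_numpy()

    # -- stage: GA selection -------------------------------------------------
    ga_config = GAConfig(**{**config.ga.__dict__, "seed": seeds["ga"]})
    evaluator = FitnessEvaluator(
        train_scores, y[train_idx], val_scores, y[val_idx], mode=config.fitness_mode
    )
    best, trace = run_ga(ga_config, evaluator, genome_length=famd_res.n_retained)
    _write(outdir / "ga_trace.tsv",
           lambda p: trace.to_frame().to_csv(p, sep="\t", index=False), manifest)
    (outdir / "best_subset.json").write_text(json.dumps(best.astype(int).tolist()))

    # -- stage: final Bayesian fit ------------------------------------------
    sel = np.flatnonzero(best)
    model = BayesianLogit(
        y[train_idx],
        train_scores[:, sel],
        exog_names=[f"sv{j + 1}" for j in sel],
    )
    posterior = model.fit(
        chains=config.chains,
        draws=config.draws,
        warmup=config.warmup,
        max_leapfrog=config.max_leapfrog,
        seed=seeds["hmc"],
    )
    _write(outdir / "posterior.csv", posterior.to_csv, manifest)

    # -- stage: evaluation ---------------------------------------------------
    val_probs = posterior.predict_prob(val_scores[:, sel])
    validation_auc = auc_ci(
        val_probs, y[val_idx], replicates=config.bootstrap_replicates,
        seed=seeds["boot_val"],
    )
    test_access.append("final_evaluation")
    test_scores = famd_res.project(design.values.iloc[test_idx]).to_numpy()
    test_probs = posterior.predict_prob(test_scores[:, sel])
    test_auc = auc_ci(
        test_probs, y[test_idx], replicates=config.bootstrap_replicates,
        seed=seeds["boot_test"],
    )

    # -- stage: reconstruction & ranking ------------------------------------
    recon = reconstruct(posterior.draws[:, 1:], famd_res, selected=best,
                        intercept=posterior.draws[:, 0])
    effect_draws = reconstructed_effect_draws(recon, design, train_idx)
    summaries = rank_variables(effect_draws)
    _write(outdir / "ranked_effects.tsv",
           lambda p: summaries.to_csv(p, sep="\t", index=False), manifest)

    report = RunReport(
        n_total=cohort.n,
        n_splits=split_sizes,
        n_first_order=len(specs),
        n_interactions=len(terms),
        n_columns=len(design.terms),
        n_dropped=len(dropped),
        n_components=len(famd_res.eigenvalues),
        n_retained=famd_res.n_retained,
        retained_variance_share=famd_res.retained_variance_share,
        best_genome=best,
        n_selected=int(best.sum()),
        validation_auc=validation_auc,
        test_auc=test_auc,
        max_rhat=float(posterior.rhat.max()),
        summaries=summaries,
        trace=trace,
        cache_hits=trace.cache_hits,
        test_access_log=test_access,
        posterior=posterior,
    )
    (outdir / "report.json").write_text(
        json.dumps(
            {
                "n_total": report.n_total,
                "n_splits": list(report.n_splits),
                "n_columns": report.n_columns,
                "n_dropped_degenerate": len(dropped),
                "dropped_columns": dropped,
                "n_retained": report.n_retained,
                "retained_variance_share": report.retained_variance_share,
                "n_selected": report.n_selected,
                "validation_auc": list(report.validation_auc),
                "test_auc": list(report.test_auc),
                "max_rhat": report.max_rhat,
                "test_access_log": report.test_access_log,
            },
            indent=2,
        )
    )
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return report


def reconstructed_effect_draws(
    recon, design: prep.DesignMatrix, train_idx: np.ndarray
) -> pd.DataFrame:
    """Per-SD log-odds effect draws for every design term.

    Quantitative columns are standardized so their reconstructed coefficient
    is already per SD; pure-binary columns get the de-weighted indicator
    difference scaled by the column's training-sample sd.
    """
    out = {}
    tr = design.values.iloc[train_idx]
    for term, is_quant in zip(design.terms, design.quantitative):
        name = term.name
        if is_quant:
            out[name] = recon.column(name)
        else:
            sd = tr[name].to_numpy(dtype=float).std(ddof=0)
            out[name] = binary_effect(recon, f"{name}=1", f"{name}=0") * sd
    return pd.DataFrame(out)
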