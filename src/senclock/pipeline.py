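"""End-to-end orchestration: simulate -> select -> train -> evaluate.

A :class:`RunConfig` (YAML-serializable) fixes every threshold and seed; a
run writes datasets, the selection ledger, the three clock models, the
evaluation report, a log, and a verbatim copy of its config into the
output directory. Identical configs produce identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .evaluation import (
    EvaluationReport,
    age_correlation,
    clock_mortality_hr,
    effect_concordance,
    evaluate_clocks_on_experiment,
    recovery_metrics,
    senolytic_change,
    senolytic_cpg_effects,
)
from .models import ClockModel, batch_harmonize, score, split_survival, train_clock
from .selection import SelectionParams, select_cpgs
from .simulate import (
    DATASET_SEED_INDEX,
    SimulationConfig,
    simulate_aging_cohort,
    simulate_immortalized_series,
    simulate_mortality_cohort,
    simulate_senescence_experiment,
    simulate_senolytic_trial,
)

logger = logging.getLogger("senclock")

CLOCK_NAMES = {
    "binomial": "SenCultureAge",
    "gaussian": "SenChronoAge",
    "cox": "SenMortalityAge",
}


@dataclass(frozen=True)
class TrainingParams:
    alpha: float = 0.5
    n_folds: int = 10
    lambda_rule: str = "min"
    n_lambdas: int = 25

    def validate(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("elastic-net alpha must lie in [0, 1]")
        if self.n_folds < 2:
            raise ValueError("need at least 2 CV folds")
        if self.lambda_rule not in ("min", "1se"):
            raise ValueError("lambda_rule must be 'min' or '1se'")


@dataclass(frozen=True)
class EvaluationParams:
    reversal_fraction: float = 0.0
    clearance_model: str = "none"
    n_trials: int = 1
    test_fraction: float = 0.3
    pooled_var: bool = False

    def validate(self) -> None:
        if not 0.0 <= self.reversal_fraction <= 1.0:
            raise ValueError("reversal_fraction must lie in [0, 1]")
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must lie in (0, 1)")


@dataclass
class RunConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    selection: SelectionParams = field(default_factory=SelectionParams)
    training: TrainingParams = field(default_factory=TrainingParams)
    evaluation: EvaluationParams = field(default_factory=EvaluationParams)
    output_dir: str = "senclock_run"
    write_datasets: bool = False
    log_level: str = "INFO"

    def validate(self) -> None:
        self.simulation.validate()
        self.training.validate()
        self.evaluation.validate()
        if not 0.0 < self.selection.alpha < 1.0:
            raise ValueError("selection alpha must lie in (0, 1)")
        if self.selection.min_significant not in (1, 2, 3):
            raise ValueError("min_significant must be 1, 2 or 3")

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        def plain(obj):
            if dataclasses.is_dataclass(obj):
                return {f.name: plain(getattr(obj, f.name))
                        for f in dataclasses.fields(obj)}
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            if isinstance(obj, (np.integer,)):
                return int(obj)
            if isinstance(obj, (np.floating,)):
                return float(obj)
            return obj

        return plain(self)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        def build(klass, data):
            names = {f.name for f in dataclasses.fields(klass)}
            unknown = set(data) - names
            if unknown:
                raise ValueError(
                    f"unknown keys {sorted(unknown)} for {klass.__name__}"
                )
            kwargs = dict(data)
            for key in ("age_range", "mortality_age_range"):
                if key in kwargs and isinstance(kwargs[key], list):
                    kwargs[key] = tuple(kwargs[key])
            return klass(**kwargs)

        cfg = cls(
            simulation=build(SimulationConfig, payload.get("simulation", {})),
            selection=build(SelectionParams, payload.get("selection", {})),
            training=build(TrainingParams, payload.get("training", {})),
            evaluation=build(EvaluationParams, payload.get("evaluation", {})),
            output_dir=payload.get("output_dir", "senclock_run"),
            write_datasets=bool(payload.get("write_datasets", False)),
            log_level=payload.get("log_level", "INFO"),
        )
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(payload, dict):
            raise ValueError(f"{path}: config must be a YAML mapping")
        return cls.from_dict(payload)


def run_pipeline(config: RunConfig) -> Dict:
    """Execute the full experiment; returns the summary dict (also written
    to <output_dir>/summary.json)."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(config.log_level)
    try:
        summary = _run(config, out)
    except Exception as exc:  # annotate the failing stage for the caller
        logger.error("pipeline failed: %s", exc)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
    (out / "summary.json").write_text(json.dumps(summary, indent=1, default=float))
    config.to_yaml(out / "config.yaml")
    return summary


def _run(config: RunConfig, out: Path) -> Dict:
    sim = config.simulation
    logger.info("simulating datasets (seed=%d, n_cpgs=%d)", sim.seed, sim.n_cpgs)
    senescence, truth = simulate_senescence_experiment(sim)
    immortalized, _ = simulate_immortalized_series(sim)
    aging, _ = simulate_aging_cohort(sim)
    mortality, _ = simulate_mortality_cohort(sim)
    mort_train, mort_test = split_survival(
        mortality, test_fraction=config.evaluation.test_fraction, seed=sim.seed
    )
    sen_test, _ = simulate_senescence_experiment(
        sim, group_sizes=sim.test_group_sizes,
        dataset_index=DATASET_SEED_INDEX["senescence_test"],
        dataset_id="senescence_test",
    )
    aging_test, _ = simulate_aging_cohort(
        sim, n=max(sim.aging_n // 2, 50),
        dataset_index=DATASET_SEED_INDEX["aging_test"],
        dataset_id="aging_test",
    )
    if config.write_datasets:
        data_dir = out / "datasets"
        data_dir.mkdir(exist_ok=True)
        for ds in (senescence, immortalized, aging, mortality, sen_test,
                   aging_test):
            mio.write_beta_matrix(ds, data_dir / f"{ds.dataset_id}_betas.tsv")
            mio.write_sample_sheet(ds.samples, data_dir / f"{ds.dataset_id}_samples.tsv")
        mio.write_truth_table(truth, data_dir / "truth.tsv")

    # --- selection ------------------------------------------------------
    logger.info("selecting CpGs (alpha=%g, min_significant=%d)",
                config.selection.alpha, config.selection.min_significant)
    ledger, tables = select_cpgs(senescence, immortalized, aging, mort_train,
                                 params=config.selection)
    for stage, count in ledger.counts.items():
        logger.info("ledger %-24s %6d", stage, count)
    mio.write_ledger(ledger, out / "selection")
    for name, table in tables.items():
        table.to_csv(out / "selection" / f"assoc_{name}.tsv", sep="\t")

    final = sorted(ledger.final)
    recovery = recovery_metrics(ledger.final, truth)
    logger.info("recovery: sensitivity=%.3f fdr=%s", recovery["sensitivity"],
                recovery["fdr"])
    if not final:
        raise RuntimeError("selection produced an empty final CpG set")

    # --- training -------------------------------------------------------
    tr = config.training
    logger.info("training clocks on %d CpGs", len(final))
    harmonized = batch_harmonize(senescence)
    clocks: Dict[str, ClockModel] = {}
    clocks["SenCultureAge"] = train_clock(
        harmonized, "senescence", final, name="SenCultureAge", alpha=tr.alpha,
        n_folds=tr.n_folds, seed=sim.seed, lambda_rule=tr.lambda_rule,
        n_lambdas=tr.n_lambdas,
    )
    clocks["SenChronoAge"] = train_clock(
        aging, "age", final, name="SenChronoAge", alpha=tr.alpha,
        n_folds=tr.n_folds, seed=sim.seed, lambda_rule=tr.lambda_rule,
        n_lambdas=tr.n_lambdas,
    )
    clocks["SenMortalityAge"] = train_clock(
        mort_train, "survival", final, name="SenMortalityAge", alpha=tr.alpha,
        n_folds=tr.n_folds, seed=sim.seed, lambda_rule=tr.lambda_rule,
        n_lambdas=tr.n_lambdas,
    )
    models_dir = out / "models"
    models_dir.mkdir(exist_ok=True)
    for name, model in clocks.items():
        mio.save_clock(model, models_dir / f"{name}.json")
        logger.info("clock %s: %d CpGs, lambda=%.5g", name, len(model.cpg_ids),
                    model.lambda_)

    # --- evaluation -----------------------------------------------------
    logger.info("evaluating clocks")
    report = EvaluationReport()
    report.group_differences = evaluate_clocks_on_experiment(
        clocks, sen_test, pooled_var=config.evaluation.pooled_var
    )
    age_rows, hr_rows = [], []
    for name, model in clocks.items():
        sc = score(model, aging_test)["score"]
        res = age_correlation(sc, aging_test.samples["age"])
        age_rows.append({"clock": name, **res})
        sc_m = score(model, mort_test)["score"]
        hr_rows.append({"clock": name,
                        **clock_mortality_hr(sc_m, mort_test.samples)})
    report.age_correlation = pd.DataFrame(age_rows)
    report.clock_hr = pd.DataFrame(hr_rows)

    ev = config.evaluation
    sol_rows = []
    concord_frames = []
    sen_effect = tables["senescence_replicative"]["scaled_mean_diff"].loc[final]
    for t_idx in range(ev.n_trials):
        trial = simulate_senolytic_trial(
            sim, reversal_fraction=ev.reversal_fraction,
            clearance_model=ev.clearance_model,
            dataset_index=DATASET_SEED_INDEX["senolytic_trial"] + 100 * t_idx,
            dataset_id=f"senolytic_trial_{t_idx}",
        )
        for name, model in clocks.items():
            sc = score(model, trial.dataset)["score"]
            res = senolytic_change(sc, trial.dataset.samples,
                                   pooled_var=ev.pooled_var)
            sol_rows.append({"trial": t_idx, "clock": name, **res})
        sol_eff = senolytic_cpg_effects(trial.dataset).loc[final]
        table, agreement = effect_concordance(sen_effect, sol_eff)
        table["trial"] = t_idx
        concord_frames.append(table)
        logger.info("trial %d sign agreement: %.3f", t_idx, agreement)
    report.senolytic_changes = pd.DataFrame(sol_rows)
    report.effect_concordance = pd.concat(concord_frames) if concord_frames \
        else pd.DataFrame()
    report.recovery = {k: v for k, v in recovery.items() if k != "flagged"}
    report.validate()
    report.save(out / "evaluation")

    summary = {
        "seed": sim.seed,
        "n_cpgs": sim.n_cpgs,
        "ledger_counts": dict(ledger.counts),
        "recovery": {k: (None if isinstance(v, float) and np.isnan(v) else v)
                     for k, v in recovery.items()},
        "clock_sizes": {k: len(v.cpg_ids) for k, v in clocks.items()},
        "age_correlation": {r["clock"]: r["r"] for r in age_rows},
        "mortality_hr": {r["clock"]: r["hr"] for r in hr_rows},
        "n_significant_clock_decreases": int(
            sum(r["significant_decrease"] for r in sol_rows)
        ),
    }
    return summary
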