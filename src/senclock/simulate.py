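"""Synthetic methylome generator with planted, fully known CpG structure.

The generator emulates the study designs a senescence-clock pipeline meets
in practice: in-vitro senescence experiments (control vs. replicative /
DNA-damage / oncogene-induced senescent cultures across several cell lines
and batches), an immortalized passaging series, an in-vivo aging cohort, a
mortality cohort with censored follow-up, and paired pre/post senolytic
trials. Every CpG belongs to exactly one planted class (see
:data:`senclock.datasets.CPG_CLASSES`) whose per-axis directions and effect
sizes are recorded in a :class:`TruthTable`, so selection and clock stages
can be scored against ground truth.

All effects are additive on the logit(beta) scale (the M-value convention):
beta values stay in (0, 1) and population-mixture arithmetic stays
tractable. The inverse logit is applied last.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Mapping, NamedTuple, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .datasets import (
    CPG_CLASSES,
    MethylationDataset,
    TruthTable,
    samples_to_frame,
    SampleInfo,
)

INDUCER_NAMES = ("replicative", "dna_damage", "oncogene")

# sub-seed registry: per-dataset seeds are config.seed + index so each
# dataset can be regenerated independently
DATASET_SEED_INDEX = {
    "senescence_experiment": 1,
    "immortalized_series": 2,
    "aging_cohort": 3,
    "mortality_cohort": 4,
    "senolytic_trial": 5,
    "senescence_test": 6,
    "aging_test": 7,
}


def _default_fractions() -> Dict[str, float]:
    # a designed test bed: most senescence-responsive CpGs are also
    # age/mortality-coupled; smaller decoupled/discordant/confounded classes
    return {
        "concordant_all": 0.04,
        "pan_senescence_hyper": 0.005,
        "pan_senescence_hypo": 0.005,
        "inducer_specific": 0.03,
        "replication_tracking": 0.05,
        "age_only": 0.05,
        "mortality_only": 0.03,
        "discordant": 0.03,
        "null": 0.76,
    }


def _default_effects() -> Dict[str, float]:
    return {
        "concordant_all": 1.0,
        "pan_senescence_hyper": 1.0,
        "pan_senescence_hypo": 1.0,
        "inducer_specific": 1.0,
        "replication_tracking": 1.0,
        "discordant": 1.0,
    }


def _default_group_sizes() -> Dict[str, Dict[str, Dict[str, int]]]:
    # training layout: one large fibroblast experiment with all three
    # inducers plus a three-cell-line experiment with two inducers
    return {
        "sen_train_1": {
            "fibroblast_1": {
                "control": 113,
                "replicative": 24,
                "dna_damage": 24,
                "oncogene": 24,
            }
        },
        "sen_train_2": {
            "dsf": {"control": 4, "replicative": 4, "dna_damage": 8},
            "msc_bm": {"control": 4, "replicative": 4, "dna_damage": 8},
            "msc_ad": {"control": 4, "replicative": 4, "dna_damage": 8},
        },
    }


def _default_test_group_sizes() -> Dict[str, Dict[str, Dict[str, int]]]:
    # held-out layout mirroring small independent validation series
    return {
        "sen_test_1": {"msc_1": {"control": 5, "replicative": 5, "dna_damage": 6}},
        "sen_test_2": {"fibroblast_2": {"control": 6, "replicative": 6, "oncogene": 3}},
        "sen_test_3": {"msc_2": {"control": 29, "dna_damage": 24}},
    }


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic methylome.

    Effect sizes are on the logit(beta) scale; ``age_slope`` and ``log_hr``
    are the planted standardized per-CpG associations (SD change in beta per
    SD of age; marginal log hazard ratio per SD of beta).
    """

    n_cpgs: int = 20_000
    cpg_class_fractions: Mapping[str, float] = field(default_factory=_default_fractions)
    effect_logit: Mapping[str, float] = field(default_factory=_default_effects)
    noise_sd_logit: float = 0.5
    baseline_beta_a: float = 2.0
    baseline_beta_b: float = 2.0
    group_sizes: Mapping[str, Mapping[str, Mapping[str, int]]] = field(
        default_factory=_default_group_sizes
    )
    test_group_sizes: Mapping[str, Mapping[str, Mapping[str, int]]] = field(
        default_factory=_default_test_group_sizes
    )
    cell_line_sd_logit: float = 0.1
    batch_shift_logit: float = 0.4
    n_passages: int = 20
    passage_replicates: int = 3
    passage_drift_logit: float = 0.08
    aging_n: int = 656
    age_range: Tuple[float, float] = (19.0, 101.0)
    age_slope: float = 0.3
    mortality_n: int = 2000
    mortality_age_range: Tuple[float, float] = (40.0, 90.0)
    censoring_rate: float = 0.30
    log_hr: float = 0.3
    latent_rho: float = 0.4
    age_cox_loghr: float = 0.5
    baseline_hazard: float = 0.02
    senolytic_n_pairs: int = 6
    pair_sd_logit: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        total = float(sum(self.cpg_class_fractions.values()))
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"class fractions sum to {total!r}, not 1")
        bad = set(self.cpg_class_fractions) - set(CPG_CLASSES)
        if bad:
            raise ValueError(f"unknown CpG classes {sorted(bad)}")
        if any(f < 0 for f in self.cpg_class_fractions.values()):
            raise ValueError("class fractions must be non-negative")
        for cls, eff in self.effect_logit.items():
            if not math.isfinite(eff):
                raise ValueError(f"non-finite effect size for class {cls!r}")
        if self.n_cpgs < 1:
            raise ValueError("n_cpgs must be positive")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ValueError("censoring_rate must lie in [0, 1)")
        if self.noise_sd_logit < 0:
            raise ValueError("noise SD must be non-negative")
        for layout in (self.group_sizes, self.test_group_sizes):
            for ds, lines in layout.items():
                for line, groups in lines.items():
                    for grp, n in groups.items():
                        if n < 2:
                            raise ValueError(
                                f"group size < 2 for {ds}/{line}/{grp}; "
                                "meta-analysis SEs undefined"
                            )

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=int(seed))


class SenolyticTrial(NamedTuple):
    dataset: MethylationDataset
    truth: TruthTable
    reversed_cpgs: list


# ---------------------------------------------------------------------------
# truth table (deterministic given the config, independent of the seed)
# ---------------------------------------------------------------------------

def class_counts(config: SimulationConfig) -> Dict[str, int]:
    """Largest-remainder apportionment so class frequencies match the
    configured fractions exactly for the configured n_cpgs."""
    config.validate()
    fracs = {c: config.cpg_class_fractions.get(c, 0.0) for c in CPG_CLASSES}
    raw = {c: f * config.n_cpgs for c, f in fracs.items()}
    counts = {c: int(math.floor(v)) for c, v in raw.items()}
    short = config.n_cpgs - sum(counts.values())
    remainders = sorted(
        CPG_CLASSES, key=lambda c: (raw[c] - counts[c], c), reverse=True
    )
    for c in remainders[:short]:
        counts[c] += 1
    return counts


def build_truth(config: SimulationConfig) -> TruthTable:
    counts = class_counts(config)
    n = config.n_cpgs
    cpg_ids = [f"cpg{i:07d}" for i in range(n)]
    cls = np.empty(n, dtype=object)
    pos = 0
    within = np.empty(n, dtype=int)
    for c in CPG_CLASSES:
        k = counts[c]
        cls[pos:pos + k] = c
        within[pos:pos + k] = np.arange(k)
        pos += k
    sign = np.where(within % 2 == 0, 1, -1)  # alternate hyper/hypo in class

    def dirs(s):
        return np.where(s > 0, "hyper", "hypo")

    table = pd.DataFrame(index=pd.Index(cpg_ids, name="cpg_id"))
    table["cpg_class"] = cls
    for col in ("sen_direction", "replicative_direction", "dna_damage_direction",
                "oncogene_direction", "age_direction", "mortality_direction"):
        table[col] = "none"
    table["age_slope"] = 0.0
    table["log_hr"] = 0.0

    is_cls = {c: cls == c for c in CPG_CLASSES}

    pan = is_cls["concordant_all"] | is_cls["pan_senescence_hyper"] | \
        is_cls["pan_senescence_hypo"] | is_cls["discordant"]
    sign = sign.copy()
    sign[is_cls["pan_senescence_hyper"]] = 1
    sign[is_cls["pan_senescence_hypo"]] = -1
    table.loc[pan, "sen_direction"] = dirs(sign[pan])
    for ind in INDUCER_NAMES:
        table.loc[pan, f"{ind}_direction"] = dirs(sign[pan])

    spec = is_cls["inducer_specific"]
    assigned = np.array([INDUCER_NAMES[i % 3] for i in within])
    for ind in INDUCER_NAMES:
        mask = spec & (assigned == ind)
        table.loc[mask, f"{ind}_direction"] = dirs(sign[mask])
    table.loc[spec, "sen_direction"] = dirs(sign[spec])

    rep = is_cls["replication_tracking"]
    table.loc[rep, "sen_direction"] = dirs(sign[rep])
    table.loc[rep, "replicative_direction"] = dirs(sign[rep])
    table.loc[rep, "oncogene_direction"] = dirs(sign[rep])

    aged = is_cls["concordant_all"] | is_cls["age_only"]
    table.loc[aged, "age_direction"] = dirs(sign[aged])
    table.loc[aged, "age_slope"] = sign[aged] * config.age_slope
    disc = is_cls["discordant"]
    table.loc[disc, "age_direction"] = dirs(-sign[disc])
    table.loc[disc, "age_slope"] = -sign[disc] * config.age_slope

    mort = is_cls["concordant_all"] | is_cls["mortality_only"]
    table.loc[mort, "mortality_direction"] = dirs(sign[mort])
    table.loc[mort, "log_hr"] = sign[mort] * config.log_hr
    table.loc[disc, "mortality_direction"] = dirs(-sign[disc])
    table.loc[disc, "log_hr"] = -sign[disc] * config.log_hr

    return TruthTable(table=table)


def _baseline_logit(config: SimulationConfig) -> np.ndarray:
    """Per-CpG baseline mean beta, shared by every dataset of a run."""
    rng = np.random.default_rng(config.seed)
    base = rng.beta(config.baseline_beta_a, config.baseline_beta_b, config.n_cpgs)
    return logit(np.clip(base, 0.05, 0.95))


def _direction_sign(series: pd.Series) -> np.ndarray:
    return np.where(series == "hyper", 1.0, np.where(series == "hypo", -1.0, 0.0))


def _senescence_effect_matrix(config: SimulationConfig, truth: TruthTable) -> pd.DataFrame:
    """Planted logit-scale shift per CpG per inducer."""
    mags = pd.Series(0.0, index=truth.table.index)
    for cls, eff in config.effect_logit.items():
        mags[truth.table["cpg_class"] == cls] = eff
    out = {}
    for ind in INDUCER_NAMES:
        out[ind] = mags.to_numpy() * _direction_sign(truth.table[f"{ind}_direction"])
    return pd.DataFrame(out, index=truth.table.index)


# ---------------------------------------------------------------------------
# in-vitro senescence experiment
# ---------------------------------------------------------------------------

def simulate_senescence_experiment(
    config: SimulationConfig,
    group_sizes: Optional[Mapping] = None,
    dataset_index: int = DATASET_SEED_INDEX["senescence_experiment"],
    dataset_id: str = "senescence_experiment",
) -> Tuple[MethylationDataset, TruthTable]:
    """Control vs. senescent cultures across cell lines, inducers, batches.

    Per-sample logit(beta) = baseline + batch shift + cell-line offset
    + planted condition effect + N(0, noise). The first batch in the layout
    is the reference (no shift).
    """
    config.validate()
    truth = build_truth(config)
    layout = group_sizes if group_sizes is not None else config.group_sizes
    for ds, lines in layout.items():
        for line, groups in lines.items():
            for grp, size in groups.items():
                if size < 2:
                    raise ValueError(f"group size < 2 for {ds}/{line}/{grp}")
    rng = np.random.default_rng(config.seed + dataset_index)
    mu = _baseline_logit(config)
    eff = _senescence_effect_matrix(config, truth)

    columns = []
    rows = []
    n = config.n_cpgs
    for b_idx, (ds, lines) in enumerate(layout.items()):
        shift = (
            np.zeros(n) if b_idx == 0
            else rng.normal(0.0, config.batch_shift_logit, n)
        )
        for line, groups in lines.items():
            cell_off = rng.normal(0.0, config.cell_line_sd_logit, n)
            base = mu + shift + cell_off
            for grp, size in groups.items():
                if grp == "control":
                    mean = base
                    condition, inducer = "control", "none"
                else:
                    if grp not in INDUCER_NAMES:
                        raise ValueError(f"unknown group {grp!r} in layout")
                    mean = base + eff[grp].to_numpy()
                    condition, inducer = "senescent", grp
                noise = rng.normal(0.0, config.noise_sd_logit, (n, size))
                columns.append(mean[:, None] + noise)
                for k in range(size):
                    rows.append(
                        SampleInfo(
                            sample_id=f"{ds}_{line}_{grp}_{k:03d}",
                            dataset_id=ds,
                            condition=condition,
                            inducer=inducer,
                            cell_line=line,
                        )
                    )
    betas = expit(np.concatenate(columns, axis=1))
    sheet = samples_to_frame(rows)
    frame = pd.DataFrame(betas, index=truth.table.index, columns=sheet.index)
    ds = MethylationDataset(betas=frame, samples=sheet, dataset_id=dataset_id)
    return ds, truth


# ---------------------------------------------------------------------------
# immortalized passaging series
# ---------------------------------------------------------------------------

def simulate_immortalized_series(
    config: SimulationConfig,
    dataset_index: int = DATASET_SEED_INDEX["immortalized_series"],
) -> Tuple[MethylationDataset, TruthTable]:
    """hTERT-style immortalized cultures sampled across passages.

    replication_tracking CpGs drift linearly with passage number on the
    logit scale (centered, so the series mean stays at baseline); all other
    classes are flat.
    """
    config.validate()
    if config.n_passages < 3:
        raise ValueError("need at least 3 passages for a correlation filter")
    truth = build_truth(config)
    rng = np.random.default_rng(config.seed + dataset_index)
    mu = _baseline_logit(config)
    drift = (
        config.passage_drift_logit
        * _direction_sign(truth.table["replicative_direction"])
        * (truth.table["cpg_class"] == "replication_tracking").to_numpy()
    )
    passages = np.repeat(np.arange(1, config.n_passages + 1),
                         config.passage_replicates)
    centered = passages - passages.mean()
    n = config.n_cpgs
    logits = mu[:, None] + drift[:, None] * centered[None, :]
    logits = logits + rng.normal(0.0, config.noise_sd_logit, logits.shape)
    rows = [
        SampleInfo(
            sample_id=f"immortal_p{p:02d}_{k}",
            dataset_id="immortalized_series",
            condition="immortalized",
            inducer="none",
            cell_line="immortalized_1",
            passage=float(p),
        )
        for k, p in enumerate(passages)
    ]
    sheet = samples_to_frame(rows)
    frame = pd.DataFrame(expit(logits), index=truth.table.index, columns=sheet.index)
    return MethylationDataset(frame, sheet, "immortalized_series"), truth


# ---------------------------------------------------------------------------
# in-vivo aging cohort
# ---------------------------------------------------------------------------

def simulate_aging_cohort(
    config: SimulationConfig,
    n: Optional[int] = None,
    dataset_index: int = DATASET_SEED_INDEX["aging_cohort"],
    dataset_id: str = "aging_cohort",
) -> Tuple[MethylationDataset, TruthTable]:
    """Whole-blood style cohort with uniform ages and planted standardized
    age slopes on age_only / concordant_all (and inverted on discordant)
    CpGs. No survival follow-up."""
    config.validate()
    n = int(n if n is not None else config.aging_n)
    lo, hi = config.age_range
    if not hi > lo:
        raise ValueError("degenerate age range")
    truth = build_truth(config)
    rng = np.random.default_rng(config.seed + dataset_index)
    mu = _baseline_logit(config)
    ages = rng.uniform(lo, hi, n)
    z_age = (ages - ages.mean()) / ages.std(ddof=1)
    rho = truth.table["age_slope"].to_numpy()
    # slope a on the logit scale giving standardized slope rho at noise sd
    with np.errstate(divide="ignore", invalid="ignore"):
        a = config.noise_sd_logit * rho / np.sqrt(1.0 - rho**2)
    logits = mu[:, None] + a[:, None] * z_age[None, :]
    logits = logits + rng.normal(0.0, config.noise_sd_logit, logits.shape)
    rows = [
        SampleInfo(
            sample_id=f"{dataset_id}_{k:04d}",
            dataset_id=dataset_id,
            condition="control",
            inducer="none",
            cell_line="whole_blood",
            age=float(age),
        )
        for k, age in enumerate(ages)
    ]
    sheet = samples_to_frame(rows)
    frame = pd.DataFrame(expit(logits), index=truth.table.index, columns=sheet.index)
    return MethylationDataset(frame, sheet, dataset_id), truth


# ---------------------------------------------------------------------------
# in-vivo mortality cohort
# ---------------------------------------------------------------------------

def simulate_mortality_cohort(
    config: SimulationConfig,
    n: Optional[int] = None,
    dataset_index: int = DATASET_SEED_INDEX["mortality_cohort"],
    dataset_id: str = "mortality_cohort",
) -> Tuple[MethylationDataset, TruthTable]:
    """Cohort with censored survival driven by a proportional-hazards model.

    Mortality-axis CpGs (concordant_all, mortality_only, and inverted
    discordant) share a latent per-subject senescence-burden factor, and the
    linear predictor is the sum of per-CpG coefficients times z-scored betas
    plus an age effect. Coefficients are scaled so the implied marginal
    standardized log HR of each mortality CpG equals ``config.log_hr``; with
    a single mortality CpG this reduces to a direct planted effect.
    """
    config.validate()
    n = int(n if n is not None else config.mortality_n)
    truth = build_truth(config)
    rng = np.random.default_rng(config.seed + dataset_index)
    mu = _baseline_logit(config)
    lo, hi = config.mortality_age_range
    if not hi > lo:
        raise ValueError("degenerate age range")
    ages = rng.uniform(lo, hi, n)
    z_age = (ages - ages.mean()) / ages.std(ddof=1)
    burden = rng.normal(0.0, 1.0, n)

    mort_sign = np.zeros(config.n_cpgs)
    tab = truth.table
    mort_mask = tab["mortality_direction"].isin(["hyper", "hypo"]).to_numpy()
    mort_sign[mort_mask] = _direction_sign(tab["mortality_direction"])[mort_mask]
    rho = config.latent_rho
    lam = config.noise_sd_logit * rho / math.sqrt(1.0 - rho**2)
    logits = mu[:, None] + (mort_sign * lam)[:, None] * burden[None, :]
    logits = logits + rng.normal(0.0, config.noise_sd_logit, logits.shape)
    betas = expit(logits)

    m = int(mort_mask.sum())
    lp = config.age_cox_loghr * z_age
    if m > 0:
        sub = betas[mort_mask]
        z = (sub - sub.mean(axis=1, keepdims=True)) / sub.std(axis=1, ddof=1,
                                                              keepdims=True)
        s = config.log_hr / (1.0 + rho**2 * (m - 1))
        lp = lp + (mort_sign[mort_mask] * s) @ z
    lp = lp - lp.mean()

    hazard = config.baseline_hazard * np.exp(lp)
    t_death = rng.exponential(1.0, n) / hazard
    rate = config.censoring_rate
    if rate == 0.0:
        time, event = t_death, np.ones(n, dtype=int)
    else:
        def mean_censored(log_rc):
            rc = math.exp(log_rc)
            return float(np.mean(rc / (rc + hazard))) - rate

        log_rc = brentq(mean_censored, -30.0, 30.0)
        t_cens = rng.exponential(1.0, n) * math.exp(-log_rc)
        event = (t_death <= t_cens).astype(int)
        time = np.minimum(t_death, t_cens)
    if event.sum() == 0:
        raise ValueError("censoring removed every event; lower censoring_rate")
    time = np.maximum(time, 1e-9)

    rows = [
        SampleInfo(
            sample_id=f"{dataset_id}_{k:04d}",
            dataset_id=dataset_id,
            condition="control",
            inducer="none",
            cell_line="whole_blood",
            age=float(ages[k]),
            survival_time=float(time[k]),
            event=int(event[k]),
        )
        for k in range(n)
    ]
    sheet = samples_to_frame(rows)
    frame = pd.DataFrame(betas, index=tab.index, columns=sheet.index)
    return MethylationDataset(frame, sheet, dataset_id), truth


# ---------------------------------------------------------------------------
# paired senolytic trial
# ---------------------------------------------------------------------------

def simulate_senolytic_trial(
    config: SimulationConfig,
    reversal_fraction: float = 0.0,
    clearance_model: str = "none",
    n_pairs: Optional[int] = None,
    pre_weight: float = 0.5,
    post_weight: float = 0.1,
    noise_sd: Optional[float] = None,
    dataset_index: int = DATASET_SEED_INDEX["senolytic_trial"],
    dataset_id: str = "senolytic_trial",
) -> SenolyticTrial:
    """Paired pre/post-treatment methylomes of senescent cultures.

    clearance_model:
      * ``none`` - post = pre state + fresh noise (no biological change);
      * ``subtract_effect`` - the planted pan-senescence effect is removed
        at post-treatment for a ``reversal_fraction`` of eligible CpGs;
      * ``remix_population`` - betas are a senescent/control population
        mixture whose senescent weight drops from ``pre_weight`` to
        ``post_weight`` (mixing is linear on the beta scale).
    """
    config.validate()
    if not 0.0 <= reversal_fraction <= 1.0:
        raise ValueError("reversal_fraction must lie in [0, 1]")
    if clearance_model not in ("none", "subtract_effect", "remix_population"):
        raise ValueError(f"unknown clearance model {clearance_model!r}")
    n_pairs = int(n_pairs if n_pairs is not None else config.senolytic_n_pairs)
    if n_pairs < 2:
        raise ValueError("need at least 2 pairs")
    sigma = config.noise_sd_logit if noise_sd is None else float(noise_sd)
    truth = build_truth(config)
    rng = np.random.default_rng(config.seed + dataset_index)
    mu = _baseline_logit(config)
    tab = truth.table
    eligible_mask = tab["cpg_class"].isin(
        ["concordant_all", "pan_senescence_hyper", "pan_senescence_hypo"]
    ).to_numpy()
    theta = np.zeros(config.n_cpgs)
    mags = pd.Series(0.0, index=tab.index)
    for cls, eff in config.effect_logit.items():
        mags[tab["cpg_class"] == cls] = eff
    theta[eligible_mask] = (
        mags.to_numpy()[eligible_mask]
        * _direction_sign(tab["sen_direction"])[eligible_mask]
    )

    eligible_idx = np.flatnonzero(eligible_mask)
    n_rev = int(round(reversal_fraction * eligible_idx.size))
    reversed_idx = rng.choice(eligible_idx, size=n_rev, replace=False) \
        if n_rev else np.array([], dtype=int)

    if clearance_model == "remix_population":
        sen_beta = expit(mu + theta)
        ctl_beta = expit(mu)
        pre_mean = logit(np.clip(pre_weight * sen_beta + (1 - pre_weight) * ctl_beta,
                                 1e-9, 1 - 1e-9))
        post_mean = logit(np.clip(post_weight * sen_beta + (1 - post_weight) * ctl_beta,
                                  1e-9, 1 - 1e-9))
    else:
        pre_mean = mu + theta
        post_mean = pre_mean.copy()
        if clearance_model == "subtract_effect":
            post_mean[reversed_idx] = mu[reversed_idx]

    columns, rows = [], []
    for p in range(n_pairs):
        pair_off = rng.normal(0.0, config.pair_sd_logit, config.n_cpgs)
        for phase, mean in (("pre", pre_mean), ("post", post_mean)):
            noise = rng.normal(0.0, sigma, config.n_cpgs)
            columns.append(mean + pair_off + noise)
            rows.append(
                SampleInfo(
                    sample_id=f"pair{p:03d}_{phase}",
                    dataset_id=dataset_id,
                    condition="senescent",
                    inducer="replicative",
                    cell_line="fibroblast_trial",
                    arm="senolytic",
                    timepoint=phase,
                    pair_id=f"pair{p:03d}",
                )
            )
    sheet = samples_to_frame(rows)
    frame = pd.DataFrame(expit(np.column_stack(columns)), index=tab.index,
                         columns=sheet.index)
    ds = MethylationDataset(frame, sheet, dataset_id)
    return SenolyticTrial(ds, truth, list(tab.index[reversed_idx]))
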