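"""Study orchestration: replicate virtual trials over a scenario grid.

A scenario is a (cohort size, Emax scale) pair.  Each replicate trial
simulates a cohort (PK parameters -> concentrations -> adverse-event
trajectories), derives the ER dataset for every imputation policy (plus
Cav,ss), applies the censoring-balance rule, and fits the logistic ER
model where allowed.  Results accumulate in a long-format table; summary
helpers produce per-scenario medians and a pivoted matrix with imputation
policies as columns.

Seeding: each trial's stream is derived from the content of
(master seed, n_subjects, Emax-scale token, replicate), never from grid
position, so running scenarios in any order or subset yields identical
rows.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ae import (
    AEModelParameters,
    DEFAULT_DRIVER,
    sample_individual_ae,
    simulate_cohort_histories,
)
from .er_fit import fit_logistic
from .metrics import (
    CAVSS_LABEL,
    DEFAULT_POLICIES,
    ERDataset,
    ImputationPolicy,
    build_er_dataset,
)
from .pk import DosingRegimen, PKParameters, sample_individual_pk

__all__ = [
    "ScenarioConfig",
    "ScenarioResultTable",
    "run_trial",
    "run_grid",
    "censoring_balance_check",
    "replicate_summary",
    "table2_matrix",
    "DEFAULT_SAMPLE_SIZES",
    "DEFAULT_EMAX_SCALES",
]

logger = logging.getLogger(__name__)

DEFAULT_SAMPLE_SIZES: tuple[int, ...] = (50, 100, 200)
DEFAULT_EMAX_SCALES: tuple[float, ...] = (0.25, 0.5, 0.75, 1.0, 1.25, 1.5)

_RESULT_COLUMNS = [
    "replicate",
    "n_subjects",
    "emax_scale",
    "metric",
    "beta0",
    "beta",
    "se_beta",
    "z",
    "p_slope",
    "p_slope_lr",
    "n_event",
    "n_censored",
    "frac_censored",
    "converged",
    "separation_detected",
    "skipped",
    "skip_reason",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """One scenario's configuration plus the shared model parameters.

    ``emax_scale`` multiplies both Emax parameters of the AE model and is
    the drug-effect magnitude axis of the study grid; ``n_subjects`` the
    cohort-size axis.  ``balance_threshold`` is the minimum fraction either
    outcome class must reach for the logistic regression to be attempted.
    """

    n_subjects: int = 200
    emax_scale: float = 1.0
    policies: tuple[ImputationPolicy, ...] = DEFAULT_POLICIES
    include_cavss: bool = True
    assessment_interval_days: float = 7.0
    n_replicates: int = 200
    balance_threshold: float = 0.05
    alpha: float = 0.05
    driver: str = DEFAULT_DRIVER
    seed: int = 0
    pk: PKParameters = field(default_factory=PKParameters)
    ae: AEModelParameters = field(default_factory=AEModelParameters)
    regimen: DosingRegimen = field(default_factory=DosingRegimen)

    def __post_init__(self) -> None:
        if self.n_subjects < 10:
            raise ValueError("need at least 10 subjects")
        if self.n_replicates < 1:
            raise ValueError("need at least 1 replicate")
        if not 0 < self.balance_threshold < 0.5:
            raise ValueError("balance threshold must be in (0, 0.5)")
        if not self.policies:
            raise ValueError("need at least one imputation policy")

    @property
    def assessment_interval_h(self) -> float:
        return 24.0 * self.assessment_interval_days


def censoring_balance_check(
    dataset: ERDataset, threshold: float = 0.05
) -> tuple[bool, float]:
    """Decide whether a logistic regression should be attempted.

    Returns ``(proceed, fraction_censored)``; ``proceed`` is False when
    the smaller outcome class is below ``threshold`` of the cohort (the
    stated rule covers too few censored subjects; the symmetric case of
    too few events is applied as well, since the fit is equally fragile).
    """
    n = len(dataset)
    if n < 1:
        raise ValueError("empty dataset")
    frac_cens = dataset.n_censored / n
    proceed = min(dataset.n_event, dataset.n_censored) / n >= threshold
    return proceed, frac_cens


def _trial_seedseq(config: ScenarioConfig, replicate: int) -> np.random.SeedSequence:
    """Content-derived entropy so grid order and subsetting never matter."""
    s_token = int(round(config.emax_scale * 1_000_000))
    return np.random.SeedSequence(
        entropy=(config.seed, config.n_subjects, s_token, replicate)
    )


def run_trial(config: ScenarioConfig, replicate_seed) -> list[dict]:
    """Simulate and analyse one virtual trial; one result row per metric.

    ``replicate_seed`` may be an integer or a SeedSequence; three child
    streams are spawned for PK sampling, AE sampling and the event
    trajectories.  Responder flags are shared across all CavTE policies
    (imputation touches only censored subjects' exposures).
    """
    if not isinstance(replicate_seed, np.random.SeedSequence):
        replicate_seed = np.random.SeedSequence(replicate_seed)
    pk_ss, ae_ss, traj_ss = replicate_seed.spawn(3)
    ae_params = dataclasses.replace(config.ae, emax_scale=config.emax_scale)
    cohort_pk = sample_individual_pk(config.pk, config.n_subjects, pk_ss)
    cohort_ae = sample_individual_ae(ae_params, config.n_subjects, ae_ss)
    histories = simulate_cohort_histories(
        cohort_pk,
        cohort_ae,
        config.regimen,
        assessment_interval=config.assessment_interval_h,
        seed=traj_ss,
        driver=config.driver,
    )
    datasets = [
        build_er_dataset(cohort_pk, histories, config.regimen, "cavte", policy)
        for policy in config.policies
    ]
    if config.include_cavss:
        datasets.append(build_er_dataset(cohort_pk, histories, config.regimen, "cavss"))

    rows = []
    for ds in datasets:
        proceed, frac_cens = censoring_balance_check(ds, config.balance_threshold)
        row = {
            "n_subjects": config.n_subjects,
            "emax_scale": config.emax_scale,
            "metric": ds.metric_name,
            "beta0": np.nan,
            "beta": np.nan,
            "se_beta": np.nan,
            "z": np.nan,
            "p_slope": np.nan,
            "p_slope_lr": np.nan,
            "n_event": ds.n_event,
            "n_censored": ds.n_censored,
            "frac_censored": frac_cens,
            "converged": False,
            "separation_detected": False,
            "skipped": not proceed,
            "skip_reason": "",
        }
        if not proceed:
            row["skip_reason"] = (
                "single-class" if min(ds.n_event, ds.n_censored) == 0 else "imbalance"
            )
            logger.info(
                "skip n=%d s=%.2f metric=%s reason=%s frac_censored=%.3f",
                config.n_subjects,
                config.emax_scale,
                ds.metric_name,
                row["skip_reason"],
                frac_cens,
            )
        else:
            fit = fit_logistic(ds)
            row.update(
                beta0=fit.beta0,
                beta=fit.beta,
                se_beta=fit.se_beta,
                z=fit.z,
                p_slope=fit.p_slope,
                p_slope_lr=fit.p_slope_lr,
                converged=fit.converged,
                separation_detected=fit.separation_detected,
            )
        rows.append(row)
    return rows


@dataclass
class ScenarioResultTable:
    """Long-format grid results: one row per replicate x scenario x metric."""

    data: pd.DataFrame

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def from_csv(cls, path) -> "ScenarioResultTable":
        return cls(pd.read_csv(path))

    def summary(self, alpha: float = 0.05) -> pd.DataFrame:
        return replicate_summary(self, alpha=alpha)

    def pivot(self, value: str = "median_p", alpha: float = 0.05) -> pd.DataFrame:
        return table2_matrix(self, value=value, alpha=alpha)


def run_grid(
    config: ScenarioConfig,
    sample_sizes: tuple[int, ...] = DEFAULT_SAMPLE_SIZES,
    emax_scales: tuple[float, ...] = DEFAULT_EMAX_SCALES,
) -> ScenarioResultTable:
    """Run the full study grid: sample sizes x Emax scales x replicates.

    Every other setting (policies, replicates, seed, model parameters) is
    taken from ``config``; its own ``n_subjects``/``emax_scale`` are
    ignored in favour of the grid axes.
    """
    if not sample_sizes or not emax_scales:
        raise ValueError("grid axes must be non-empty")
    rows = []
    for n in sample_sizes:
        for s in emax_scales:
            cell = dataclasses.replace(config, n_subjects=int(n), emax_scale=float(s))
            for r in range(config.n_replicates):
                for row in run_trial(cell, _trial_seedseq(cell, r)):
                    rows.append({"replicate": r, **row})
    return ScenarioResultTable(pd.DataFrame(rows, columns=_RESULT_COLUMNS))


def replicate_summary(table: ScenarioResultTable, alpha: float = 0.05) -> pd.DataFrame:
    """Per scenario x metric: median slope p, significant fraction, median
    censored fraction and skip rate across replicates.

    Medians are over non-skipped replicates; a fully skipped cell keeps
    NaN medians with skip rate 1.
    """
    df = table.data
    out = []
    for (n, s, metric), g in df.groupby(
        ["n_subjects", "emax_scale", "metric"], sort=True
    ):
        fitted = g[~g["skipped"]]
        out.append(
            {
                "n_subjects": n,
                "emax_scale": s,
                "metric": metric,
                "n_replicates": len(g),
                "median_p": fitted["p_slope"].median() if len(fitted) else np.nan,
                "frac_significant": (
                    float((fitted["p_slope"] < alpha).mean()) if len(fitted) else np.nan
                ),
                "median_frac_censored": g["frac_censored"].median(),
                "skip_rate": float(g["skipped"].mean()),
            }
        )
    return pd.DataFrame(out)


def table2_matrix(
    table: ScenarioResultTable, value: str = "median_p", alpha: float = 0.05
) -> pd.DataFrame:
    """Pivot CavTE results into a policy matrix: one row per
    (sample size, Emax scale), one column per imputation policy.

    ``value``: ``median_p`` (median slope p across replicates, NaN where
    skipped) or ``p`` (single-realization mode: requires one replicate).
    """
    df = table.data
    cavte = df[df["metric"] != CAVSS_LABEL].copy()
    label_to_name = {p.metric_label: p.name for p in DEFAULT_POLICIES}
    cavte["policy"] = cavte["metric"].map(lambda m: label_to_name.get(m, m))
    if value == "p":
        if cavte["replicate"].nunique() > 1:
            raise ValueError("value='p' requires a single replicate")
        piv = cavte.pivot(
            index=["n_subjects", "emax_scale"], columns="policy", values="p_slope"
        )
    elif value == "median_p":
        summ = cavte[~cavte["skipped"]].groupby(
            ["n_subjects", "emax_scale", "policy"]
        )["p_slope"].median()
        piv = summ.unstack("policy")
    else:
        raise ValueError(f"unknown value {value!r}")
    order = [p.name for p in DEFAULT_POLICIES if p.name in piv.columns]
    extra = [c for c in piv.columns if c not in order]
    return piv[order + extra]
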