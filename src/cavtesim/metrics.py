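"""Exposure metrics and analysis-ready exposure-response (ER) datasets.

CavTE — time-averaged concentration to event — is the cumulative AUC from
treatment start to a reference time divided by that time.  For responders
the reference time is the first-event time.  For censored subjects (no
event by end of treatment) it must be imputed; the supported policies are
EoT and EoT plus 7, 14, 21 or 28 days of follow-up.  Because dosing stops
at EoT, the AUC accrues only the washout tail after it, so longer imputed
follow-up strictly lowers a censored subject's CavTE (the "left shift" of
the censored exposure distribution).

Cav,ss — average steady-state concentration — is F*D/(CL*tau) and does not
depend on event times at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ae import EventHistory, first_event
from .pk import DosingRegimen, IndividualPK, cav_ss, cumulative_auc

__all__ = [
    "ImputationPolicy",
    "ERDataset",
    "DataIntegrityError",
    "DEFAULT_POLICIES",
    "CAVSS_LABEL",
    "cav_te",
    "imputed_reference_time",
    "build_er_dataset",
]

#: CSV schema shared by all ER datasets
ER_COLUMNS = ("subject_id", "metric", "exposure_ng_ml", "responder", "event_time_h")

CAVSS_LABEL = "CAVSS"


class DataIntegrityError(ValueError):
    """Raised when cohorts that must align by subject do not."""


@dataclass(frozen=True)
class ImputationPolicy:
    """Reference-time imputation for censored subjects: EoT plus a fixed
    number of follow-up days."""

    name: str
    extra_follow_up_days: int = 0

    def __post_init__(self) -> None:
        if self.extra_follow_up_days < 0 or self.extra_follow_up_days % 7:
            raise ValueError("extra follow-up must be a non-negative multiple of 7 days")

    @property
    def metric_label(self) -> str:
        d = self.extra_follow_up_days
        return f"CAVTE_EOT{d}" if d else "CAVTE_EOT"


DEFAULT_POLICIES: tuple[ImputationPolicy, ...] = (
    ImputationPolicy("EoT", 0),
    ImputationPolicy("EoT+7", 7),
    ImputationPolicy("EoT+14", 14),
    ImputationPolicy("EoT+21", 21),
    ImputationPolicy("EoT+28", 28),
)


def cav_te(ind_pk: IndividualPK, regimen: DosingRegimen, t_ref: float) -> float:
    """Time-averaged concentration (ng/mL) from treatment start to `t_ref`:
    cumulative AUC(0, t_ref) / t_ref."""
    if t_ref <= 0:
        raise ValueError("reference time must be strictly positive")
    return cumulative_auc(ind_pk, regimen, t_ref) / t_ref


def imputed_reference_time(policy: ImputationPolicy, regimen: DosingRegimen) -> float:
    """Reference time (h) a censored subject is assigned under `policy`:
    EoT + 24 * extra follow-up days."""
    return regimen.eot + 24.0 * policy.extra_follow_up_days


@dataclass
class ERDataset:
    """One cohort's ER records for a single exposure metric.

    Wraps a DataFrame with columns ``subject_id, metric, exposure_ng_ml,
    responder, event_time_h`` (event time NaN for censored subjects).
    """

    data: pd.DataFrame
    metric_name: str = field(default="")

    def __post_init__(self) -> None:
        missing = set(ER_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"ER dataset missing columns {sorted(missing)}")
        resp = self.data["responder"]
        if not resp.isin([0, 1]).all():
            raise ValueError("responder must be binary")
        has_time = self.data["event_time_h"].notna()
        if not (has_time == resp.astype(bool)).all():
            raise ValueError("event_time_h must be present iff responder == 1")
        if not self.metric_name:
            self.metric_name = str(self.data["metric"].iloc[0])

    def __len__(self) -> int:
        return len(self.data)

    @property
    def exposure(self) -> np.ndarray:
        return self.data["exposure_ng_ml"].to_numpy(float)

    @property
    def responder(self) -> np.ndarray:
        return self.data["responder"].to_numpy(int)

    @property
    def n_event(self) -> int:
        return int(self.data["responder"].sum())

    @property
    def n_censored(self) -> int:
        return len(self.data) - self.n_event

    def to_csv(self, path) -> None:
        """Write with 12 significant digits so round trips are lossless."""
        self.data.to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def from_csv(cls, path) -> "ERDataset":
        df = pd.read_csv(Path(path))
        return cls(df)


def build_er_dataset(
    cohort_pk: list[IndividualPK],
    histories: list[EventHistory],
    regimen: DosingRegimen,
    metric: str = "cavte",
    policy: ImputationPolicy | None = None,
) -> ERDataset:
    """Assemble one record per subject for the requested exposure metric.

    ``metric="cavte"``: responders get CavTE at their first-event time;
    censored subjects get CavTE at the policy's imputed reference time
    (so a `policy` is required).  ``metric="cavss"``: every subject gets
    Cav,ss regardless of event status.  Responder flags come from the
    event histories either way.
    """
    metric = metric.lower()
    if metric not in ("cavte", "cavss"):
        raise ValueError(f"unknown metric {metric!r}")
    if metric == "cavte" and policy is None:
        raise ValueError("CavTE requires an imputation policy")
    by_id = {h.subject_id: h for h in histories}
    rows = []
    label = CAVSS_LABEL if metric == "cavss" else policy.metric_label
    for ind in cohort_pk:
        try:
            hist = by_id[ind.subject_id]
        except KeyError:
            raise DataIntegrityError(
                f"no event history for subject {ind.subject_id}"
            ) from None
        fe = first_event(hist)
        responder = int(fe is not None)
        event_time = fe[0] if fe is not None else np.nan
        if metric == "cavss":
            x = cav_ss(ind, regimen)
        else:
            t_ref = fe[0] if fe is not None else imputed_reference_time(policy, regimen)
            x = cav_te(ind, regimen, t_ref)
        rows.append(
            {
                "subject_id": ind.subject_id,
                "metric": label,
                "exposure_ng_ml": x,
                "responder": responder,
                "event_time_h": event_time,
            }
        )
    return ERDataset(pd.DataFrame(rows, columns=list(ER_COLUMNS)), metric_name=label)
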