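"""Ordinal adverse-event simulation: proportional odds with Markov components.

Grades 0/1/2 evolve on a discrete assessment grid as a first-order Markov
chain.  Conditional on the previous grade, the cumulative event
probabilities follow a proportional-odds (cumulative logit) construction
whose logits are shifted upwards by a saturable (Emax) function of the
concurrent drug concentration.  The maximal logit shift depends on whether
the previous assessment showed any event (grade >= 1) or not.

Cumulative-logit convention, with DE the concentration-driven logit shift:

    P(grade >= 1 | prev) = expit(anchor(prev) + DE)
    P(grade >= 2 | prev) = expit(anchor(prev) + increment(prev) + DE)

    prev = 0 -> (anchor, increment) = (B01, B02)
    prev = 1 -> (B11, B12)
    prev = 2 -> (B21, B22)

i.e. the parameter targeting grade 1 anchors P(>=1) and the parameter
targeting grade 2 forms the >=2 increment.  Increments are negative at the
default values, so P(>=2) <= P(>=1) and the three state probabilities are a
valid distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .pk import (
    DosingRegimen,
    IndividualPK,
    _as_seedseq,
    concentration,
    cumulative_auc,
    lognormal_sigma,
)

__all__ = [
    "AEModelParameters",
    "IndividualAEParams",
    "EventHistory",
    "drug_effect",
    "transition_probabilities",
    "sample_individual_ae",
    "simulate_event_history",
    "simulate_cohort_histories",
    "simulate_grades_from_concentration",
    "first_event",
    "assessment_times",
    "concentration_driver",
    "DEFAULT_DRIVER",
]

#: supported concentration drivers for the transition logits
DRIVERS = ("trough", "interval_average")

#: driver used when none is specified; see concentration_driver
DEFAULT_DRIVER = "interval_average"


@dataclass(frozen=True)
class AEModelParameters:
    """Typical adverse-event model parameters.

    ``b01 .. b22`` are the transition logit parameters (dimensionless);
    ``emax0``/``emax1`` the maximal logit drug effect when the previous
    grade was 0 / >= 1; ``ec50`` the half-maximal concentration in ng/mL.
    ``cv_ae`` is the fractional IIV applied to every AE parameter and
    ``emax_scale`` the scenario multiplier applied to both Emax values
    (the knob that sets the strength of the exposure-response relation).
    """

    b01: float = -6.59
    b02: float = -1.80
    b11: float = 0.311
    b12: float = -6.70
    b21: float = -0.563
    b22: float = -0.684
    emax0: float = 4.73
    emax1: float = 1.09
    ec50: float = 6.05
    cv_ae: float = 0.10
    emax_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.ec50 <= 0:
            raise ValueError("EC50 must be strictly positive")
        if self.emax_scale < 0:
            raise ValueError("emax_scale must be non-negative")
        if self.cv_ae < 0:
            raise ValueError("cv_ae must be non-negative")


@dataclass(frozen=True)
class IndividualAEParams:
    """Realised subject-level AE parameters (after IIV)."""

    subject_id: int
    b01: float
    b02: float
    b11: float
    b12: float
    b21: float
    b22: float
    emax0: float
    emax1: float
    ec50: float
    emax_scale: float = 1.0

    def __post_init__(self) -> None:
        if min(self.emax0, self.emax1, self.ec50) <= 0:
            raise ValueError("emax0, emax1 and ec50 must be strictly positive")

    def anchor_increment(self, prev_grade: int) -> tuple[float, float]:
        try:
            return {
                0: (self.b01, self.b02),
                1: (self.b11, self.b12),
                2: (self.b21, self.b22),
            }[prev_grade]
        except KeyError:
            raise ValueError(f"invalid grade {prev_grade!r}") from None


@dataclass(frozen=True)
class EventHistory:
    """One subject's ordinal grade trajectory on the assessment grid.

    The implicit state before the first assessment is grade 0.
    """

    subject_id: int
    assessment_times: np.ndarray
    grades: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.assessment_times, dtype=float)
        g = np.asarray(self.grades, dtype=int)
        if t.shape != g.shape or t.ndim != 1:
            raise ValueError("times and grades must be 1-D of equal length")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("assessment times must be strictly increasing")
        if np.any((g < 0) | (g > 2)):
            raise ValueError("grades must be in {0, 1, 2}")
        object.__setattr__(self, "assessment_times", t)
        object.__setattr__(self, "grades", g)


def drug_effect(c, prev_grade: int, ind: IndividualAEParams):
    """Concentration-driven logit shift: s * Emax_prev * C / (EC50 + C).

    Emax_prev is ``emax0`` when the previous grade is 0 and ``emax1`` when
    it is >= 1.  The shift is bounded in [0, s * Emax_prev).
    """
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    if prev_grade not in (0, 1, 2):
        raise ValueError(f"invalid grade {prev_grade!r}")
    emax = ind.emax0 if prev_grade == 0 else ind.emax1
    de = ind.emax_scale * emax * c / (ind.ec50 + c)
    return float(de) if de.ndim == 0 else de


def transition_probabilities(
    prev_grade: int, de: float, ind: IndividualAEParams
) -> tuple[float, float, float]:
    """State probabilities (p0, p1, p2) for the next assessment."""
    anchor, inc = ind.anchor_increment(prev_grade)
    p_ge1 = float(expit(anchor + de))
    p_ge2 = float(expit(anchor + inc + de))
    return (1.0 - p_ge1, p_ge1 - p_ge2, p_ge2)


def sample_individual_ae(
    params: AEModelParameters, n: int, seed
) -> list[IndividualAEParams]:
    """Draw `n` subjects' AE parameters with IIV.

    Strictly positive parameters (emax0, emax1, ec50) are perturbed
    log-normally with sigma^2 = ln(1 + cv^2).  The transition logit
    parameters are sign-indefinite, so a log-normal is not defined for
    them; they are perturbed additively with a normal of SD cv * |typical|,
    which matches the log-normal's spread to first order.  Per-subject
    child streams as in PK sampling; within a subject the draw order is
    b01, b02, b11, b12, b21, b22, emax0, emax1, ec50.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    ss = _as_seedseq(seed)
    cv = params.cv_ae
    sig = lognormal_sigma(cv)
    logits = np.array(
        [params.b01, params.b02, params.b11, params.b12, params.b21, params.b22]
    )
    out = []
    for i, child in enumerate(ss.spawn(n)):
        rng = np.random.default_rng(child)
        zb = rng.standard_normal(6)
        zp = rng.standard_normal(3)
        b = logits + cv * np.abs(logits) * zb
        out.append(
            IndividualAEParams(
                subject_id=i,
                b01=float(b[0]),
                b02=float(b[1]),
                b11=float(b[2]),
                b12=float(b[3]),
                b21=float(b[4]),
                b22=float(b[5]),
                emax0=params.emax0 * float(np.exp(sig * zp[0])),
                emax1=params.emax1 * float(np.exp(sig * zp[1])),
                ec50=params.ec50 * float(np.exp(sig * zp[2])),
                emax_scale=params.emax_scale,
            )
        )
    return out


def assessment_times(regimen: DosingRegimen, assessment_interval: float) -> np.ndarray:
    """Assessment grid t_k = k * interval, k = 1 .. EoT/interval.

    The interval must divide the treatment duration exactly.
    """
    if assessment_interval <= 0:
        raise ValueError("assessment interval must be positive")
    duration = regimen.eot - regimen.first_dose_time
    n_assess = duration / assessment_interval
    if abs(n_assess - round(n_assess)) > 1e-9:
        raise ValueError("assessment interval must divide the treatment duration")
    k = np.arange(1, int(round(n_assess)) + 1)
    return regimen.first_dose_time + k * assessment_interval


def concentration_driver(
    ind_pk: IndividualPK,
    regimen: DosingRegimen,
    times: np.ndarray,
    driver: str = DEFAULT_DRIVER,
) -> np.ndarray:
    """Concentration used in the transition logits at each assessment.

    ``trough``: the pre-dose concentration at the assessment time (a dose
    scheduled exactly at the assessment has not yet been absorbed because
    of the lag time).  ``interval_average``: cumulative AUC over the
    assessment interval divided by its length.
    """
    if driver == "trough":
        return np.atleast_1d(concentration(ind_pk, regimen, times))
    if driver == "interval_average":
        auc = np.atleast_1d(cumulative_auc(ind_pk, regimen, times))
        prev = np.concatenate(([0.0], auc[:-1]))
        widths = np.diff(np.concatenate(([regimen.first_dose_time], times)))
        return (auc - prev) / widths
    raise ValueError(f"unknown driver {driver!r}; expected one of {DRIVERS}")


def _ae_param_arrays(cohort_ae: list[IndividualAEParams]) -> dict[str, np.ndarray]:
    names = ("b01", "b02", "b11", "b12", "b21", "b22", "emax0", "emax1", "ec50",
             "emax_scale")
    return {k: np.array([getattr(a, k) for a in cohort_ae]) for k in names}


def _simulate_grades(
    conc: np.ndarray, cohort_ae: list[IndividualAEParams], uniforms: np.ndarray
) -> np.ndarray:
    """Vectorised Markov chain over subjects.

    conc and uniforms have shape (n_subjects, n_assessments); one uniform
    draw decides each transition: grade = [u < P(>=1)] + [u < P(>=2)].
    """
    p = _ae_param_arrays(cohort_ae)
    n, n_assess = conc.shape
    anchors = np.column_stack([p["b01"], p["b11"], p["b21"]])
    incs = np.column_stack([p["b02"], p["b12"], p["b22"]])
    rows = np.arange(n)
    prev = np.zeros(n, dtype=int)
    grades = np.zeros((n, n_assess), dtype=int)
    for k in range(n_assess):
        c = conc[:, k]
        emax = np.where(prev == 0, p["emax0"], p["emax1"])
        de = p["emax_scale"] * emax * c / (p["ec50"] + c)
        eta1 = anchors[rows, prev] + de
        eta2 = eta1 + incs[rows, prev]
        u = uniforms[:, k]
        prev = (u < expit(eta1)).astype(int) + (u < expit(eta2))
        grades[:, k] = prev
    return grades


def simulate_grades_from_concentration(
    conc: np.ndarray, cohort_ae: list[IndividualAEParams], seed=None
) -> np.ndarray:
    """Simulate grade trajectories given driver concentrations directly.

    ``conc`` has shape (n_subjects, n_assessments); subject i uses the
    i-th child stream spawned from ``seed``.  Useful for studying the
    Markov chain under a controlled (e.g. constant) exposure profile.
    Returns the (n_subjects, n_assessments) grade matrix.
    """
    conc = np.asarray(conc, dtype=float)
    if conc.ndim != 2 or conc.shape[0] != len(cohort_ae):
        raise ValueError("conc must be (n_subjects, n_assessments)")
    children = _as_seedseq(seed).spawn(conc.shape[0])
    uniforms = np.vstack(
        [np.random.default_rng(c).random(conc.shape[1]) for c in children]
    )
    return _simulate_grades(conc, cohort_ae, uniforms)


def simulate_event_history(
    ind_pk: IndividualPK,
    ind_ae: IndividualAEParams,
    regimen: DosingRegimen,
    assessment_interval: float = 168.0,
    seed=None,
    driver: str = DEFAULT_DRIVER,
) -> EventHistory:
    """Simulate one subject's grade trajectory on the assessment grid.

    The chain starts in grade 0, runs over (0, EoT] only, and draws the
    state at each assessment from :func:`transition_probabilities` with the
    drug effect evaluated at that assessment's driver concentration.
    Deterministic given the seed.
    """
    times = assessment_times(regimen, assessment_interval)
    conc = concentration_driver(ind_pk, regimen, times, driver)
    rng = np.random.default_rng(_as_seedseq(seed))
    u = rng.random(times.size)[np.newaxis, :]
    grades = _simulate_grades(conc[np.newaxis, :], [ind_ae], u)[0]
    return EventHistory(ind_pk.subject_id, times, grades)


def simulate_cohort_histories(
    cohort_pk: list[IndividualPK],
    cohort_ae: list[IndividualAEParams],
    regimen: DosingRegimen,
    assessment_interval: float = 168.0,
    seed=None,
    driver: str = DEFAULT_DRIVER,
) -> list[EventHistory]:
    """Simulate a whole cohort, one independent child stream per subject.

    Subject i's trajectory is identical to calling
    :func:`simulate_event_history` with the i-th spawned child seed, so the
    vectorised path and the per-subject path are interchangeable.
    """
    if len(cohort_pk) != len(cohort_ae):
        raise ValueError("PK and AE cohorts must have equal length")
    times = assessment_times(regimen, assessment_interval)
    conc = np.vstack(
        [concentration_driver(ind, regimen, times, driver) for ind in cohort_pk]
    )
    grades = simulate_grades_from_concentration(conc, cohort_ae, seed)
    return [
        EventHistory(ind.subject_id, times, grades[i])
        for i, ind in enumerate(cohort_pk)
    ]


def first_event(history: EventHistory):
    """Time and grade of the first grade >= 1 assessment, or None if the
    subject never has an event (censored)."""
    idx = np.nonzero(history.grades >= 1)[0]
    if idx.size == 0:
        return None
    i = int(idx[0])
    return (float(history.assessment_times[i]), int(history.grades[i]))
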