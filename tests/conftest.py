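"""Shared fixtures: typical-value subjects, regimens, and an independent
ODE oracle for the closed-form PK solutions."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from cavtesim import AEModelParameters, DosingRegimen, IndividualAEParams, IndividualPK


@pytest.fixture
def typical_ind() -> IndividualPK:
    """Subject at the typical population values."""
    return IndividualPK(subject_id=0, cl=17.7, v=229.0, ka=4.23, alag=0.154)


@pytest.fixture
def default_regimen() -> DosingRegimen:
    """60 mg q24h for 112 doses (four 28-day cycles)."""
    return DosingRegimen()


@pytest.fixture
def single_dose() -> DosingRegimen:
    return DosingRegimen(n_doses=1)


@pytest.fixture
def typical_ae_ind() -> IndividualAEParams:
    """AE parameters at the typical values (no IIV)."""
    p = AEModelParameters()
    return IndividualAEParams(
        subject_id=0,
        b01=p.b01,
        b02=p.b02,
        b11=p.b11,
        b12=p.b12,
        b21=p.b21,
        b22=p.b22,
        emax0=p.emax0,
        emax1=p.emax1,
        ec50=p.ec50,
        emax_scale=p.emax_scale,
    )


@pytest.fixture
def small_er_dataset_factory():
    """ER datasets with a prescribed event/censored split (exposure values
    are arbitrary but non-degenerate)."""
    import pandas as pd

    from cavtesim import ERDataset

    def _make(n: int, n_event: int) -> ERDataset:
        y = np.r_[np.ones(n_event, dtype=int), np.zeros(n - n_event, dtype=int)]
        df = pd.DataFrame(
            {
                "subject_id": np.arange(n),
                "metric": "CAVTE_EOT",
                "exposure_ng_ml": np.linspace(50.0, 250.0, n),
                "responder": y,
                "event_time_h": np.where(y == 1, 500.0, np.nan),
            }
        )
        return ERDataset(df)

    return _make


def ode_concentration(ind: IndividualPK, regimen: DosingRegimen, t_eval):
    """Concentration (ng/mL) by numerical integration of the depot/central
    two-state system, independent of the closed-form superposition.

    Each dose enters the depot compartment at its dose time plus the lag;
    the system is integrated piecewise between those absorption-start
    times with tight tolerances.
    """
    t_eval = np.asarray(t_eval, dtype=float)
    starts = np.asarray(regimen.dose_times) + ind.alag
    t_end = max(float(t_eval.max()), float(starts.max())) + 1.0

    def rhs(t, y):
        a, x = y
        return [-ind.ka * a, ind.ka * a - ind.ke * x]

    segments = np.concatenate([[0.0], starts[starts < t_end], [t_end]])
    segments = np.unique(segments)
    y = np.array([0.0, 0.0])
    out = np.full(t_eval.shape, np.nan)
    for lo, hi in zip(segments[:-1], segments[1:]):
        if np.any(np.isclose(lo, starts)):
            y = y + np.array([ind.f_bio * regimen.dose_amount, 0.0])
        inside = (t_eval >= lo) & (t_eval < hi)
        # always integrate to hi so the carried state is the segment end
        t_seg = np.append(np.sort(t_eval[inside]), hi)
        sol = solve_ivp(
            rhs, (lo, hi), y, t_eval=t_seg, rtol=1e-11, atol=1e-13, method="LSODA"
        )
        if inside.any():
            order = np.argsort(t_eval[inside])
            vals = np.empty(order.size)
            vals[order] = sol.y[1, :-1]
            out[inside] = vals
        y = sol.y[:, -1]
    # exact hits on the final segment boundary
    at_end = np.isclose(t_eval, t_end)
    out[at_end] = y[1]
    return out / ind.v * 1000.0
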