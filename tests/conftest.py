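"""Shared fixtures and the independent ODE oracle."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from amikpk.cohort import CohortSpec, TrueModel, generate_dataset, sample_cohort
from amikpk.pk_model import DoseEvent, IndividualParams

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=50)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


def ode_concentrations(ind: IndividualParams, doses, times, rtol=1e-12):
    """Brute-force ODE integration of the two-compartment infusion system.

    Independent of the package's closed-form solver: integrates the raw
    right-hand side piecewise between infusion discontinuities with a
    high-accuracy adaptive integrator.
    """
    def rhs(t, y):
        rate = sum(
            d.amount / d.duration
            for d in doses
            if d.start_time <= t < d.start_time + d.duration
        )
        a1, a2 = y
        return [
            rate - (ind.CL / ind.V) * a1 - (ind.Q / ind.V) * a1 + (ind.Q / ind.Vp) * a2,
            (ind.Q / ind.V) * a1 - (ind.Q / ind.Vp) * a2,
        ]

    breaks = sorted(
        {0.0}
        | {d.start_time for d in doses}
        | {d.start_time + d.duration for d in doses}
        | set(float(t) for t in times)
    )
    y = np.zeros(2)
    value_at = {breaks[0]: y.copy()}
    for a, b in zip(breaks[:-1], breaks[1:]):
        sol = solve_ivp(rhs, (a, b), y, method="DOP853", rtol=rtol, atol=1e-12)
        y = sol.y[:, -1]
        value_at[b] = y.copy()
    return np.array([value_at[float(t)][0] / ind.V for t in times])


@pytest.fixture(scope="session")
def small_dataset():
    """20-subject synthetic dataset for unit tests of the fit machinery."""
    cohort = sample_cohort(CohortSpec(n_subjects=20, seed=0))
    truth = TrueModel.surrogate_default(gamma=1.5)
    return generate_dataset(cohort, truth, dose_mg_per_kg=30.0, seed=0)


@pytest.fixture(scope="session")
def median_patient():
    return IndividualParams(CL=4.41, V=20.40, Vp=16.32, Q=5.43)


@pytest.fixture(scope="session")
def single_dose():
    return [DoseEvent(start_time=0.0, amount=2000.0, duration=0.5)]
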