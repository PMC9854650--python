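"""Two-compartment intravenous-infusion model with covariate submodels.

Structural model
----------------
Amikacin disposition is described by a linear two-compartment system with
zero-order (constant-rate) infusion input into the central compartment and
first-order elimination from it:

    dA1/dt = R(t) − (CL/V)·A1 − (Q/V)·A1 + (Q/Vp)·A2
    dA2/dt =        (Q/V)·A1 − (Q/Vp)·A2
    C(t)   = A1 / V

with A1, A2 the central and peripheral amounts (mg), CL the central
clearance (L/h), V and Vp the central and peripheral volumes (L), Q the
intercompartmental clearance (L/h, fixed at 5.43 by default), and R(t) the
infusion rate (mg/h), piecewise-constant over half-open windows
[start, start + duration).

Covariate submodel (final model): CL = CL1 · (eGFR/70)^CL2 and
V = V1 · (TBW/76.5); Vp and Q carry no covariate.

The solver evaluates the exact piecewise bi-exponential solution
(superposition over infusion windows), vectorized over parameter arrays so
that Monte-Carlo simulation needs no per-draw loop.  An alternative
``rate_constant`` parameterization reads CL and Q as first-order rate
constants (h⁻¹) instead of clearances.

Residual-error model: the assay SD is a polynomial in the observation,
SD(obs) = C0 + C1·obs + C2·obs² + C3·obs³, inflated either multiplicatively
(gamma: SD·γ) or additively (lambda: sqrt(SD² + λ²)) to capture process
noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "StructuralParams",
    "IndividualParams",
    "DoseEvent",
    "ErrorModel",
    "CovariateRelationship",
    "apply_covariate_model",
    "apply_relationship",
    "predict_concentrations",
    "predict_amounts",
    "concentration_profile",
    "residual_sd",
    "total_error_sd",
    "Q_FIXED",
    "EGFR_MEDIAN",
    "TBW_MEDIAN",
]

#: Intercompartmental clearance fixed to its estimated population mean (L/h).
Q_FIXED = 5.43
#: Population medians used to normalize the covariate submodels.
EGFR_MEDIAN = 70.0
TBW_MEDIAN = 76.5


@dataclass(frozen=True)
class StructuralParams:
    """Typical-value population parameters of the covariate model.

    CL1: central clearance (L/h) at eGFR 70 mL/min/1.73 m²
    CL2: dimensionless power exponent on eGFR/70
    V1:  central volume (L) at TBW 76.5 kg
    Vp:  peripheral volume (L)
    Q:   intercompartmental clearance (L/h), fixed
    """

    CL1: float
    CL2: float
    V1: float
    Vp: float
    Q: float = Q_FIXED

    def __post_init__(self):
        for name in ("CL1", "CL2", "V1", "Vp", "Q"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class IndividualParams:
    """Covariate-resolved parameters for one subject.

    Volumes and Q strictly positive; CL ≥ 0 (zero clearance is admitted so
    the no-elimination mass-balance limit can be exercised).
    """

    CL: float
    V: float
    Vp: float
    Q: float = Q_FIXED

    def __post_init__(self):
        for name in ("V", "Vp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        # CL = 0 admits the no-elimination limit; Q = 0 the one-compartment limit
        if self.CL < 0 or self.Q < 0:
            raise ValueError("CL and Q must be non-negative")


@dataclass(frozen=True)
class DoseEvent:
    """One constant-rate infusion: ``amount`` mg over ``duration`` h from ``start_time``."""

    start_time: float
    amount: float
    duration: float = 0.5

    def __post_init__(self):
        if self.amount < 0:
            raise ValueError("dose amount must be non-negative")
        if self.duration <= 0:
            raise ValueError("infusion duration must be strictly positive")
        if self.start_time < 0:
            raise ValueError("dose start time must be non-negative")


@dataclass(frozen=True)
class ErrorModel:
    """Residual-error model: SD polynomial plus gamma or lambda noise scalar."""

    kind: str = "gamma"  # "gamma" (multiplicative) or "lambda" (additive)
    noise: float = 1.0
    c0: float = 1.25
    c1: float = 0.05
    c2: float = 0.0
    c3: float = 0.0

    def __post_init__(self):
        if self.kind not in ("gamma", "lambda"):
            raise ValueError(f"unknown error-model kind: {self.kind!r}")
        if self.noise <= 0 and self.kind == "gamma":
            raise ValueError("gamma noise scalar must be strictly positive")
        if self.noise < 0:
            raise ValueError("lambda noise scalar must be non-negative")

    def with_noise(self, noise: float) -> "ErrorModel":
        return replace(self, noise=noise)


def residual_sd(obs, em: ErrorModel):
    """Assay SD polynomial C0 + C1·obs + C2·obs² + C3·obs³ (mg/L)."""
    obs = np.asarray(obs, dtype=float)
    if np.any(obs < 0):
        raise ValueError("observations must be non-negative")
    sd = em.c0 + em.c1 * obs + em.c2 * obs**2 + em.c3 * obs**3
    if np.any(sd <= 0):
        raise ValueError("degenerate SD polynomial: non-positive SD")
    return sd if sd.ndim else float(sd)


def total_error_sd(obs, em: ErrorModel):
    """Total residual SD: gamma → SD·γ; lambda → sqrt(SD² + λ²)."""
    sd = np.asarray(residual_sd(obs, em), dtype=float)
    if em.kind == "gamma":
        total = sd * em.noise
    else:
        total = np.sqrt(sd**2 + em.noise**2)
    if np.any(total <= 0):
        raise ValueError("non-positive total error SD")
    return total if total.ndim else float(total)


def apply_covariate_model(
    params: StructuralParams, egfr: float, tbw: float
) -> IndividualParams:
    """Resolve typical values to one subject: CL = CL1·(eGFR/70)^CL2, V = V1·(TBW/76.5)."""
    if egfr <= 0 or tbw <= 0:
        raise ValueError("covariates eGFR and TBW must be strictly positive")
    return IndividualParams(
        CL=params.CL1 * (egfr / EGFR_MEDIAN) ** params.CL2,
        V=params.V1 * (tbw / TBW_MEDIAN),
        Vp=params.Vp,
        Q=params.Q,
    )


@dataclass(frozen=True)
class CovariateRelationship:
    """One covariate-parameter relationship of the covariate submodel.

    Forms (P1 is the typical value, P2 a shape parameter where present):
      linear              P1 · (COV/COVmedian)
      exponential         P1 · exp(P2 · COV/COVmedian)
      power               P1 · (COV/COVmedian)^P2
      allometric          P1 · (COV/COVmedian)^e, e fixed (0.75 clearance-like,
                          1.0 volume-like)
      binary_linear       P1 + P2 · COV          (COV ∈ {0, 1})
      binary_exponential  P1 · P2^COV            (COV ∈ {0, 1})
    """

    form: str
    covariate_name: str
    covariate_median: float = 1.0
    p2: float | None = None
    allometric_exponent: float = 0.75

    _FORMS = (
        "linear",
        "exponential",
        "power",
        "allometric",
        "binary_linear",
        "binary_exponential",
    )

    def __post_init__(self):
        if self.form not in self._FORMS:
            raise ValueError(f"unknown covariate relationship form: {self.form!r}")
        if self.form.startswith("binary"):
            return
        if self.covariate_median <= 0:
            raise ValueError("covariate median must be strictly positive")


def apply_relationship(rel: CovariateRelationship, base, cov):
    """Evaluate a covariate relationship with typical value ``base`` (= P1)."""
    base = np.asarray(base, dtype=float)
    cov = np.asarray(cov, dtype=float)
    if rel.form.startswith("binary"):
        if not np.all(np.isin(cov, (0.0, 1.0))):
            raise ValueError("binary covariate must be 0 or 1")
    x = cov / rel.covariate_median
    if rel.form == "linear":
        return base * x
    if rel.form == "exponential":
        return base * np.exp(rel.p2 * x)
    if rel.form == "power":
        return base * x**rel.p2
    if rel.form == "allometric":
        return base * x**rel.allometric_exponent
    if rel.form == "binary_linear":
        return base + rel.p2 * cov
    if rel.form == "binary_exponential":
        return base * rel.p2**cov
    raise ValueError(f"unknown covariate relationship form: {rel.form!r}")


# --------------------------------------------------------------------------
# Exact solution of the two-compartment infusion system
# --------------------------------------------------------------------------

def _h(lam, tau):
    # (1 - exp(-lam*tau)) / lam, with the lam -> 0 limit tau; tau >= 0
    lam, tau = np.broadcast_arrays(lam, tau)
    small = np.abs(lam) < 1e-12
    lam_safe = np.where(small, 1.0, lam)
    return np.where(small, tau, -np.expm1(-lam_safe * tau) / lam_safe)


def _amounts(k10, k12, k21, doses: Sequence[DoseEvent], times):
    """Central/peripheral amounts; parameters broadcastable arrays, shape + (T,)."""
    k10, k12, k21 = np.broadcast_arrays(
        np.asarray(k10, dtype=float),
        np.asarray(k12, dtype=float),
        np.asarray(k21, dtype=float),
    )
    times = np.asarray(times, dtype=float)
    s = k10 + k12 + k21
    # discriminant strictly positive whenever k12 > 0
    disc = np.sqrt(np.maximum(s**2 - 4.0 * k10 * k21, 0.0))
    alpha = 0.5 * (s + disc)
    beta = 0.5 * (s - disc)
    shape = k10.shape + times.shape
    a1 = np.zeros(shape)
    a2 = np.zeros(shape)
    al = alpha[..., None]
    be = beta[..., None]
    k21e = k21[..., None]
    k12e = k12[..., None]
    denom = al - be  # > 0 strictly (distinct roots when k12 > 0)
    for dose in doses:
        if dose.amount == 0:
            continue
        rate = dose.amount / dose.duration
        tau = times - dose.start_time  # (T,)
        active = tau > 0
        tau_c = np.where(active, tau, 0.0)
        during = tau_c <= dose.duration
        tin = np.where(during, tau_c, dose.duration)
        tout = np.where(during, 0.0, tau_c - dose.duration)

        def term(lam):
            # integral of e^{-lam u} over the elapsed infusion, decayed post-infusion
            return np.exp(-lam * tout) * _h(lam, tin)

        t_a = term(al)
        t_b = term(be)
        c_a = (al - k21e) / denom
        c_b = (k21e - be) / denom
        a1 += np.where(active, rate * (c_a * t_a + c_b * t_b), 0.0)
        a2 += np.where(active, rate * k12e / denom * (t_b - t_a), 0.0)
    return a1, a2


def _rates(ind: IndividualParams | dict, parameterization: str = "clearance"):
    if parameterization == "clearance":
        k10 = ind.CL / ind.V
        k12 = ind.Q / ind.V
        k21 = ind.Q / ind.Vp
    elif parameterization == "rate_constant":
        # CL and Q read directly as first-order rate constants (h^-1)
        k10 = ind.CL
        k12 = ind.Q
        k21 = ind.Q * ind.V / ind.Vp
    else:
        raise ValueError(f"unknown parameterization: {parameterization!r}")
    return k10, k12, k21


def _check_times(times) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if times.ndim != 1:
        raise ValueError("times must be one-dimensional")
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    if np.any(np.diff(times) < 0):
        raise ValueError("times must be sorted ascending")
    return times


def predict_concentrations(
    ind: IndividualParams,
    doses: Sequence[DoseEvent],
    times,
    parameterization: str = "clearance",
) -> np.ndarray:
    """Central-compartment concentrations (mg/L) at sorted ``times`` (h)."""
    times = _check_times(times)
    k10, k12, k21 = _rates(ind, parameterization)
    a1, _ = _amounts(k10, k12, k21, doses, times)
    conc = a1 / ind.V
    # nonnegative by construction of the linear system; clamp roundoff
    assert np.all(conc > -1e-9)
    return np.maximum(conc, 0.0)


def predict_amounts(
    ind: IndividualParams,
    doses: Sequence[DoseEvent],
    times,
    parameterization: str = "clearance",
) -> tuple[np.ndarray, np.ndarray]:
    """Central and peripheral amounts (mg); used for mass-balance checks."""
    times = _check_times(times)
    k10, k12, k21 = _rates(ind, parameterization)
    return _amounts(k10, k12, k21, doses, times)


def concentration_profile(cl, v, vp, q, doses: Sequence[DoseEvent], times) -> np.ndarray:
    """Vectorized concentrations: parameter arrays broadcast, output shape + (T,).

    Same model as :func:`predict_concentrations` but accepting arrays of
    (CL, V, Vp, Q) so Monte-Carlo draws are simulated without a Python loop.
    """
    times = _check_times(times)
    cl, v, vp, q = np.broadcast_arrays(
        np.asarray(cl, dtype=float),
        np.asarray(v, dtype=float),
        np.asarray(vp, dtype=float),
        np.asarray(q, dtype=float),
    )
    if np.any(cl < 0) or np.any(v <= 0) or np.any(vp <= 0) or np.any(q < 0):
        raise ValueError("all PK parameters must be strictly positive")
    a1, _ = _amounts(cl / v, q / v, q / vp, doses, times)
    return np.maximum(a1 / v[..., None], 0.0)
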