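"""Synthetic ICU cohort and concentration-data generator.

Emulates the covariate structure of a septic-shock cohort (n = 138, 407
amikacin concentrations): total body weight and eGFR are sampled from
log-normals matched to the reported median and quartiles, height from a
truncated normal, age from a two-piece (quartile-matched, skewed) normal,
and sex as Bernoulli(0.652 male).  Serum creatinine is back-solved from
the sampled eGFR through the CKD-EPI equation so the written dataset is
internally consistent; the model itself consumes the sampled eGFR
directly, avoiding a circular error in the covariate of record.

Concentration data are generated under the two-compartment covariate model:
each subject receives ``dose_mg_per_kg`` × TBW over a 30-min infusion and is
sampled at 1 h always, plus 6/12/24 h each with probability 0.65 (so the
expected number of observations per subject is 1 + 3·0.65 = 2.95 ≈ 407/138).
Observation noise is additive Gaussian with SD = total_error_sd(true
concentration), truncated at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import covariates as cov
from .dataset import COLUMNS, PKDataset
from .pk_model import ErrorModel, Q_FIXED, concentration_profile, DoseEvent, total_error_sd
from .population import LogNormalSurrogate, PARAM_NAMES

__all__ = ["CohortSpec", "TrueModel", "sample_cohort", "generate_dataset"]

_Z75 = norm.ppf(0.75)  # 0.6745...


def _lognormal_from_quartiles(median: float, q1: float, q3: float):
    """(mu, sigma) of a log-normal matched to median and the geometric mean
    of the two quartile ratios (q3/median and median/q1)."""
    if not (0 < q1 < median < q3):
        raise ValueError("require 0 < q1 < median < q3")
    gm_ratio = np.sqrt(q3 / q1)
    return np.log(median), np.log(gm_ratio) / _Z75


def _truncated_lognormal_params(median, q1, q3, lo, hi):
    """(mu, sigma) of the parent log-normal such that, after truncation to
    [lo, hi], the sampled distribution still matches the target median and
    quartile-ratio.  Without this correction a heavy upper tail clipped at
    ``hi`` drags the realized median below the target."""
    from scipy.optimize import fsolve

    target_ratio = np.sqrt(q3 / q1)

    def trunc_quantile(mu, sigma, p):
        a = norm.cdf((np.log(lo) - mu) / sigma)
        b = norm.cdf((np.log(hi) - mu) / sigma)
        return np.exp(mu + sigma * norm.ppf(a + p * (b - a)))

    def equations(x):
        mu, log_sigma = x
        sigma = np.exp(log_sigma)
        med = trunc_quantile(mu, sigma, 0.5)
        ratio = np.sqrt(
            trunc_quantile(mu, sigma, 0.75) / trunc_quantile(mu, sigma, 0.25)
        )
        return [np.log(med / median), np.log(ratio / target_ratio)]

    mu0, sigma0 = _lognormal_from_quartiles(median, q1, q3)
    sol = fsolve(equations, [mu0, np.log(sigma0)], full_output=False)
    mu, sigma = float(sol[0]), float(np.exp(sol[1]))
    if not np.all(np.isfinite([mu, sigma])) or sigma <= 0:
        raise ValueError("infeasible truncated-quantile targets")
    return mu, sigma


def _truncated(draws: np.ndarray, rng, sampler, lo: float, hi: float) -> np.ndarray:
    """Redraw out-of-range values (rejection), preserving vector shape."""
    out = draws.copy()
    bad = (out < lo) | (out > hi)
    for _ in range(1000):
        if not bad.any():
            return out
        out[bad] = sampler(rng, int(bad.sum()))
        bad = (out < lo) | (out > hi)
    raise RuntimeError("truncation rejection did not converge; check bounds")


@dataclass
class CohortSpec:
    """Covariate distributions of the emulated ICU population."""

    n_subjects: int = 138
    seed: int = 0
    # (median, q1, q3), log-normal
    tbw_quartiles: tuple = (76.5, 62.0, 88.5)
    # (median, q1, q3, lo, hi), truncated normal
    height_quartiles: tuple = (170.0, 163.0, 177.0, 140.0, 210.0)
    # (median, q1, q3, lo, hi), two-piece normal (skewed)
    age_quartiles: tuple = (62.0, 49.0, 72.0, 18.0, 95.0)
    sex_male_prob: float = 0.652
    # (median, q1, q3, lo, hi), truncated log-normal
    egfr_quartiles: tuple = (70.0, 41.9, 111.5, 10.0, 180.0)

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")


@dataclass
class TrueModel:
    """Generating truth: a population sampler over (CL1, CL2, V1, Vp) plus noise."""

    sampler: object  # LogNormalSurrogate or DiscreteSampler
    q: float = Q_FIXED
    error_model: ErrorModel = field(
        default_factory=lambda: ErrorModel(kind="gamma", noise=1.5)
    )

    @classmethod
    def surrogate_default(cls, gamma: float = 1.5) -> "TrueModel":
        """Published amikacin estimates as generating truth (gamma noise)."""
        return cls(
            sampler=LogNormalSurrogate.amikacin_default(),
            error_model=ErrorModel(kind="gamma", noise=gamma),
        )


def sample_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Sample a reproducible covariate table (one row per subject)."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects

    mu_w, sd_w = _lognormal_from_quartiles(*spec.tbw_quartiles)
    tbw = np.exp(rng.normal(mu_w, sd_w, n))

    h_med, h_q1, h_q3, h_lo, h_hi = spec.height_quartiles
    h_sd = (h_q3 - h_q1) / (2 * _Z75)
    height = _truncated(
        rng.normal(h_med, h_sd, n), rng,
        lambda r, m: r.normal(h_med, h_sd, m), h_lo, h_hi,
    )

    a_med, a_q1, a_q3, a_lo, a_hi = spec.age_quartiles
    sd_below = (a_med - a_q1) / _Z75
    sd_above = (a_q3 - a_med) / _Z75

    def draw_age(r, m):
        z = r.standard_normal(m)
        return a_med + np.where(z < 0, sd_below, sd_above) * z

    age = _truncated(draw_age(rng, n), rng, draw_age, a_lo, a_hi)

    sex = (rng.random(n) < spec.sex_male_prob).astype(int)  # 1 = male

    g_med, g_q1, g_q3, g_lo, g_hi = spec.egfr_quartiles
    mu_g, sd_g = _truncated_lognormal_params(g_med, g_q1, g_q3, g_lo, g_hi)

    def draw_egfr(r, m):
        return np.exp(r.normal(mu_g, sd_g, m))

    egfr = _truncated(draw_egfr(rng, n), rng, draw_egfr, g_lo, g_hi)

    scr = np.array(
        [cov.scr_from_ckdepi(g, a, s) for g, a, s in zip(egfr, age, sex)]
    )
    table = pd.DataFrame(
        {
            "ID": np.arange(1, n + 1),
            "AGE": age,
            "SEX": sex,
            "HT": height,
            "WT": tbw,
            "SCR": scr,
            "EGFR": egfr,
        }
    )
    return table


DEFAULT_SAMPLING = {"always": (1.0,), "optional": (6.0, 12.0, 24.0), "p_optional": 0.65}


def generate_dataset(
    cohort: pd.DataFrame,
    truth: TrueModel,
    dose_mg_per_kg: float = 30.0,
    sampling_design: dict | None = None,
    seed: int = 0,
    infusion_duration: float = 0.5,
    covariate_effects: bool = True,
) -> PKDataset:
    """Simulate concentrations for a cohort under the generating truth.

    Per-subject RNG substreams are spawned from one master seed, so the
    generated table is independent of iteration order.  With
    ``covariate_effects=False`` the sampled (CL1, V1) are used directly as
    (CL, V) — a null population with no eGFR or weight influence, used to
    measure the false-selection rate of the covariate search.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    design = dict(DEFAULT_SAMPLING if sampling_design is None else sampling_design)

    rows = []
    for pos, row in enumerate(cohort.itertuples()):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), pos]))
        theta = truth.sampler.draw(1, rng)[0]  # (CL1, CL2, V1, Vp)
        p = dict(zip(PARAM_NAMES, theta))
        if covariate_effects:
            cl = p["CL1"] * (row.EGFR / 70.0) ** p["CL2"]
            v = p["V1"] * (row.WT / 76.5)
        else:
            cl, v = p["CL1"], p["V1"]
        amount = dose_mg_per_kg * row.WT
        dose = DoseEvent(start_time=0.0, amount=amount, duration=infusion_duration)

        times = list(design["always"])
        for t in design["optional"]:
            if rng.random() < design["p_optional"]:
                times.append(t)
        times = np.sort(np.asarray(times, dtype=float))

        true_conc = concentration_profile(cl, v, p["Vp"], truth.q, [dose], times)
        sd = np.asarray(total_error_sd(true_conc, truth.error_model))
        obs = np.maximum(true_conc + rng.normal(0.0, 1.0, times.size) * sd, 0.0)

        base = {
            "ID": row.ID, "WT": row.WT, "SCR": row.SCR, "AGE": row.AGE,
            "SEX": row.SEX, "HT": row.HT, "EGFR": row.EGFR,
        }
        rows.append({**base, "TIME": 0.0, "EVID": 1, "AMT": amount,
                     "DUR": infusion_duration, "DV": np.nan})
        for t, y in zip(times, obs):
            rows.append({**base, "TIME": t, "EVID": 0, "AMT": np.nan,
                         "DUR": np.nan, "DV": y})

    df = pd.DataFrame(rows)[COLUMNS]
    return PKDataset(df)
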