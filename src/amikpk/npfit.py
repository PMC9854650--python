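"""Nonparametric population PK estimation by adaptive-grid maximum likelihood.

The between-subject distribution of the PK parameters is estimated as a
discrete distribution — support points with probabilities — maximizing the
marginal likelihood

    L(F) = Π_i Σ_j w_j p(y_i | θ_j)

without any parametric (e.g. log-normal) assumption.  ``p(y_i | θ_j)`` is a
product of Gaussian densities with SD given by the residual-error model.
The optimal mixing distribution is known to be discrete with at most as
many support points as subjects, which motivates the approach:

1. seed the parameter box with a low-discrepancy (Sobol) grid;
2. optimize the probability weights over the simplex (a convex problem,
   solved here by EM / multiplicative updates);
3. prune negligible-weight points and merge near-duplicates;
4. locally refine: propose ±ε perturbations of every surviving support
   point per dimension, re-optimize, and shrink ε when nothing improves;
5. interleave a one-dimensional search over the residual noise scalar
   (gamma or lambda).

Covariate submodels are declared as :class:`CovariateTerm` entries of a
:class:`ModelSpec`; a forward/backward stepwise search over candidate terms
uses the likelihood-ratio χ² criterion at the 0.05 level.

All likelihood computation is done in log space with per-subject max
subtraction; the reported log-likelihood is exact (no normalization is
dropped).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import chi2
from scipy.stats import qmc
from scipy.optimize import minimize_scalar

from .dataset import PKDataset, Subject
from .pk_model import ErrorModel, concentration_profile, total_error_sd

__all__ = [
    "SupportPoint",
    "NPDistribution",
    "CovariateTerm",
    "ModelSpec",
    "FitConfig",
    "FitResult",
    "DistributionSummary",
    "initialize_grid",
    "likelihood_matrix",
    "optimize_weights",
    "mixture_loglik",
    "condense",
    "adaptive_refine",
    "estimate_gamma",
    "fit",
    "predictions",
    "fit_metrics",
    "summarize",
    "weighted_median",
    "covariate_search",
    "final_model_spec",
    "base_model_spec",
]

_LOG_2PI = float(np.log(2.0 * np.pi))

# Stepwise-comparison stabilization: a decision whose -2Δloglik lies within
# _STAB_BAND of the χ² critical value (or below it) triggers up to
# _STAB_ROUNDS alternating warm-started refits of both models; a refit
# counts as progress when it gains more than _STAB_TOL log-likelihood.
# The band matches the observed optimizer noise of a few loglik units.
_STAB_ROUNDS = 2
_STAB_BAND = 10.0
_STAB_TOL = 0.5


# --------------------------------------------------------------------------
# Model specification
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CovariateTerm:
    """A covariate effect on one structural parameter.

    ``form`` follows the covariate-relationship catalogue: linear scaling by
    COV/COVmedian has no shape parameter; power and exponential forms add a
    fitted shape dimension (P2); allometric fixes the exponent; the binary
    forms add a fitted offset/factor for a 0/1 covariate.
    """

    parameter: str  # "CL", "V" or "Vp"
    covariate: str  # dataset column, e.g. "EGFR", "WT"
    form: str
    median: float = 1.0
    p2_range: tuple = (0.01, 10.0)
    allometric_exponent: float = 0.75

    _WITH_P2 = ("power", "exponential", "binary_linear", "binary_exponential")

    @property
    def has_p2(self) -> bool:
        return self.form in self._WITH_P2

    def label(self) -> str:
        return f"{self.covariate}->{self.parameter}({self.form})"


@dataclass(frozen=True)
class ModelSpec:
    """Structural + covariate model: which dimensions are estimated, and how
    a support-point vector resolves to subject-level (CL, V, Vp, Q)."""

    base_ranges: dict  # e.g. {"CL": (0.01, 15), "V": (0.01, 60), "Vp": (0.1, 100)}
    terms: tuple = ()
    q: float = 5.43
    n_compartments: int = 2

    def __post_init__(self):
        base = ("CL", "V", "Vp") if self.n_compartments == 2 else ("CL", "V")
        if set(self.base_ranges) != set(base):
            raise ValueError(f"base_ranges must have exactly {base}")
        for t in self.terms:
            if t.parameter not in base:
                raise ValueError(f"term on unknown parameter {t.parameter}")

    @property
    def base_params(self) -> tuple:
        return ("CL", "V", "Vp") if self.n_compartments == 2 else ("CL", "V")

    def _terms_on(self, p: str):
        return [t for t in self.terms if t.parameter == p]

    @property
    def dim_names(self) -> list:
        names = []
        for p in self.base_params:
            terms = self._terms_on(p)
            names.append(f"{p}1" if terms else p)
            k = 2
            for t in terms:
                if t.has_p2:
                    names.append(f"{p}{k}")
                    k += 1
        return names

    @property
    def ranges(self) -> dict:
        out = {}
        for p in self.base_params:
            terms = self._terms_on(p)
            out[f"{p}1" if terms else p] = tuple(self.base_ranges[p])
            k = 2
            for t in terms:
                if t.has_p2:
                    out[f"{p}{k}"] = tuple(t.p2_range)
                    k += 1
        return out

    @property
    def n_dims(self) -> int:
        return len(self.dim_names)

    def resolve(self, theta: np.ndarray, covs: dict):
        """Map support vectors (m, d) + subject covariates to (CL, V, Vp, Q)."""
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        values = {}
        i = 0
        for p in self.base_params:
            val = theta[:, i]
            i += 1
            for t in self._terms_on(p):
                c = float(covs[t.covariate])
                x = c / t.median
                if t.form == "linear":
                    val = val * x
                elif t.form == "power":
                    val = val * x ** theta[:, i]
                    i += 1
                elif t.form == "exponential":
                    val = val * np.exp(theta[:, i] * x)
                    i += 1
                elif t.form == "allometric":
                    val = val * x**t.allometric_exponent
                elif t.form == "binary_linear":
                    val = val + theta[:, i] * c
                    i += 1
                elif t.form == "binary_exponential":
                    val = val * theta[:, i] ** c
                    i += 1
                else:
                    raise ValueError(f"unknown form {t.form!r}")
            values[p] = val
        cl, v = values["CL"], values["V"]
        if self.n_compartments == 2:
            return cl, v, values["Vp"], self.q
        one = np.ones_like(cl)
        return cl, v, one, 0.0

    def dim_layout(self) -> dict:
        """Per base parameter: its P1 dim name and the P2 dim names of its terms."""
        layout = {}
        for p in self.base_params:
            terms = self._terms_on(p)
            p2 = []
            k = 2
            for t in terms:
                if t.has_p2:
                    p2.append(f"{p}{k}")
                    k += 1
            layout[p] = {"p1": f"{p}1" if terms else p, "p2": p2}
        return layout

    def with_term(self, term: CovariateTerm) -> "ModelSpec":
        return replace(self, terms=self.terms + (term,))

    def without_term(self, term: CovariateTerm) -> "ModelSpec":
        return replace(self, terms=tuple(t for t in self.terms if t != term))


def base_model_spec(n_compartments: int = 2) -> ModelSpec:
    """Covariate-free model with wide default search ranges."""
    if n_compartments == 2:
        ranges = {"CL": (0.01, 15.0), "V": (0.01, 60.0), "Vp": (0.1, 100.0)}
    else:
        ranges = {"CL": (0.01, 15.0), "V": (0.01, 100.0)}
    return ModelSpec(base_ranges=ranges, n_compartments=n_compartments)


def final_model_spec() -> ModelSpec:
    """The final amikacin model: eGFR power on CL, TBW linear on V.

    Fitted dimensions CL1 (L/h at eGFR 70), CL2 (power exponent), V1 (L at
    TBW 76.5 kg), Vp (L); Q fixed at 5.43 L/h.  Search ranges are the
    published pre-set intervals.
    """
    return ModelSpec(
        base_ranges={"CL": (0.01, 15.0), "V": (0.01, 60.0), "Vp": (0.1, 100.0)},
        terms=(
            CovariateTerm("CL", "EGFR", "power", median=70.0, p2_range=(0.01, 10.0)),
            CovariateTerm("V", "WT", "linear", median=76.5),
        ),
    )


# --------------------------------------------------------------------------
# Distribution containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SupportPoint:
    theta: np.ndarray
    weight: float


@dataclass
class NPDistribution:
    """Discrete population distribution: support points with probabilities."""

    theta: np.ndarray  # (m, d)
    weights: np.ndarray  # (m,)
    dim_names: list
    ranges: dict  # name -> (lo, hi)

    def __post_init__(self):
        self.theta = np.atleast_2d(np.asarray(self.theta, dtype=float))
        self.weights = np.asarray(self.weights, dtype=float)
        if self.theta.shape[0] != self.weights.size:
            raise ValueError("theta/weights mismatch")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        for k, name in enumerate(self.dim_names):
            lo, hi = self.ranges[name]
            if np.any(self.theta[:, k] < lo - 1e-12) or np.any(self.theta[:, k] > hi + 1e-12):
                raise ValueError(f"support outside declared range for {name}")

    @property
    def n_points(self) -> int:
        return self.theta.shape[0]

    @property
    def points(self) -> list:
        return [SupportPoint(t, w) for t, w in zip(self.theta, self.weights)]

    def column(self, name: str) -> np.ndarray:
        return self.theta[:, self.dim_names.index(name)]


def initialize_grid(ranges: dict, n_points: int, seed: int = 0) -> "NPDistribution":
    """Low-discrepancy (scrambled Sobol) grid with uniform weights."""
    names = list(ranges)
    d = len(names)
    if n_points < d + 1:
        raise ValueError("n_points must be at least dimension + 1")
    lows = np.array([ranges[n][0] for n in names], dtype=float)
    highs = np.array([ranges[n][1] for n in names], dtype=float)
    if np.any(lows >= highs):
        raise ValueError("each range must satisfy lo < hi")
    sampler = qmc.Sobol(d, scramble=True, seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # non power-of-two draw
        u = sampler.random(n_points)
    theta = lows + u * (highs - lows)
    w = np.full(n_points, 1.0 / n_points)
    return NPDistribution(theta=theta, weights=w, dim_names=names, ranges=dict(ranges))


# --------------------------------------------------------------------------
# Likelihood machinery
# --------------------------------------------------------------------------

class _Workspace:
    """Flattened observations + cached prediction machinery for one dataset."""

    def __init__(self, dataset: PKDataset, model: ModelSpec, error_model: ErrorModel,
                 loq: float | None = None, blq_strategy: str = "drop"):
        self.model = model
        self.error_model = error_model
        self.n_blq_dropped = 0
        if loq is not None and blq_strategy == "drop":
            dataset, self.n_blq_dropped = dataset.drop_blq(loq)
        subjects = dataset.subjects()
        if loq is not None and blq_strategy == "half":
            for s in subjects:
                s.obs_values = np.where(s.obs_values < loq, loq / 2.0, s.obs_values)
        for s in subjects:
            if s.n_obs < 1:
                raise ValueError(f"subject {s.id} has no observations")
        self.subjects = subjects
        self.ids = [s.id for s in subjects]
        counts = np.array([s.n_obs for s in subjects])
        self.offsets = np.concatenate([[0], np.cumsum(counts)])
        self.y = np.concatenate([s.obs_values for s in subjects])
        self.sd_poly = np.asarray(
            error_model.c0 + error_model.c1 * self.y
            + error_model.c2 * self.y**2 + error_model.c3 * self.y**3
        )
        if np.any(self.sd_poly <= 0):
            raise ValueError("SD polynomial non-positive at an observation")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_obs(self) -> int:
        return self.y.size

    def total_sd(self, noise: float) -> np.ndarray:
        if self.error_model.kind == "gamma":
            return self.sd_poly * noise
        return np.sqrt(self.sd_poly**2 + noise**2)

    def pred(self, theta: np.ndarray) -> np.ndarray:
        """(m, total_obs) model predictions for every support vector."""
        theta = np.atleast_2d(theta)
        m = theta.shape[0]
        out = np.empty((m, self.n_obs))
        for i, s in enumerate(self.subjects):
            cl, v, vp, q = self.model.resolve(theta, s.covariates)
            conc = concentration_profile(cl, v, vp, q, s.doses, s.obs_times)
            out[:, self.offsets[i]:self.offsets[i + 1]] = conc
        if not np.all(np.isfinite(out)):
            bad = np.argwhere(~np.isfinite(out))
            i_sub = int(np.searchsorted(self.offsets, bad[0, 1], side="right") - 1)
            raise FloatingPointError(
                f"non-finite prediction for subject {self.ids[i_sub]} "
                f"at support point {bad[0, 0]}"
            )
        return out

    def loglik_from_pred(self, pred: np.ndarray, noise: float) -> np.ndarray:
        """(N, m) per-subject log-likelihood of each support point."""
        sd = self.total_sd(noise)
        z2 = ((pred - self.y) / sd) ** 2
        obs_ll = -0.5 * (z2 + _LOG_2PI) - np.log(sd)
        return np.add.reduceat(obs_ll, self.offsets[:-1], axis=1).T

    def loglik_matrix(self, theta: np.ndarray, noise: float) -> np.ndarray:
        return self.loglik_from_pred(self.pred(theta), noise)


def likelihood_matrix(dataset: PKDataset, model: ModelSpec,
                      points: np.ndarray, error_model: ErrorModel) -> np.ndarray:
    """Per-subject likelihood of each support point, row-rescaled.

    Entry (i, j) is the product of Gaussian observation densities for
    subject i under point j, divided by the subject's row maximum so every
    row is finite with maximum 1 (raw densities underflow for rich
    designs).  Relative magnitudes within a row — all the weight optimizer
    uses — are preserved.
    """
    ws = _Workspace(dataset, model, error_model)
    logL = ws.loglik_matrix(np.atleast_2d(points), error_model.noise)
    L = np.exp(logL - logL.max(axis=1, keepdims=True))
    if not np.all(np.isfinite(L)):
        raise FloatingPointError("non-finite likelihood after rescaling")
    return L


def mixture_loglik(L: np.ndarray, weights: np.ndarray) -> float:
    """Σ_i log Σ_j w_j L_ij for a linear-scale likelihood matrix."""
    mix = L @ weights
    if np.any(mix <= 0):
        return -np.inf
    return float(np.log(mix).sum())


def _em_weights(logL: np.ndarray, w0: np.ndarray | None = None,
                tol: float = 1e-8, max_iter: int = 5000):
    """EM / multiplicative updates for the convex NPML weight problem.

    Monotone in log-likelihood; returns (weights, loglik) with the exact
    (unscaled) log-likelihood.
    """
    n, m = logL.shape
    rowmax = logL.max(axis=1, keepdims=True)
    dead = ~np.isfinite(rowmax[:, 0])
    if np.any(dead):
        raise ValueError(
            f"subject row(s) {np.nonzero(dead)[0].tolist()} supported by no point"
        )
    L = np.exp(logL - rowmax)
    scale = float(rowmax.sum())
    w = np.full(m, 1.0 / m) if w0 is None else np.asarray(w0, dtype=float).copy()
    w = np.maximum(w, 0.0)
    w /= w.sum()
    ll_prev = -np.inf
    for _ in range(max_iter):
        mix = L @ w
        if np.any(mix <= 0):
            # a zero-weight region left a subject unsupported; re-seed uniformly
            w = np.full(m, 1.0 / m)
            mix = L @ w
        ll = float(np.log(mix).sum()) + scale
        if ll - ll_prev < tol:
            ll_prev = ll
            break
        ll_prev = ll
        w = w * (L.T @ (1.0 / mix)) / n
        s = w.sum()
        if s <= 0:
            raise FloatingPointError("weight iteration collapsed")
        w /= s
    return w, ll_prev


def optimize_weights(L: np.ndarray, tol: float = 1e-8, max_iter: int = 5000) -> np.ndarray:
    """Maximize Σ_i log Σ_j w_j L_ij over the probability simplex.

    ``L`` is a linear-scale (possibly row-rescaled) likelihood matrix with
    no all-zero row.
    """
    L = np.asarray(L, dtype=float)
    if np.any(L < 0):
        raise ValueError("likelihood matrix must be nonnegative")
    zero_rows = np.nonzero(~(L > 0).any(axis=1))[0]
    if zero_rows.size:
        raise ValueError(f"subject row(s) {zero_rows.tolist()} supported by no point")
    with np.errstate(divide="ignore"):
        logL = np.log(L)
    w, _ = _em_weights(logL, tol=tol, max_iter=max_iter)
    return w


# --------------------------------------------------------------------------
# Pruning and refinement
# --------------------------------------------------------------------------

def _condense_arrays(theta: np.ndarray, w: np.ndarray, ranges_arr: np.ndarray,
                     weight_tol: float, merge_tol: float):
    """Drop tiny weights, merge near-duplicates; returns (theta, w, kept_idx)."""
    keep = w >= weight_tol * w.max()
    idx = np.nonzero(keep)[0]
    theta, w = theta[idx], w[idx].copy()
    widths = ranges_arr[:, 1] - ranges_arr[:, 0]
    order = np.argsort(-w)
    scaled = theta / widths
    accepted: list[int] = []
    for j in order:
        merged = False
        for a in accepted:
            if np.max(np.abs(scaled[j] - scaled[a])) <= merge_tol:
                w[a] += w[j]
                merged = True
                break
        if not merged:
            accepted.append(j)
    accepted = sorted(accepted)
    theta, w, idx = theta[accepted], w[accepted], idx[accepted]
    w = w / w.sum()
    return theta, w, idx


def condense(dist: NPDistribution, weight_tol: float = 1e-10,
             merge_tol: float = 1e-4) -> NPDistribution:
    """Prune a distribution: drop relative weights below ``weight_tol`` and
    merge points closer than ``merge_tol`` (relative to range width) in every
    dimension, summing their weights (the heavier point's location is kept)."""
    ranges_arr = np.array([dist.ranges[n] for n in dist.dim_names], dtype=float)
    theta, w, _ = _condense_arrays(
        dist.theta, dist.weights, ranges_arr, weight_tol, merge_tol
    )
    return NPDistribution(theta, w, list(dist.dim_names), dict(dist.ranges))


@dataclass
class _RefineInfo:
    loglik: float
    cycles: int
    converged: bool
    eps_final: float


def _refine(ws: _Workspace, dist: NPDistribution, noise: float, cfg: "FitConfig"):
    """Adaptive local search; returns (NPDistribution, pred_matrix, info)."""
    names = dist.dim_names
    ranges_arr = np.array([dist.ranges[n] for n in names], dtype=float)
    lows, highs = ranges_arr[:, 0], ranges_arr[:, 1]
    widths = highs - lows

    theta, w = dist.theta.copy(), dist.weights.copy()
    P = ws.pred(theta)
    w, ll = _em_weights(ws.loglik_from_pred(P, noise), w0=w,
                        tol=cfg.em_tol, max_iter=cfg.em_max_iter)
    theta, w, kept = _condense_arrays(theta, w, ranges_arr, cfg.weight_tol, cfg.merge_tol)
    P = P[kept]

    eps = cfg.eps0
    cycles = 0
    converged = False
    while cycles < cfg.max_refine_cycles:
        if eps < cfg.eps_min:
            converged = True
            break
        cycles += 1
        m, d = theta.shape
        cand = np.repeat(theta, 2 * d, axis=0)
        steps = np.zeros((2 * d, d))
        for k in range(d):
            steps[2 * k, k] = eps * widths[k]
            steps[2 * k + 1, k] = -eps * widths[k]
        cand = cand + np.tile(steps, (m, 1))
        cand = np.clip(cand, lows, highs)
        Pc = ws.pred(cand)
        P_full = np.vstack([P, Pc])
        theta_full = np.vstack([theta, cand])
        w0 = np.concatenate([w * (1.0 - 1e-6),
                             np.full(cand.shape[0], 1e-6 / cand.shape[0])])
        w_full, ll_new = _em_weights(ws.loglik_from_pred(P_full, noise), w0=w0,
                                     tol=cfg.em_tol, max_iter=cfg.em_max_iter)
        theta_new, w_new, kept = _condense_arrays(
            theta_full, w_full, ranges_arr, cfg.weight_tol, cfg.merge_tol
        )
        P_new = P_full[kept]
        w_new, ll_new = _em_weights(ws.loglik_from_pred(P_new, noise), w0=w_new,
                                    tol=cfg.em_tol, max_iter=cfg.em_max_iter)
        if ll_new > ll + cfg.refine_ll_tol:
            theta, w, P, ll = theta_new, w_new, P_new, ll_new
        else:
            if ll_new > ll:  # keep small gains, still shrink the step
                theta, w, P, ll = theta_new, w_new, P_new, ll_new
            eps *= 0.5

    out = NPDistribution(theta, w, list(names), dict(dist.ranges))
    return out, P, _RefineInfo(loglik=ll, cycles=cycles, converged=converged,
                               eps_final=eps)


def adaptive_refine(dataset: PKDataset, model: ModelSpec, dist: NPDistribution,
                    error_model: ErrorModel, max_cycles: int = 10,
                    config: "FitConfig | None" = None) -> NPDistribution:
    """Refine a support distribution by local ±ε search (log-lik never decreases)."""
    cfg = config or FitConfig()
    cfg = replace(cfg, max_refine_cycles=max_cycles)
    ws = _Workspace(dataset, model, error_model, loq=cfg.loq,
                    blq_strategy=cfg.blq_strategy)
    out, _, info = _refine(ws, dist, error_model.noise, cfg)
    if not info.converged:
        warnings.warn(
            f"adaptive refinement stopped after {info.cycles} cycles "
            f"(eps={info.eps_final:.2e}) before meeting the step tolerance"
        )
    return out


def estimate_gamma(dataset: PKDataset, model: ModelSpec, dist: NPDistribution,
                   error_model: ErrorModel, bounds: tuple = (0.1, 10.0),
                   start: float = 3.0, config: "FitConfig | None" = None) -> float:
    """Maximize the weight-optimized log-likelihood over the noise scalar."""
    cfg = config or FitConfig()
    ws = _Workspace(dataset, model, error_model, loq=cfg.loq,
                    blq_strategy=cfg.blq_strategy)
    g, _, _ = _estimate_noise(ws, dist.theta, dist.weights, bounds, start, cfg)
    return g


def _estimate_noise(ws: _Workspace, theta, w, bounds, start, cfg):
    P = ws.pred(theta)

    def negll(g: float) -> float:
        _, ll = _em_weights(ws.loglik_from_pred(P, g), w0=w,
                            tol=cfg.em_tol, max_iter=cfg.em_max_iter)
        return -ll

    res = minimize_scalar(negll, bounds=bounds, method="bounded",
                          options={"xatol": 1e-3})
    g_hat = float(res.x)
    ll_hat = -float(res.fun)
    ll_start = -negll(start)
    if ll_hat < ll_start:  # maximization contract: never worse than the start value
        g_hat, ll_hat = start, ll_start
    if min(g_hat - bounds[0], bounds[1] - g_hat) < 1e-2 * (bounds[1] - bounds[0]):
        warnings.warn(f"noise scalar at search boundary: {g_hat:.3g}")
    w_new, ll = _em_weights(ws.loglik_from_pred(P, g_hat), w0=w,
                            tol=cfg.em_tol, max_iter=cfg.em_max_iter)
    return g_hat, w_new, ll


# --------------------------------------------------------------------------
# Full fit
# --------------------------------------------------------------------------

@dataclass
class FitConfig:
    """Tuning knobs of the adaptive-grid fit (all defaults documented)."""

    n_init: int = 256
    seed: int = 0
    max_refine_cycles: int = 10
    eps0: float = 0.2
    eps_min: float = 1e-4
    refine_ll_tol: float = 1e-4
    em_tol: float = 1e-8
    em_max_iter: int = 5000
    max_outer: int = 4
    outer_tol: float = 1e-3
    estimate_noise: bool = True
    noise_start: float = 3.0
    noise_bounds: tuple = (0.1, 10.0)
    weight_tol: float = 1e-10
    merge_tol: float = 1e-4
    loq: float | None = None
    blq_strategy: str = "drop"  # or "half"


@dataclass
class FitResult:
    """Everything the fit produced, serializable to JSON."""

    model: ModelSpec
    distribution: NPDistribution
    error_model: ErrorModel
    loglik: float
    aic: float
    gamma_hat: float
    pop_bias: float
    pop_imprecision: float
    ind_bias: float
    ind_imprecision: float
    posterior: np.ndarray  # (n_subjects, n_points)
    subject_ids: list
    converged: bool
    n_blq_dropped: int = 0
    messages: list = field(default_factory=list)

    def summary(self, **kwargs) -> "DistributionSummary":
        return summarize(self.distribution, **kwargs)

    def to_json(self, path=None) -> str:
        payload = {
            "dim_names": self.distribution.dim_names,
            "ranges": {k: list(v) for k, v in self.distribution.ranges.items()},
            "support": self.distribution.theta.tolist(),
            "weights": self.distribution.weights.tolist(),
            "loglik": self.loglik,
            "aic": self.aic,
            "gamma_hat": self.gamma_hat,
            "error_model": {
                "kind": self.error_model.kind, "noise": self.error_model.noise,
                "c0": self.error_model.c0, "c1": self.error_model.c1,
                "c2": self.error_model.c2, "c3": self.error_model.c3,
            },
            "metrics": {
                "pop_bias": self.pop_bias, "pop_imprecision": self.pop_imprecision,
                "ind_bias": self.ind_bias, "ind_imprecision": self.ind_imprecision,
            },
            "model": {
                "base_ranges": {k: list(v) for k, v in self.model.base_ranges.items()},
                "q": self.model.q,
                "n_compartments": self.model.n_compartments,
                "terms": [
                    {"parameter": t.parameter, "covariate": t.covariate,
                     "form": t.form, "median": t.median,
                     "p2_range": list(t.p2_range),
                     "allometric_exponent": t.allometric_exponent}
                    for t in self.model.terms
                ],
            },
            "posterior": self.posterior.tolist(),
            "subject_ids": [str(s) for s in self.subject_ids],
            "converged": self.converged,
            "n_blq_dropped": self.n_blq_dropped,
            "messages": self.messages,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "FitResult":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        model = ModelSpec(
            base_ranges={k: tuple(v) for k, v in payload["model"]["base_ranges"].items()},
            terms=tuple(
                CovariateTerm(
                    parameter=t["parameter"], covariate=t["covariate"], form=t["form"],
                    median=t["median"], p2_range=tuple(t["p2_range"]),
                    allometric_exponent=t["allometric_exponent"],
                )
                for t in payload["model"]["terms"]
            ),
            q=payload["model"]["q"],
            n_compartments=payload["model"]["n_compartments"],
        )
        dist = NPDistribution(
            theta=np.asarray(payload["support"], dtype=float),
            weights=np.asarray(payload["weights"], dtype=float),
            dim_names=list(payload["dim_names"]),
            ranges={k: tuple(v) for k, v in payload["ranges"].items()},
        )
        em = payload["error_model"]
        return cls(
            model=model,
            distribution=dist,
            error_model=ErrorModel(kind=em["kind"], noise=em["noise"], c0=em["c0"],
                                   c1=em["c1"], c2=em["c2"], c3=em["c3"]),
            loglik=payload["loglik"],
            aic=payload["aic"],
            gamma_hat=payload["gamma_hat"],
            pop_bias=payload["metrics"]["pop_bias"],
            pop_imprecision=payload["metrics"]["pop_imprecision"],
            ind_bias=payload["metrics"]["ind_bias"],
            ind_imprecision=payload["metrics"]["ind_imprecision"],
            posterior=np.asarray(payload["posterior"], dtype=float),
            subject_ids=list(payload["subject_ids"]),
            converged=payload["converged"],
            n_blq_dropped=payload["n_blq_dropped"],
            messages=list(payload["messages"]),
        )


def fit(dataset: PKDataset, model: ModelSpec, config: FitConfig | None = None,
        error_model: ErrorModel | None = None,
        init: NPDistribution | None = None) -> FitResult:
    """Full adaptive-grid fit: grid → (weights → prune → refine → noise) cycles.

    ``init`` supplies extra starting support points (e.g. the support of a
    previously fitted nested model during stepwise covariate selection);
    they are pooled with the Sobol grid before the first weight pass.
    """
    cfg = config or FitConfig()
    em0 = error_model or ErrorModel(kind="gamma", noise=cfg.noise_start)
    ws = _Workspace(dataset, model, em0, loq=cfg.loq, blq_strategy=cfg.blq_strategy)

    dist = initialize_grid(model.ranges, cfg.n_init, cfg.seed)
    if init is not None:
        names = dist.dim_names
        lows = np.array([dist.ranges[n][0] for n in names])
        highs = np.array([dist.ranges[n][1] for n in names])
        extra = np.clip(np.atleast_2d(init.theta), lows, highs)
        theta0 = np.vstack([dist.theta, extra])
        w0 = np.full(theta0.shape[0], 1.0 / theta0.shape[0])
        dist = NPDistribution(theta0, w0, names, dist.ranges)
    noise = cfg.noise_start if cfg.estimate_noise else em0.noise
    messages: list[str] = []
    ll = -np.inf
    converged_refine = False
    for _ in range(cfg.max_outer):
        dist, P, info = _refine(ws, dist, noise, cfg)
        converged_refine = info.converged
        ll_new = info.loglik
        if cfg.estimate_noise:
            noise, w, ll_new = _estimate_noise(
                ws, dist.theta, dist.weights, cfg.noise_bounds, noise, cfg
            )
            dist = NPDistribution(dist.theta, w / w.sum(), dist.dim_names, dist.ranges)
        if ll_new - ll < cfg.outer_tol:
            ll = max(ll, ll_new)
            break
        ll = ll_new
    if not converged_refine:
        messages.append("refinement reached max_refine_cycles before step tolerance")

    em_fit = em0.with_noise(noise)
    logL = ws.loglik_from_pred(ws.pred(dist.theta), noise)
    rowmax = logL.max(axis=1, keepdims=True)
    Lr = np.exp(logL - rowmax)
    post = Lr * dist.weights
    post /= post.sum(axis=1, keepdims=True)

    n_params = len(model.dim_names) + (1 if cfg.estimate_noise else 0)
    aic = -2.0 * ll + 2.0 * n_params

    pred_df = _predictions_from(ws, dist, post)
    metrics = fit_metrics(pred_df, em_fit)

    return FitResult(
        model=model,
        distribution=dist,
        error_model=em_fit,
        loglik=float(ll),
        aic=float(aic),
        gamma_hat=float(noise),
        pop_bias=metrics["pop_bias"],
        pop_imprecision=metrics["pop_imprecision"],
        ind_bias=metrics["ind_bias"],
        ind_imprecision=metrics["ind_imprecision"],
        posterior=post,
        subject_ids=ws.ids,
        converged=converged_refine,
        n_blq_dropped=ws.n_blq_dropped,
        messages=messages,
    )


# --------------------------------------------------------------------------
# Predictions, metrics, summaries
# --------------------------------------------------------------------------

def _predictions_from(ws: _Workspace, dist: NPDistribution,
                      posterior: np.ndarray) -> pd.DataFrame:
    P = ws.pred(dist.theta)  # (m, total_obs)
    pop = dist.weights @ P
    ind = np.empty(ws.n_obs)
    for i in range(ws.n_subjects):
        sl = slice(ws.offsets[i], ws.offsets[i + 1])
        ind[sl] = posterior[i] @ P[:, sl]
    rows = []
    for i, s in enumerate(ws.subjects):
        sl = slice(ws.offsets[i], ws.offsets[i + 1])
        for t, y, pp, ip in zip(s.obs_times, s.obs_values, pop[sl], ind[sl]):
            rows.append({"ID": s.id, "TIME": t, "DV": y,
                         "POP_PRED": pp, "IND_PRED": ip})
    return pd.DataFrame(rows)


def predictions(result: FitResult, dataset: PKDataset,
                config: FitConfig | None = None) -> pd.DataFrame:
    """Population (prior-weighted) and individual (posterior-weighted) predictions."""
    cfg = config or FitConfig()
    ws = _Workspace(dataset, result.model, result.error_model,
                    loq=cfg.loq, blq_strategy=cfg.blq_strategy)
    if ws.ids != result.subject_ids and [str(i) for i in ws.ids] != list(result.subject_ids):
        raise ValueError("dataset subjects do not match the fitted result")
    return _predictions_from(ws, result.distribution, result.posterior)


def fit_metrics(pred_df: pd.DataFrame, error_model: ErrorModel) -> dict:
    """Weighted bias and imprecision for population and individual predictions.

    e = (pred − obs)/SD(obs); bias = mean(e); imprecision = mean(e²) − bias².
    """
    obs = pred_df["DV"].to_numpy(dtype=float)
    sd = np.asarray(total_error_sd(obs, error_model))
    if np.any(sd <= 0):
        raise ValueError("zero or negative SD in metric weights")
    out = {}
    for kind, col in (("pop", "POP_PRED"), ("ind", "IND_PRED")):
        e = (pred_df[col].to_numpy(dtype=float) - obs) / sd
        bias = float(np.mean(e))
        out[f"{kind}_bias"] = bias
        out[f"{kind}_imprecision"] = float(np.mean(e**2) - bias**2)
    return out


def weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Smallest value whose cumulative weight reaches half the total."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    order = np.argsort(values)
    cw = np.cumsum(weights[order])
    k = int(np.searchsorted(cw, 0.5 * weights.sum() - 1e-12))
    return float(values[order][min(k, values.size - 1)])


@dataclass
class DistributionSummary:
    """Weighted medians, MAWD dispersion, optional bootstrap CIs per dimension."""

    medians: dict
    mawd: dict
    ci: dict | None = None  # name -> (lo, hi)

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for name in self.medians:
            row = {"parameter": name, "median": self.medians[name],
                   "mawd": self.mawd[name]}
            if self.ci is not None:
                row["ci_lo"], row["ci_hi"] = self.ci[name]
            rows.append(row)
        return pd.DataFrame(rows)


def summarize(dist: NPDistribution, n_boot: int = 200, seed: int = 0,
              dataset: PKDataset | None = None, model: ModelSpec | None = None,
              error_model: ErrorModel | None = None,
              config: FitConfig | None = None) -> DistributionSummary:
    """Per-parameter weighted median and MAWD; bootstrap CI when data given.

    The 95% CI resamples subjects with replacement and re-optimizes only the
    weights over the fixed support (a documented simplification of a full
    refit); without a dataset no CI is produced.
    """
    medians = {}
    mawd = {}
    for k, name in enumerate(dist.dim_names):
        med = weighted_median(dist.theta[:, k], dist.weights)
        medians[name] = med
        mawd[name] = weighted_median(np.abs(dist.theta[:, k] - med), dist.weights)
    ci = None
    if dataset is not None:
        if model is None or error_model is None:
            raise ValueError("bootstrap CI needs model and error_model")
        cfg = config or FitConfig()
        ws = _Workspace(dataset, model, error_model, loq=cfg.loq,
                        blq_strategy=cfg.blq_strategy)
        logL = ws.loglik_matrix(dist.theta, error_model.noise)
        rng = np.random.default_rng(seed)
        boots = {name: [] for name in dist.dim_names}
        for _ in range(n_boot):
            idx = rng.integers(0, ws.n_subjects, size=ws.n_subjects)
            w_b, _ = _em_weights(logL[idx], w0=dist.weights,
                                 tol=1e-6, max_iter=500)
            for k, name in enumerate(dist.dim_names):
                boots[name].append(weighted_median(dist.theta[:, k], w_b))
        ci = {}
        for name in dist.dim_names:
            lo, hi = np.percentile(boots[name], [2.5, 97.5])
            ci[name] = (min(lo, medians[name]), max(hi, medians[name]))
    return DistributionSummary(medians=medians, mawd=mawd, ci=ci)


# --------------------------------------------------------------------------
# Stepwise covariate selection
# --------------------------------------------------------------------------

def _embed_support(dist: NPDistribution, old_spec: ModelSpec,
                   new_spec: ModelSpec, n_levels: int = 5,
                   p1_scales: dict | None = None) -> NPDistribution:
    """Carry a fitted support into a neighboring model's parameter space.

    P1 columns are matched through the base parameter they belong to; a P2
    dimension present only in the new space is filled with ``n_levels``
    log-spaced levels across its range (each old point replicated per
    level); a P2 dimension that disappears is dropped.  ``p1_scales`` maps a
    new-space P1 dim name to multipliers (each old point replicated per
    multiplier) — used when a term without a shape dimension (e.g. linear)
    appears or disappears, where the typical value must be rescaled by the
    covariate factor at representative covariate quantiles.  Used to
    warm-start stepwise candidate fits so nested comparisons are not
    dominated by optimization noise.
    """
    old_layout = old_spec.dim_layout()
    new_layout = new_spec.dim_layout()
    old_names = dist.dim_names
    new_ranges = new_spec.ranges
    new_names = new_spec.dim_names

    cols = {}
    fill_dims = []
    for p in new_spec.base_params:
        cols[new_layout[p]["p1"]] = dist.theta[:, old_names.index(old_layout[p]["p1"])]
        old_p2 = old_layout[p]["p2"]
        for j, name in enumerate(new_layout[p]["p2"]):
            if j < len(old_p2):
                cols[name] = dist.theta[:, old_names.index(old_p2[j])]
            else:
                fill_dims.append(name)
    theta = np.column_stack([
        cols[n] if n in cols else np.zeros(dist.n_points) for n in new_names
    ])
    for name in fill_dims:
        lo, hi = new_ranges[name]
        levels = np.geomspace(lo, hi, n_levels) if lo > 0 else np.linspace(lo, hi, n_levels)
        k = new_names.index(name)
        reps = []
        for lev in levels:
            block = theta.copy()
            block[:, k] = lev
            reps.append(block)
        theta = np.vstack(reps)
    for name, mults in (p1_scales or {}).items():
        k = new_names.index(name)
        reps = []
        for m in np.atleast_1d(mults):
            block = theta.copy()
            block[:, k] = block[:, k] * m
            reps.append(block)
        theta = np.vstack(reps)
    lows = np.array([new_ranges[n][0] for n in new_names])
    highs = np.array([new_ranges[n][1] for n in new_names])
    theta = np.clip(theta, lows, highs)
    w = np.full(theta.shape[0], 1.0 / theta.shape[0])
    return NPDistribution(theta, w, list(new_names),
                          {n: tuple(new_ranges[n]) for n in new_names})


@dataclass
class SelectionResult:
    model: ModelSpec
    fit: FitResult
    included: list
    trace: pd.DataFrame


def covariate_search(dataset: PKDataset, base_model: ModelSpec,
                     candidates: list, config: FitConfig | None = None,
                     alpha: float = 0.05) -> SelectionResult:
    """Forward/backward stepwise covariate selection by likelihood-ratio χ².

    Forward: among candidate terms not yet included, add the one whose fit
    improves −2·loglik by more than the χ²(1−alpha) critical value with df =
    number of added support dimensions (floored at 1 — a linear term adds
    none); ties go to the larger AIC improvement.  Backward: remove any
    included term whose deletion worsens −2·loglik by less than the same
    threshold.  Candidates whose fit fails are skipped and logged.

    Each comparison that lands near the decision boundary is *stabilized*:
    the two models are alternately refit, each warm-started from the
    other's support, until neither improves.  Nonparametric fits carry
    optimization noise of a few log-likelihood units; without this the
    accept/reject decision at the χ² threshold would be dominated by which
    side happened to converge better rather than by the data.
    """
    cfg = config or FitConfig()
    current = base_model
    cur_fit = fit(dataset, current, cfg)
    included: list[CovariateTerm] = []
    rows = []

    cov_quantiles = {}
    subjects = dataset.subjects()

    def _factor_quantiles(term: CovariateTerm) -> np.ndarray:
        """Covariate factor (COV/COVmedian) at representative quantiles."""
        if term.covariate not in cov_quantiles:
            values = np.array([s.covariates[term.covariate] for s in subjects])
            cov_quantiles[term.covariate] = np.quantile(
                values, [0.1, 0.3, 0.5, 0.7, 0.9]
            )
        return cov_quantiles[term.covariate] / term.median

    def _scales(term: CovariateTerm, spec: ModelSpec) -> dict:
        """P1 rescaling levels when a term without a shape dimension is added.

        A linear term is not nested, so the richer model's typical value
        must start from the incumbent's value divided by the covariate
        factor at representative quantiles or its fit cannot reach the
        optimum from the warm start.
        """
        if term.has_p2:
            return {}
        q = _factor_quantiles(term)
        name = spec.dim_layout()[term.parameter]["p1"]
        return {name: 1.0 / q}

    def _df_of(term: CovariateTerm) -> int:
        return max(1, 1 if term.has_p2 else 0)

    def _warm(spec_to: ModelSpec, spec_from: ModelSpec, fit_from: FitResult,
              extra: NPDistribution | None = None,
              scales: dict | None = None) -> NPDistribution:
        init = _embed_support(fit_from.distribution, spec_from, spec_to,
                              p1_scales=scales)
        if extra is not None:
            theta = np.vstack([init.theta, extra.theta])
            init = NPDistribution(theta, np.full(theta.shape[0],
                                                 1.0 / theta.shape[0]),
                                  init.dim_names, init.ranges)
        return init

    def _stabilize(rich_spec: ModelSpec, rich_fit: FitResult,
                   poor_spec: ModelSpec, poor_fit: FitResult,
                   term: CovariateTerm, crit: float):
        """Ping-pong refits while the decision could still flip."""
        for _ in range(_STAB_ROUNDS):
            d2ll = 2.0 * (rich_fit.loglik - poor_fit.loglik)
            if d2ll - crit > _STAB_BAND:
                break  # significance robust to optimizer noise
            improved = False
            r = fit(dataset, rich_spec, cfg,
                    init=_warm(rich_spec, poor_spec, poor_fit,
                               extra=rich_fit.distribution,
                               scales=_scales(term, rich_spec)))
            if r.loglik > rich_fit.loglik + _STAB_TOL:
                rich_fit = r
                improved = True
            p = fit(dataset, poor_spec, cfg,
                    init=_warm(poor_spec, rich_spec, rich_fit,
                               extra=poor_fit.distribution))
            if p.loglik > poor_fit.loglik + _STAB_TOL:
                poor_fit = p
                improved = True
            if not improved:
                break
        return rich_fit, poor_fit

    def _skip_row(step: str, term: CovariateTerm, exc: Exception) -> None:
        rows.append({"step": step, "term": term.label(), "loglik": np.nan,
                     "aic": np.nan, "delta_m2ll": np.nan, "pop_bias": np.nan,
                     "pop_imprecision": np.nan, "selected": False,
                     "note": f"fit failed: {exc}"})

    improved = True
    while improved:
        improved = False
        best = None
        for term in candidates:
            if term in included:
                continue
            rich_spec = current.with_term(term)
            crit = chi2.ppf(1.0 - alpha, _df_of(term))
            try:
                trial = fit(dataset, rich_spec, cfg,
                            init=_warm(rich_spec, current, cur_fit,
                                       scales=_scales(term, rich_spec)))
                trial, new_cur = _stabilize(rich_spec, trial, current, cur_fit,
                                            term, crit)
            except Exception as exc:  # noqa: BLE001 — candidate skipped
                _skip_row("forward", term, exc)
                continue
            cur_fit = new_cur
            d2ll = 2.0 * (trial.loglik - cur_fit.loglik)
            rows.append({"step": "forward", "term": term.label(),
                         "loglik": trial.loglik, "aic": trial.aic,
                         "delta_m2ll": d2ll, "pop_bias": trial.pop_bias,
                         "pop_imprecision": trial.pop_imprecision,
                         "selected": False, "note": ""})
            if d2ll > crit:
                aic_gain = cur_fit.aic - trial.aic
                if best is None or aic_gain > best[0]:
                    best = (aic_gain, term, trial)
        if best is not None:
            _, term, trial = best
            current = current.with_term(term)
            cur_fit = trial
            included.append(term)
            rows[-_row_index(rows, term.label())]["selected"] = True
            improved = True

    removed = True
    while removed and included:
        removed = False
        for term in list(included):
            reduced = current.without_term(term)
            crit = chi2.ppf(1.0 - alpha, _df_of(term))
            try:
                trial = fit(dataset, reduced, cfg,
                            init=_warm(reduced, current, cur_fit))
                cur_fit, trial = _stabilize(current, cur_fit, reduced, trial,
                                            term, crit)
            except Exception as exc:  # noqa: BLE001 — removal skipped
                _skip_row("backward", term, exc)
                continue
            d2ll = 2.0 * (cur_fit.loglik - trial.loglik)
            drop = d2ll < crit
            rows.append({"step": "backward", "term": term.label(),
                         "loglik": trial.loglik, "aic": trial.aic,
                         "delta_m2ll": d2ll, "pop_bias": trial.pop_bias,
                         "pop_imprecision": trial.pop_imprecision,
                         "selected": drop, "note": "removed" if drop else "kept"})
            if drop:
                current = reduced
                cur_fit = trial
                included.remove(term)
                removed = True
                break

    return SelectionResult(model=current, fit=cur_fit, included=included,
                           trace=pd.DataFrame(rows))


def _row_index(rows: list, label: str) -> int:
    for k, row in enumerate(reversed(rows)):
        if row["term"] == label and row["step"] == "forward":
            return k + 1
    raise KeyError(label)
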