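"""Goodness-of-fit surfaces: observed-vs-predicted tables and visual
predictive checks (VPC).

The VPC is subject-level: for every subject in the dataset, ``n_sim``
parameter vectors are drawn from the population distribution (prior
weights), that subject's own dosing and sampling design is re-simulated
with residual noise, and observed and simulated concentrations are pooled
into time bins.  Bin edges are quantile-based (equal observation counts)
because sampling is heavily concentrated at the 1-h peak sample; equal-width
bins would leave most bins nearly empty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import PKDataset
from .npfit import FitResult, ModelSpec, NPDistribution, _Workspace
from .pk_model import ErrorModel, concentration_profile

__all__ = ["VPCResult", "vpc", "gof_tables"]

_PCTL = (5.0, 50.0, 95.0)


@dataclass
class VPCResult:
    """Percentiles of observed and simulated concentrations per time bin."""

    bin_edges: np.ndarray
    bin_centers: np.ndarray
    observed: np.ndarray   # (n_bins, 3): 5th/50th/95th
    simulated: np.ndarray  # (n_bins, 3)
    n_obs_per_bin: np.ndarray
    n_sim: int

    @property
    def n_bins(self) -> int:
        return self.bin_centers.size

    def coverage(self) -> float:
        """Fraction of bins whose observed median lies inside the simulated
        5th-95th percentile band."""
        ok = (self.observed[:, 1] >= self.simulated[:, 0]) & (
            self.observed[:, 1] <= self.simulated[:, 2]
        )
        return float(np.mean(ok))

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lo": self.bin_edges[:-1],
                "bin_hi": self.bin_edges[1:],
                "bin_center": self.bin_centers,
                "obs_p5": self.observed[:, 0],
                "obs_p50": self.observed[:, 1],
                "obs_p95": self.observed[:, 2],
                "sim_p5": self.simulated[:, 0],
                "sim_p50": self.simulated[:, 1],
                "sim_p95": self.simulated[:, 2],
                "n_obs": self.n_obs_per_bin,
            }
        )


def _unpack(fit, model, error_model):
    if isinstance(fit, FitResult):
        return fit.distribution, fit.model, fit.error_model
    if model is None or error_model is None:
        raise ValueError("passing a bare distribution requires model and error_model")
    return fit, model, error_model


def vpc(dataset: PKDataset, fit: FitResult | NPDistribution, n_sim: int = 1000,
        n_bins: int = 5, seed: int = 0, model: ModelSpec | None = None,
        error_model: ErrorModel | None = None) -> VPCResult:
    """Subject-level visual predictive check.

    Draws ``n_sim`` support vectors per subject, simulates that subject's
    design with residual noise (truncated at zero), pools observed and
    simulated concentrations into quantile time bins, and reports the
    5th/50th/95th percentiles of both pools per bin.  Bins that would hold
    fewer than two observations are merged with a neighbor.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    dist, model, em = _unpack(fit, model, error_model)
    rng = np.random.default_rng(seed)

    obs_t, obs_y = [], []
    sim_t, sim_y = [], []
    for subject in dataset.subjects():
        idx = rng.choice(dist.n_points, size=n_sim, p=dist.weights / dist.weights.sum())
        theta = dist.theta[idx]
        cl, v, vp, q = model.resolve(theta, subject.covariates)
        conc = concentration_profile(cl, v, vp, q, subject.doses, subject.obs_times)
        sd = em.c0 + em.c1 * conc + em.c2 * conc**2 + em.c3 * conc**3
        if em.kind == "gamma":
            sd = sd * em.noise
        else:
            sd = np.sqrt(sd**2 + em.noise**2)
        noisy = np.maximum(conc + rng.standard_normal(conc.shape) * sd, 0.0)
        obs_t.append(subject.obs_times)
        obs_y.append(subject.obs_values)
        sim_t.append(np.broadcast_to(subject.obs_times, conc.shape).ravel())
        sim_y.append(noisy.ravel())
    obs_t = np.concatenate(obs_t)
    obs_y = np.concatenate(obs_y)
    sim_t = np.concatenate(sim_t)
    sim_y = np.concatenate(sim_y)

    # quantile bin edges over observed times; with few distinct sampling
    # times (a sparse design) each distinct time gets its own bin
    distinct = np.unique(obs_t)
    if distinct.size <= n_bins:
        mid = 0.5 * (distinct[:-1] + distinct[1:])
        edges = np.concatenate([[distinct[0] - 0.5], mid, [distinct[-1] + 0.5]])
    else:
        qs = np.linspace(0.0, 100.0, n_bins + 1)
        edges = np.unique(np.percentile(obs_t, qs))
    if edges.size < 2:
        edges = np.array([obs_t.min() - 0.5, obs_t.max() + 0.5])
    edges = edges.astype(float)
    edges[0] -= 1e-9
    edges[-1] += 1e-9

    def bin_of(t):
        return np.clip(np.searchsorted(edges, t, side="right") - 1, 0,
                       edges.size - 2)

    obs_bin = bin_of(obs_t)
    # merge bins holding < 2 observations into their left neighbor
    counts = np.bincount(obs_bin, minlength=edges.size - 1)
    while edges.size > 2 and counts.min() < 2:
        k = int(np.argmin(counts))
        drop = k if k > 0 else 1
        edges = np.delete(edges, drop)
        obs_bin = bin_of(obs_t)
        counts = np.bincount(obs_bin, minlength=edges.size - 1)
    sim_bin = bin_of(sim_t)

    n_bins_eff = edges.size - 1
    observed = np.empty((n_bins_eff, 3))
    simulated = np.empty((n_bins_eff, 3))
    centers = np.empty(n_bins_eff)
    for b in range(n_bins_eff):
        observed[b] = np.percentile(obs_y[obs_bin == b], _PCTL)
        simulated[b] = np.percentile(sim_y[sim_bin == b], _PCTL)
        centers[b] = np.median(obs_t[obs_bin == b])
    return VPCResult(bin_edges=edges, bin_centers=centers, observed=observed,
                     simulated=simulated, n_obs_per_bin=counts, n_sim=n_sim)


def gof_tables(pred_df: pd.DataFrame, error_model: ErrorModel) -> dict:
    """Long-format diagnostic table plus obs~pred regression summaries.

    ``pred_df`` is the output of :func:`amikpk.npfit.predictions` (columns
    ID, TIME, DV, POP_PRED, IND_PRED).  Weighted residuals use the same
    (pred − obs)/SD(obs) convention as the fit metrics.
    """
    from .pk_model import total_error_sd

    obs = pred_df["DV"].to_numpy(dtype=float)
    sd = np.asarray(total_error_sd(obs, error_model))
    table = pred_df.copy()
    table["WRES_POP"] = (table["POP_PRED"] - obs) / sd
    table["WRES_IND"] = (table["IND_PRED"] - obs) / sd

    regression = {}
    for kind, col in (("pop", "POP_PRED"), ("ind", "IND_PRED")):
        pred = pred_df[col].to_numpy(dtype=float)
        slope, intercept = np.polyfit(pred, obs, 1)
        regression[kind] = {"slope": float(slope), "intercept": float(intercept)}
    return {"table": table, "regression": regression}
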