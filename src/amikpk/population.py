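"""Population parameter distributions for simulation.

Two samplers over the model's typical-value vector (CL1, CL2, V1, Vp):

* :class:`DiscreteSampler` — draws support points of a fitted nonparametric
  distribution by their probabilities.
* :class:`LogNormalSurrogate` — independent log-normal marginals standing in
  for an unpublished joint nonparametric distribution.  Each marginal's
  median is set to the reported population median and its log-scale sigma is
  solved numerically so the marginal's median absolute deviation (MAD about
  the median) equals the reported MAWD dispersion.  The independence
  assumption is an approximation; see docs/methods.md.

``AMIKACIN_MEDIANS`` / ``AMIKACIN_MAWD`` hold the published amikacin
population estimates used as defaults throughout (CL1 L/h, CL2
dimensionless, V1 L, Vp L; Q fixed at 5.43 L/h).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from .pk_model import Q_FIXED

__all__ = [
    "PARAM_NAMES",
    "AMIKACIN_MEDIANS",
    "AMIKACIN_MAWD",
    "lognormal_sigma_from_mad",
    "LogNormalSurrogate",
    "DiscreteSampler",
]

PARAM_NAMES = ("CL1", "CL2", "V1", "Vp")

#: Published population weighted medians (CL1 L/h, CL2 -, V1 L, Vp L).
AMIKACIN_MEDIANS = {"CL1": 4.41, "CL2": 0.72, "V1": 20.40, "Vp": 16.32}
#: Published MAWD dispersion of the same parameters.
AMIKACIN_MAWD = {"CL1": 1.24, "CL2": 0.29, "V1": 5.45, "Vp": 7.20}


def _mad_ratio(sigma: float) -> float:
    """median(|X/median − 1|) for X log-normal with log-scale ``sigma``."""

    def cdf_gap(t: float) -> float:
        return (
            norm.cdf(np.log1p(t) / sigma)
            - norm.cdf(np.log1p(-t) / sigma)
            - 0.5
        )

    return brentq(cdf_gap, 1e-12, 1.0 - 1e-12, xtol=1e-12)


def lognormal_sigma_from_mad(median: float, mad: float) -> float:
    """Log-scale sigma of a log-normal with given median and MAD about it.

    Solves median(|X − median|) = mad for sigma; requires mad < median
    (the MAD of a log-normal about its median is below the median).
    """
    if median <= 0 or mad <= 0:
        raise ValueError("median and mad must be strictly positive")
    r = mad / median
    if r >= 1.0:
        raise ValueError("mad must be smaller than the median for a log-normal")
    return brentq(lambda s: _mad_ratio(s) - r, 1e-8, 10.0, xtol=1e-10)


@dataclass
class LogNormalSurrogate:
    """Independent log-normal marginals matched to medians and MAWD."""

    medians: dict
    mawd: dict
    q: float = Q_FIXED

    def __post_init__(self):
        self.sigmas = {
            k: lognormal_sigma_from_mad(self.medians[k], self.mawd[k])
            for k in PARAM_NAMES
        }

    @classmethod
    def amikacin_default(cls) -> "LogNormalSurrogate":
        return cls(medians=dict(AMIKACIN_MEDIANS), mawd=dict(AMIKACIN_MAWD))

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """(n, 4) array of (CL1, CL2, V1, Vp) draws."""
        cols = [
            self.medians[k] * np.exp(self.sigmas[k] * rng.standard_normal(n))
            for k in PARAM_NAMES
        ]
        return np.column_stack(cols)


@dataclass
class DiscreteSampler:
    """Sampler over the support points of a discrete population distribution."""

    theta: np.ndarray  # (n_points, 4) in PARAM_NAMES order
    weights: np.ndarray
    q: float = Q_FIXED

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.theta.ndim != 2 or self.theta.shape[0] != self.weights.size:
            raise ValueError("theta and weights shapes do not match")
        if abs(self.weights.sum() - 1.0) > 1e-6:
            raise ValueError("weights must sum to 1")

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        idx = rng.choice(self.theta.shape[0], size=n, p=self.weights / self.weights.sum())
        return self.theta[idx]
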