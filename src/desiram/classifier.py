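"""Bayesian identification of the stimulating chemical.

Given a blind characteristic vector {y_i} and the learned model functions
f(x|s,i) with residual scales sigma_{s,i}, the posterior over chemical
identity s marginalises the unknown concentration x:

    p(s | {y}) propto  Integral  prod_i A(s,i) exp(-(y_i - f(x|s,i))^2
                                                   / (2 sigma_{s,i}^2))  dx

with a uniform prior over chemicals.  The integral is evaluated by
trapezoidal quadrature on a uniform grid in u = log10 x spanning the
chemical's training range padded by half a log-unit; the prior measure over
concentration (uniform in log x, or uniform in x) is configurable.  All
products are accumulated in the log domain and combined with log-sum-exp,
so 15-factor likelihoods that underflow doubles remain exact to rounding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .concentration import ModelSet
from .exceptions import BadConfigError, DesiramError, InvalidDataError
from .template import N_INDICES, CharacteristicVector

_LOG10 = np.log(10.0)


@dataclass
class ClassifierConfig:
    """Quadrature and prior settings for the posterior computation.

    ``grid_points`` quadrature nodes span ``[log10 x_lo - pad,
    log10 x_hi + pad]`` per chemical; ``amplitude_mode`` chooses whether the
    per-index factor carries the Gaussian normalisation 1/(sqrt(2 pi) sigma)
    (``gaussian``) or not (``unit``); ``prior_measure`` integrates the
    nuisance concentration uniformly in log10 x or in x; ``active_indices``
    restricts the likelihood to a subset of the 15 indices (1-based).
    """

    grid_points: int = 4001
    pad: float = 0.5
    amplitude_mode: str = "gaussian"
    prior_measure: str = "log_uniform"
    active_indices: tuple = tuple(range(1, N_INDICES + 1))

    def __post_init__(self):
        if self.grid_points < 2:
            raise BadConfigError("grid_points must be >= 2")
        if self.amplitude_mode not in ("gaussian", "unit"):
            raise BadConfigError(f"unknown amplitude_mode {self.amplitude_mode!r}")
        if self.prior_measure not in ("log_uniform", "linear_uniform"):
            raise BadConfigError(f"unknown prior_measure {self.prior_measure!r}")
        idx = tuple(self.active_indices)
        if not idx:
            raise BadConfigError("active_indices must not be empty")
        if any(not (1 <= i <= N_INDICES) for i in idx):
            raise BadConfigError(f"active_indices must lie in 1..{N_INDICES}")
        self.active_indices = idx


@dataclass
class ConcentrationProfile:
    """Per-chemical marginalisation profile: grid and unnormalised integrand."""

    x_grid: np.ndarray
    log_integrand: np.ndarray

    @property
    def map_concentration(self) -> float:
        return float(self.x_grid[int(np.argmax(self.log_integrand))])


@dataclass
class PosteriorResult:
    """Posterior over chemicals for one blind vector."""

    chemicals: list
    probabilities: np.ndarray
    log_evidence: np.ndarray
    profiles: dict  # chemical -> ConcentrationProfile
    tie: bool = False

    def __post_init__(self):
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if abs(self.probabilities.sum() - 1.0) > 1e-12:
            raise InvalidDataError("posterior probabilities must sum to 1")
        if (self.probabilities < 0).any():
            raise InvalidDataError("posterior probabilities must be non-negative")

    @property
    def decision(self) -> str:
        """Argmax chemical; ties resolved to the first label in model order."""
        return self.chemicals[int(np.argmax(self.probabilities))]

    @property
    def map_concentration(self) -> dict:
        return {s: p.map_concentration for s, p in self.profiles.items()}

    def probability(self, chemical: str) -> float:
        return float(self.probabilities[self.chemicals.index(chemical)])


def _log_integrand(vector, models, chemical, u_grid, cfg) -> np.ndarray:
    """Log of prod_i A(s,i) exp(-(y_i - f(u))^2 / 2 sigma^2) on the u grid."""
    total = np.zeros(u_grid.size)
    for i in cfg.active_indices:
        f = models.function(chemical, i)
        pred = f.predict_u(u_grid)
        total += -((vector.y[i - 1] - pred) ** 2) / (2.0 * f.sigma**2)
        if cfg.amplitude_mode == "gaussian":
            total += np.log(f.amplitude)
    return total


def _log_trapz_weights(u_grid: np.ndarray, prior_measure: str) -> np.ndarray:
    """Log trapezoid weights for integrating over the nuisance concentration.

    log_uniform integrates du; linear_uniform integrates dx = x ln10 du,
    folded into the weights so the integrand itself is measure-free.
    """
    n = u_grid.size
    du = u_grid[1] - u_grid[0]
    w = np.full(n, du)
    w[0] = w[-1] = du / 2.0
    if prior_measure == "linear_uniform":
        w = w * np.power(10.0, u_grid) * _LOG10
    return np.log(w)


def posterior(
    vector: CharacteristicVector,
    models: ModelSet,
    config: ClassifierConfig | None = None,
) -> PosteriorResult:
    """Posterior over chemical identity with the concentration marginalised."""
    cfg = config or ClassifierConfig()
    if not np.isfinite(vector.y).all():
        raise InvalidDataError("characteristic vector contains non-finite indices")

    log_ev = np.empty(len(models.chemicals))
    profiles = {}
    for k, s in enumerate(models.chemicals):
        x_lo, x_hi = models.conc_range(s)
        u = np.linspace(
            np.log10(x_lo) - cfg.pad, np.log10(x_hi) + cfg.pad, cfg.grid_points
        )
        li = _log_integrand(vector, models, s, u, cfg)
        log_ev[k] = logsumexp(li + _log_trapz_weights(u, cfg.prior_measure))
        profiles[s] = ConcentrationProfile(x_grid=np.power(10.0, u), log_integrand=li)

    if not np.isfinite(log_ev).any():
        raise DesiramError(
            "all chemical evidences underflow even in the log domain; "
            f"log-evidences: {dict(zip(models.chemicals, log_ev))}"
        )
    # Uniform prior over chemicals: normalise the evidences.
    log_post = log_ev - logsumexp(log_ev)
    probs = np.exp(log_post)
    probs = probs / probs.sum()

    best = probs.max()
    tie = int(np.sum(np.isclose(probs, best, rtol=0, atol=1e-12))) > 1
    return PosteriorResult(
        chemicals=list(models.chemicals),
        probabilities=probs,
        log_evidence=log_ev,
        profiles=profiles,
        tie=tie,
    )


def classify(
    vector: CharacteristicVector,
    models: ModelSet,
    config: ClassifierConfig | None = None,
) -> str:
    """Maximum-posterior chemical label (ties go to the first model label)."""
    return posterior(vector, models, config).decision


def estimate_concentration(
    vector: CharacteristicVector,
    models: ModelSet,
    chemical: str,
    config: ClassifierConfig | None = None,
) -> float:
    """MAP concentration (mM) of the vector assuming the given chemical."""
    cfg = config or ClassifierConfig()
    if chemical not in models.chemicals:
        raise BadConfigError(f"unknown chemical {chemical!r}")
    res = posterior(vector, models, cfg)
    return res.profiles[chemical].map_concentration
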