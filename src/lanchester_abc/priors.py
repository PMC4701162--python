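"""Priors over hyperparameters and the per-battle stochastic odds ratio.

A fixed odds ratio ``P`` across hundreds of battles would ignore any
engagement-to-engagement variation in relative fighting value, so ``P``
is drawn fresh for every battle from a gamma distribution.  For
interpretability the gamma is parameterised by its mean ``mu`` and
standard deviation ``sigma``::

    kappa = (mu / sigma) ** 2        (shape)
    theta = sigma ** 2 / mu          (scale)

``mu`` and ``sigma`` carry uniform U(0, 5) priors by default.

Reproducibility contract: every consumer of randomness derives an
independent named substream from one root seed, so changing how one
consumer draws cannot shift another consumer's stream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PriorConfig",
    "HyperDraw",
    "DEGENERACY_EPS",
    "gamma_from_moments",
    "sample_hyperparams",
    "sample_odds_ratio",
    "substream",
]

#: draws of mu below this are resampled and sigma below it is treated as
#: exactly zero (deterministic P = mu); boundary handling for the U(0,5)
#: prior where the gamma reparameterization is undefined.
DEGENERACY_EPS = 1e-6

# fixed tags keeping named consumers on disjoint streams
STREAM_HYPER = 101
STREAM_BATTLE_P = 102
STREAM_SYNTH = 103


def substream(root_seed: int, *tags: int) -> np.random.Generator:
    """Independent generator for a named consumer under one root seed."""
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence((root_seed, *tags))))


@dataclass(frozen=True)
class PriorConfig:
    """Bounds of the independent uniform priors on mu and sigma."""

    mu_low: float = 0.0
    mu_high: float = 5.0
    sigma_low: float = 0.0
    sigma_high: float = 5.0

    def __post_init__(self) -> None:
        if not (0 <= self.mu_low < self.mu_high):
            raise ValueError("require 0 <= mu_low < mu_high")
        if not (0 <= self.sigma_low < self.sigma_high):
            raise ValueError("require 0 <= sigma_low < sigma_high")


@dataclass(frozen=True)
class HyperDraw:
    """One (mu, sigma) pair with the derived gamma shape/scale attached.

    ``kappa`` and ``theta`` are None when sigma is degenerate (the
    odds ratio is then deterministic at mu).
    """

    mu: float
    sigma: float
    kappa: "float | None"
    theta: "float | None"

    @classmethod
    def from_moments(cls, mu: float, sigma: float) -> "HyperDraw":
        if sigma < DEGENERACY_EPS:
            return cls(mu=mu, sigma=sigma, kappa=None, theta=None)
        kappa, theta = gamma_from_moments(mu, sigma)
        return cls(mu=mu, sigma=sigma, kappa=kappa, theta=theta)

    @property
    def degenerate(self) -> bool:
        return self.kappa is None


def gamma_from_moments(mu: float, sigma: float) -> tuple[float, float]:
    """Gamma (shape, scale) with mean ``mu`` and standard deviation ``sigma``."""
    if mu <= 0:
        raise ValueError("mu must be positive")
    if sigma <= 0:
        raise ValueError("sigma must be positive (degenerate sigma is handled upstream)")
    return (mu / sigma) ** 2, sigma**2 / mu


def sample_hyperparams(prior: PriorConfig, rng: np.random.Generator) -> HyperDraw:
    """Draw (mu, sigma) from the uniform priors.

    mu draws below the degeneracy threshold are resampled (mu = 0 gives
    an undefined gamma and a physically meaningless odds ratio); sigma
    draws below it route to the deterministic P = mu branch.
    """
    mu = rng.uniform(prior.mu_low, prior.mu_high)
    while mu < DEGENERACY_EPS:
        mu = rng.uniform(prior.mu_low, prior.mu_high)
    sigma = rng.uniform(prior.sigma_low, prior.sigma_high)
    return HyperDraw.from_moments(mu, sigma)


def sample_odds_ratio(h: HyperDraw, rng: np.random.Generator, size=None):
    """Per-battle odds ratio(s) ``P ~ Gamma(kappa, theta)``.

    With a degenerate sigma every draw is exactly mu.  ``size`` follows
    numpy semantics (None returns a scalar).
    """
    if h.degenerate:
        return h.mu if size is None else np.full(size, h.mu)
    draws = rng.gamma(h.kappa, h.theta, size=size)
    # a gamma variate is a.s. positive; draws at very small shape can
    # underflow to exactly 0.0, so floor at the smallest normal float
    return np.maximum(draws, np.finfo(float).tiny)
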