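"""Phenotype generators on top of simulated genotypes.

Binary traits follow a logistic model

    logit P(y_i = 1) = b0 + b1 * s_i + sum_j G_ij * c_j,

with a stratum indicator s_i for population-stratification studies and
per-variant log-odds effects c_j. The conventional rare-variant effect-size
rule beta = (ln 5 / 4) * |log10 MAF| ties effect sizes to allele rarity.

Time-to-event traits follow a Weibull proportional-hazards model with a
family-correlated log-normal frailty:

    lambda_i(t | b) = (rho/lam) (t/lam)^(rho-1) * exp(b_i + x_i' beta),
    b ~ MVN(0, sigma2 * B)  per family,

where B is the IBD-derived relationship matrix of the family. Right-censoring
uses each individual's current age, drawn per generation from a normal
distribution (defaults: means 95/75/55 for generations 1/2/3, variance 2.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit

DEFAULT_CENSOR_MEANS = (95.0, 75.0, 55.0)
DEFAULT_CENSOR_VAR = 2.5
RIDGE = 1e-8


def effect_from_maf(maf) -> np.ndarray | float:
    """Log-odds (or log-hazard) effect (ln5/4)*|log10 MAF| of a variant."""
    maf = np.asarray(maf, dtype=float)
    if np.any(maf <= 0):
        raise ValueError("MAF must be positive")
    out = (np.log(5.0) / 4.0) * np.abs(np.log10(maf))
    return float(out) if out.ndim == 0 else out


@dataclass
class BinaryTraitModel:
    """Logistic disease model with optional stratum effect."""

    b0: float = 0.0
    b1: float = 0.0
    c: np.ndarray = field(default_factory=lambda: np.zeros(0))
    causal_set: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))

    def __post_init__(self) -> None:
        self.c = np.atleast_1d(np.asarray(self.c, dtype=float))
        self.causal_set = np.atleast_1d(np.asarray(self.causal_set, dtype=int))
        if len(self.c) != len(self.causal_set):
            raise ValueError("one effect per causal variant required")

    def linear_predictor(self, G: np.ndarray, strata=None) -> np.ndarray:
        G = np.asarray(G)
        eta = np.full(G.shape[0], self.b0, dtype=float)
        if strata is not None:
            eta += self.b1 * np.asarray(strata, dtype=float)
        if len(self.causal_set):
            eta += G[:, self.causal_set] @ self.c
        return eta


def simulate_binary(
    model: BinaryTraitModel,
    G: np.ndarray,
    rng: np.random.Generator,
    strata=None,
) -> np.ndarray:
    """Bernoulli outcomes from the logistic model given dosages G (N, M)."""
    prob = expit(model.linear_predictor(G, strata))
    return (rng.random(len(prob)) < prob).astype(np.int8)


@dataclass
class SurvivalTraitModel:
    """Weibull baseline + correlated frailty survival generator settings."""

    rho_w: float = 3.0
    lambda_w: float = 143.0
    beta: np.ndarray = field(default_factory=lambda: np.asarray([0.5]))
    sigma2: float = 0.0
    censor_age_means: Sequence[float] = DEFAULT_CENSOR_MEANS
    censor_age_var: float = DEFAULT_CENSOR_VAR

    def __post_init__(self) -> None:
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        if self.rho_w <= 0 or self.lambda_w <= 0 or self.sigma2 < 0:
            raise ValueError("need rho > 0, lambda > 0, sigma2 >= 0")


def _draw_frailty(
    model: SurvivalTraitModel,
    n: int,
    family_blocks: Optional[Sequence[Sequence[int]]],
    B_blocks: Optional[Sequence[np.ndarray]],
    rng: np.random.Generator,
) -> np.ndarray:
    b = np.zeros(n)
    if model.sigma2 == 0 or family_blocks is None:
        if model.sigma2 > 0:
            b = rng.normal(0.0, np.sqrt(model.sigma2), n)
        return b
    for members, B in zip(family_blocks, B_blocks):
        members = np.asarray(members, dtype=int)
        cov = model.sigma2 * (np.asarray(B) + RIDGE * np.eye(len(members)))
        L = np.linalg.cholesky(cov)
        b[members] = L @ rng.standard_normal(len(members))
    return b


def simulate_survival(
    model: SurvivalTraitModel,
    X: np.ndarray,
    generation: np.ndarray,
    rng: np.random.Generator,
    family_blocks: Optional[Sequence[Sequence[int]]] = None,
    B_blocks: Optional[Sequence[np.ndarray]] = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Generate (observed time, event status, censoring age).

    Latent event times come from Weibull inversion
    ``T = lam * (-log U / exp(b + X beta))**(1/rho)``; each individual is
    right-censored at a current age drawn from
    ``Normal(censor_age_means[generation-1], censor_age_var)`` (truncated at
    zero). ``status`` is 1 when the event precedes the censoring age and the
    observed time is ``min(T, age)``.

    ``family_blocks``/``B_blocks`` give, per family, member row indices into X
    and the matching IBD relationship matrix; omit them (or set sigma2=0) for
    independent individuals.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if X.shape[1] != len(model.beta):
        raise ValueError("X and beta dimensions disagree")
    generation = np.asarray(generation, dtype=int)
    if len(generation) != n:
        raise ValueError("generation labels must match X rows")

    b = _draw_frailty(model, n, family_blocks, B_blocks, rng)
    eta = X @ model.beta + b
    U = rng.uniform(size=n)
    T = model.lambda_w * (-np.log(U) / np.exp(eta)) ** (1.0 / model.rho_w)

    means = np.asarray(model.censor_age_means, dtype=float)[generation - 1]
    age = rng.normal(means, np.sqrt(model.censor_age_var))
    age = np.clip(age, 0.0, None)

    status = (T <= age).astype(np.int8)
    time = np.minimum(T, age)
    return time, status, age
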