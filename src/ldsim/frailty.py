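"""Weibull correlated-frailty model and the boundary likelihood-ratio test.

Families share log-normal frailties ``b_f ~ MVN(0, sigma2 * B_f)`` where
``B_f`` is the family's IBD relationship matrix over the tested region; the
conditional hazard is Weibull proportional hazards,

    lambda_i(t | b) = (rho/lam) (t/lam)^(rho-1) exp(b_i + x_i' beta).

The marginal log-likelihood integrates the family random effects out by a
Laplace approximation around the joint-density mode (exact when sigma2 = 0).
Association between a variant region and survival is tested by the
likelihood-ratio statistic for sigma2 = 0, whose null distribution is the
equal mixture of a point mass at zero and chi-square with 1 df, so

    p = 1                      if LRT = 0,
    p = 0.5 * P(chi2_1 >= LRT) otherwise.

The inner Newton mode-finding is written so that sigma2 -> 0 is numerically
stable: steps use ``delta = Sigma (I + D Sigma)^{-1} grad`` and the Laplace
determinant is ``logdet(I + Sigma D)``, neither of which inverts Sigma.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import chi2

from .haplotype import HaplotypeModel, HaplotypePool
from .meiosis import RecombinationParams, mate
from .pedigree import compute_pair_ibd12, founder_from_pool
from .phenotype import SurvivalTraitModel, simulate_survival

RIDGE = 1e-8
INNER_MAX_ITER = 100
SIGMA2_SMALL = 1e-10  # below this the exact sigma2=0 likelihood is used


@dataclass
class FrailtyFitResult:
    """Maximum-likelihood estimates for the correlated-frailty Weibull model."""

    rho_hat: float
    lambda_hat: float
    beta_hat: np.ndarray
    sigma2_hat: float
    loglik: float
    converged: bool
    n_families: int


@dataclass
class LRTResult:
    """Boundary LRT for sigma2 = 0 with the 0.5*chi2_0 + 0.5*chi2_1 null."""

    statistic: float
    p_value: float


@dataclass
class FrailtyData:
    """Per-family survival data: times, statuses, covariates, IBD matrix B."""

    times: list[np.ndarray]
    status: list[np.ndarray]
    X: list[np.ndarray]
    B: list[np.ndarray]

    def __post_init__(self) -> None:
        if not (len(self.times) == len(self.status) == len(self.X) == len(self.B)):
            raise ValueError("per-family lists must have equal length")

    @property
    def n_families(self) -> int:
        return len(self.times)


class _PackedData:
    """Families padded to a common size and stacked for batched linalgebra.

    Padding members carry t = 0, d = 0, X = 0 and an identity B block, which
    makes their likelihood, mode and Laplace-correction contributions exactly
    zero — one batched solve then covers every family per Newton iteration.
    """

    def __init__(self, data: FrailtyData):
        self.n_events = sum(int(np.sum(d)) for d in data.status)
        F = data.n_families
        s = max(len(t) for t in data.times)
        p = np.atleast_2d(data.X[0]).shape[1]
        t = np.zeros((F, s))
        d = np.zeros((F, s))
        X = np.zeros((F, s, p))
        B = np.zeros((F, s, s))
        B[:] = np.eye(s)
        for f in range(F):
            n = len(data.times[f])
            t[f, :n] = data.times[f]
            d[f, :n] = data.status[f]
            X[f, :n] = np.atleast_2d(data.X[f])
            B[f, :n, :n] = data.B[f]
        B += RIDGE * np.eye(s)
        self.groups = [(s, t, d, X, B)]


def _group_loglik_laplace(t, d, X, B, log_rho, log_lam, beta, sigma2):
    """Laplace marginal log-likelihood, vectorized over a (F, s) family group.

    The inner Newton always starts from b = 0 and maintains the pair
    ``(b, w)`` with ``w = B^{-1} b`` incrementally (never via inversion),
    which keeps the iteration stable even when B is near-singular — IBD2 = 1
    relative pairs produce duplicate rows in B. Cold starts make the
    returned value a smooth, deterministic function of the parameters, which
    the outer optimizer differentiates by finite differences.
    """
    rho, lam = np.exp(log_rho), np.exp(log_lam)
    with np.errstate(divide="ignore"):
        logz = np.log(t / lam)  # -inf on padded (t = 0) entries
    eta = X @ beta
    log_h0 = np.log(rho / lam) + (rho - 1.0) * logz
    mu0 = np.exp(rho * logz + eta)  # cumulative hazard, 0 on padded entries
    base = np.where(d > 0, d * (log_h0 + eta), 0.0)
    if not np.all(np.isfinite(mu0)):
        return -np.inf

    if sigma2 <= SIGMA2_SMALL:
        return float(np.sum(base - mu0))

    F, s = t.shape
    Sigma = sigma2 * B  # (F, s, s)
    eye = np.eye(s)
    log_mu0 = rho * logz + eta  # -inf on padded entries: mu stays 0, b stays 0
    b = np.zeros((F, s))
    w = np.zeros((F, s))  # w = B^{-1} b by construction of the updates

    def _mu(bv):
        return np.exp(np.clip(log_mu0 + bv, None, 300.0))

    def joint(bv, wv):
        # -0.5 b' Sigma^{-1} b = -0.5 b.w / sigma2, exact since w = B^{-1} b
        return (np.sum(base + d * bv - _mu(bv), axis=1)
                - 0.5 * np.sum(bv * wv, axis=1) / sigma2)

    # Damped Newton with Newton-decrement convergence. The joint log-density
    # is strictly concave in b, so the mode is unique; converging every
    # family to decrement < 1e-11 makes the returned value deterministic to
    # ~1e-10 regardless of the starting point (important: the outer optimizer
    # differentiates this value by finite differences).
    obj = joint(b, w)
    for _ in range(INNER_MAX_ITER):
        mu = _mu(b)
        grad = d - mu - w / sigma2
        A = eye + Sigma * mu[:, None, :]  # I + Sigma diag(mu)
        x = np.linalg.solve(A, grad[..., None])[..., 0]
        db = np.einsum("fij,fj->fi", Sigma, x)
        dec = 0.5 * np.sum(grad * db, axis=1)  # Newton decrement^2 / 2, >= 0
        active = dec > 1e-11
        if not np.any(active):
            break
        step = np.where(active, 1.0, 0.0)[:, None]
        for _ in range(30):  # Armijo backtracking on the active families
            b_new = b + step * db
            w_new = w + step * (sigma2 * x)  # keeps w = B^{-1} b exactly
            obj_new = joint(b_new, w_new)
            bad = active & ~(obj_new >= obj + 0.1 * step[:, 0] * dec)
            if not np.any(bad):
                break
            step[bad] *= 0.5
        ok = (obj_new >= obj) & active
        b = np.where(ok[:, None], b_new, b)
        w = np.where(ok[:, None], w_new, w)
        obj = np.where(ok, obj_new, obj)
        if not np.any(ok):
            break  # no family can improve at machine precision

    mu = _mu(b)
    A = np.eye(s) + Sigma * mu[:, None, :]
    _, logdet = np.linalg.slogdet(A)

    # Higher-order Laplace term. The conditional log-density has diagonal
    # third and fourth b-derivatives (both -mu_i), so with V = (K + D)^{-1}
    # the next-order factor is closed form:
    #   C = (1/8) sum_i t4_i V_ii^2 + (1/8) u' V u + (1/12) sum_ij a_i a_j V_ij^3
    # with a_i = t4_i = -mu_i and u_i = a_i V_ii.
    V = np.linalg.solve(A, Sigma)
    a = -mu
    Vii = np.diagonal(V, axis1=1, axis2=2)
    u = a * Vii
    c1 = 0.125 * np.sum(a * Vii**2, axis=1)
    c2 = 0.125 * np.einsum("fi,fij,fj->f", u, V, u)
    c3 = np.einsum("fi,fij,fj->f", a, V**3, a) / 12.0
    corr = np.log1p(np.clip(c1 + c2 + c3, -0.9, None))
    return float(np.sum(obj - 0.5 * logdet + corr))


def family_loglik(
    t, d, X, B_f, rho: float, lam: float, beta, sigma2: float
) -> float:
    """Marginal log-likelihood contribution of a single family.

    Exact when ``sigma2 = 0``; otherwise Laplace-approximated around the mode
    of the joint log-density (inner Newton to 1e-10 gradient norm).
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    d = np.atleast_1d(np.asarray(d, dtype=float))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    B_f = np.atleast_2d(np.asarray(B_f, dtype=float))
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    if rho <= 0 or lam <= 0 or sigma2 < 0:
        raise ValueError("need rho > 0, lam > 0, sigma2 >= 0")
    w = np.linalg.eigvalsh(B_f)
    if w.min() < -1e-8:
        raise ValueError("family relationship matrix B is not PSD")
    return _group_loglik_laplace(
        t[None, :], d[None, :], X[None, :, :], B_f[None, :, :] + RIDGE * np.eye(len(t)),
        np.log(rho), np.log(lam), beta, sigma2,
    )


def _total_loglik(packed: _PackedData, log_rho, log_lam, beta, sigma2) -> float:
    return sum(
        _group_loglik_laplace(t, d, X, B, log_rho, log_lam, beta, sigma2)
        for _, t, d, X, B in packed.groups
    )


def fit(
    data: FrailtyData,
    null: bool,
    beta_init: Optional[np.ndarray] = None,
    start: Optional[dict] = None,
) -> FrailtyFitResult:
    """Maximize the marginal likelihood over (rho, lam, beta[, sigma2]).

    Positive parameters are log-transformed; ``sigma2`` (alternative fit
    only) is box-constrained to [0, 50] so boundary solutions sigma2 = 0 are
    admissible. Optimizer failure is reported through ``converged``, never
    raised silently.
    """
    if data.n_families < 2:
        raise ValueError("need at least two families")
    packed = _PackedData(data)
    if packed.n_events == 0:
        raise ValueError("all observations are censored; model is unidentifiable")
    p = np.atleast_2d(data.X[0]).shape[1]

    t_all = np.concatenate([np.atleast_1d(t) for t in data.times])
    start = start or {}
    x0 = [
        start.get("log_rho", 0.0),
        start.get("log_lam", float(np.log(np.mean(t_all)))),
    ]
    x0 += list(start.get("beta", beta_init if beta_init is not None else np.zeros(p)))
    bounds = [(-4.0, 4.0), (-5.0, 20.0)] + [(None, None)] * p
    if not null:
        x0.append(start.get("sigma2", 0.2))
        bounds.append((0.0, 50.0))

    def negloglik(theta):
        sigma2 = theta[2 + p] if not null else 0.0
        val = -_total_loglik(packed, theta[0], theta[1], theta[2 : 2 + p], sigma2)
        return val if np.isfinite(val) else 1e12

    res = optimize.minimize(
        negloglik, np.asarray(x0, dtype=float), method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 120, "maxfun": 400, "ftol": 1e-10, "gtol": 1e-6,
                 "eps": 1e-6},
    )
    theta = res.x
    return FrailtyFitResult(
        rho_hat=float(np.exp(theta[0])),
        lambda_hat=float(np.exp(theta[1])),
        beta_hat=theta[2 : 2 + p].copy(),
        sigma2_hat=0.0 if null else float(theta[2 + p]),
        loglik=float(-res.fun),
        converged=bool(res.success),
        n_families=data.n_families,
    )


def lrt_pvalue(statistic: float) -> float:
    """P-value under the 0.5*chi2_0 + 0.5*chi2_1 boundary mixture."""
    if statistic < 0:
        raise ValueError("LRT statistic must be non-negative")
    if statistic == 0:
        return 1.0
    return float(0.5 * chi2.sf(statistic, df=1))


def lrt(null_fit: FrailtyFitResult, alt_fit: FrailtyFitResult) -> LRTResult:
    """Boundary LRT of sigma2 = 0 from nested null/alternative fits."""
    stat = max(0.0, 2.0 * (alt_fit.loglik - null_fit.loglik))
    return LRTResult(statistic=stat, p_value=lrt_pvalue(stat))


# --------------------------------------------------------------------------
# Table-4-style simulation study: three-generation families, genotype-driven
# hazards, IBD-based variance-component test.
# --------------------------------------------------------------------------


@dataclass
class StudyConfig:
    """One Table-4-style study grid.

    Families are three generations: two parents, 1-2 children, and 1-2
    grandchildren per child; married-in spouses are simulated founders used
    for mating only. ``beta_g`` values are shared log-hazard effects of
    ``n_causal`` variants drawn from the model's variant set (all within
    ``maf_range`` by construction of the study fixture).
    """

    n_families: Sequence[int] = (100,)
    beta_g: Sequence[float] = (0.0,)
    replicates: int = 500
    n_causal: int = 3
    beta_sex: float = 0.5
    rho_w: float = 3.0
    lambda_w: float = 143.0
    sigma2_gen: float = 0.0
    alpha: float = 0.05
    maf_range: tuple[float, float] = (0.02, 0.1)
    seed: int = 0


def simulate_three_generation_family(
    pool: HaplotypePool,
    params: RecombinationParams,
    rng: np.random.Generator,
    variant_cms: np.ndarray,
    region_cm: tuple[float, float],
) -> tuple[list, np.ndarray, np.ndarray]:
    """One family; returns (blood individuals, generation labels, sex codes).

    Blood members are the two parents, each second-generation child and each
    grandchild (4-8 individuals); spouses are founders used for mating only.
    Sexes: parents are one male/one female, children random, spouse opposite.
    """
    father = founder_from_pool(pool, region_cm, id="g1-f", sex=1)
    mother = founder_from_pool(pool, region_cm, id="g1-m", sex=2)
    blood = [father, mother]
    gens = [1, 1]
    k2 = int(rng.integers(1, 3))
    for c in range(k2):
        child_sex = int(rng.integers(1, 3))
        child = mate(father, mother, rng, params, variant_cms, region_cm,
                     child_id=f"g2-{c}", sex=child_sex)
        spouse = founder_from_pool(pool, region_cm, id=f"g2-{c}s",
                                   sex=3 - child_sex)
        blood.append(child)
        gens.append(2)
        k3 = int(rng.integers(1, 3))
        dad, mom = (child, spouse) if child_sex == 1 else (spouse, child)
        for g in range(k3):
            gc = mate(dad, mom, rng, params, variant_cms, region_cm,
                      child_id=f"g3-{c}-{g}", sex=int(rng.integers(1, 3)))
            blood.append(gc)
            gens.append(3)
    sexes = np.array([ind.sex for ind in blood])
    return blood, np.asarray(gens), sexes


def _family_ibd_matrix(members: list) -> np.ndarray:
    n = len(members)
    B = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            B[i, j] = B[j, i] = compute_pair_ibd12(members[i], members[j]).mean_ibd
    return B


def simulate_study_replicate(
    model: HaplotypeModel,
    variant_cms: np.ndarray,
    causal_idx: np.ndarray,
    n_families: int,
    beta_g: float,
    config: StudyConfig,
    params: RecombinationParams,
    rng: np.random.Generator,
) -> tuple[FrailtyData, np.ndarray]:
    """Simulate one replicate; returns the frailty data and generation labels."""
    region = (float(variant_cms[0]), float(variant_cms[-1] + 1e-9))
    pool = HaplotypePool(model, rng)
    times, status, Xs, Bs, gen_all = [], [], [], [], []
    surv = SurvivalTraitModel(
        rho_w=config.rho_w,
        lambda_w=config.lambda_w,
        beta=np.concatenate([[config.beta_sex], np.full(len(causal_idx), beta_g)]),
        sigma2=config.sigma2_gen,
    )
    for _ in range(n_families):
        members, gens, sexes = simulate_three_generation_family(
            pool, params, rng, variant_cms, region
        )
        B = _family_ibd_matrix(members)
        G = np.array([ind.genotype[causal_idx] for ind in members], dtype=float)
        sex01 = (sexes == 2).astype(float)
        X_gen = np.column_stack([sex01, G])
        blocks = [list(range(len(members)))]
        t, d, _ = simulate_survival(
            surv, X_gen, gens, rng, family_blocks=blocks, B_blocks=[B]
        )
        times.append(t)
        status.append(d.astype(float))
        Xs.append(sex01[:, None])  # estimation covariate: sex only
        Bs.append(B)
        gen_all.append(gens)
    return FrailtyData(times, status, Xs, Bs), np.concatenate(gen_all)


def run_study(
    config: StudyConfig,
    model: HaplotypeModel,
    variant_cms: np.ndarray,
    params: Optional[RecombinationParams] = None,
    return_pvalues: bool = False,
):
    """Empirical rejection rate of the frailty LRT over a study grid.

    Per replicate: simulate three-generation families, compute per-family IBD
    matrices B from the origin tracks, generate survival data from the Weibull
    model with genotype covariates, fit null (sigma2 = 0) and alternative
    models, and reject when the mixture p-value is <= ``config.alpha``.

    Returns a DataFrame with one row per (n_families, beta_g) cell; with
    ``return_pvalues`` a dict of per-cell p-value arrays is returned too.
    """
    if config.replicates < 1:
        raise ValueError("need at least one replicate")
    params = params or RecombinationParams()
    variant_cms = np.asarray(variant_cms, dtype=float)
    master = np.random.default_rng(config.seed)
    causal_idx = np.sort(
        master.choice(model.n_variants, size=config.n_causal, replace=False)
    )
    rows = []
    pvals_by_cell = {}
    for n_fam in config.n_families:
        for bg in config.beta_g:
            cell_rng = np.random.default_rng(master.integers(2**31))
            pvals, failures = [], 0
            for _ in range(config.replicates):
                data, _ = simulate_study_replicate(
                    model, variant_cms, causal_idx, n_fam, bg, config, params,
                    cell_rng,
                )
                try:
                    f0 = fit(data, null=True)
                    # two sigma2 starts guard against stalls on the flat
                    # boundary profile; the better likelihood wins
                    anchor = {
                        "log_rho": np.log(f0.rho_hat),
                        "log_lam": np.log(f0.lambda_hat),
                        "beta": f0.beta_hat,
                    }
                    fits = [
                        fit(data, null=False, start={**anchor, "sigma2": s0})
                        for s0 in (0.2, 1.0)
                    ]
                    f1 = max(fits, key=lambda r: r.loglik)
                    if not (f0.converged and f1.converged):
                        failures += 1
                    pvals.append(lrt(f0, f1).p_value)
                except (ValueError, np.linalg.LinAlgError):
                    failures += 1
            pvals = np.asarray(pvals)
            rows.append(
                {
                    "n_families": n_fam,
                    "beta_g": bg,
                    "replicates": config.replicates,
                    "n_tested": len(pvals),
                    "rejection_rate": float(np.mean(pvals <= config.alpha))
                    if len(pvals)
                    else np.nan,
                    "fit_failures": failures,
                }
            )
            pvals_by_cell[(n_fam, bg)] = pvals
    table = pd.DataFrame(rows)
    if return_pvalues:
        return table, pvals_by_cell
    return table
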