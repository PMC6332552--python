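"""Latent-Gaussian haplotype model: fit from phased haplotypes, simulate new ones.

A haplotype over M biallelic sites is modeled through a latent M-variate
standard Gaussian Z with correlation matrix R: site j carries the alternate
allele iff Z_j < q_j where q_j = Phi^{-1}(p_j). Marginal allele frequencies are
then matched exactly, and R is chosen per pair so that the bivariate-normal
orthant probability reproduces the observed haplotypic joint frequency
(a tetrachoric correlation). Only pairwise LD is matched; three-way and
higher haplotype moments are not modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from scipy.linalg import cholesky
from scipy.special import ndtr, ndtri, owens_t

from .vcf_io import HaplotypeMatrix

RHO_CLIP = 0.999
EPS_PD = 1e-6
P_LIMIT = 1e-6  # frequencies this close to 0/1 are rejected at fit time
DEFAULT_BATCH_SIZE = 1000


def bvn_cdf(h, k, rho):
    """P(Z1 <= h, Z2 <= k) for standard bivariate normal with correlation rho.

    Vectorized over all arguments via Owen's T function; absolute accuracy is
    at the 1e-14 level away from |rho| = 1.
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    rho = np.asarray(rho, dtype=float)
    h, k, rho = np.broadcast_arrays(h, k, rho)
    # nudge exact zeros: T(h, (k - rho h)/(h sqrt(1-rho^2))) is singular at h=0
    # and the CDF is continuous there; the perturbation error is < 1e-13.
    h = np.where(np.abs(h) < 1e-13, 1e-13, h)
    k = np.where(np.abs(k) < 1e-13, 1e-13, k)
    denom = np.sqrt(np.clip(1.0 - rho * rho, 1e-300, None))
    ah = (k - rho * h) / (h * denom)
    ak = (h - rho * k) / (k * denom)
    beta = np.where(h * k > 0, 0.0, 0.5)
    val = 0.5 * (ndtr(h) + ndtr(k)) - owens_t(h, ah) - owens_t(k, ak) - beta
    return np.clip(val, 0.0, 1.0)


def _frechet_bounds(p_j, p_k):
    lo = np.maximum(0.0, p_j + p_k - 1.0)
    hi = np.minimum(p_j, p_k)
    return lo, hi


def _solve_latent_corr(q_j, q_k, p_jk, iters: int = 60) -> np.ndarray:
    """Vectorized bisection for rho with Phi2(q_j, q_k; rho) = p_jk.

    The orthant probability is strictly increasing in rho, so the bracket
    [-RHO_CLIP, RHO_CLIP] is valid; 60 halvings leave an interval far below
    the 1e-8 tolerance.
    """
    lo = np.full_like(q_j, -RHO_CLIP, dtype=float)
    hi = np.full_like(q_j, RHO_CLIP, dtype=float)
    # targets outside the achievable range at the clip bounds saturate there
    f_lo = bvn_cdf(q_j, q_k, lo) - p_jk
    f_hi = bvn_cdf(q_j, q_k, hi) - p_jk
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        f_mid = bvn_cdf(q_j, q_k, mid) - p_jk
        take_hi = f_mid < 0
        lo = np.where(take_hi, mid, lo)
        hi = np.where(take_hi, hi, mid)
    rho = 0.5 * (lo + hi)
    rho = np.where(f_hi <= 0, RHO_CLIP, rho)
    rho = np.where(f_lo >= 0, -RHO_CLIP, rho)
    return rho


def latent_correlation(p_j: float, p_k: float, p_jk: float) -> float:
    """Tetrachoric correlation matching a haplotypic joint frequency.

    Finds rho with ``P(Z_j < q_j, Z_k < q_k; rho) = p_jk`` where
    ``q = Phi^{-1}(p)``, by bisection to below 1e-8; the result is clipped to
    [-0.999, 0.999].
    """
    if not (0.0 < p_j < 1.0 and 0.0 < p_k < 1.0):
        raise ValueError("marginal frequencies must lie strictly in (0, 1)")
    lo, hi = _frechet_bounds(p_j, p_k)
    if not (lo - 1e-12 <= p_jk <= hi + 1e-12):
        raise ValueError(
            f"joint frequency {p_jk} outside Frechet bounds [{lo}, {hi}]"
        )
    q_j, q_k = ndtri(p_j), ndtri(p_k)
    rho = _solve_latent_corr(
        np.asarray([q_j]), np.asarray([q_k]), np.asarray([float(p_jk)])
    )
    return float(rho[0])


def repair_pd(R: np.ndarray, eps: float = EPS_PD) -> tuple[np.ndarray, float]:
    """Eigenvalue-clip a symmetric unit-diagonal matrix to positive definiteness.

    Eigenvalues below ``eps`` are raised to ``eps`` and the result rescaled to
    unit diagonal. Already-PD input is returned unchanged. Returns
    ``(R_repaired, max_abs_deviation)``.
    """
    R = np.asarray(R, dtype=float)
    w = np.linalg.eigvalsh(R)
    if w[0] >= eps * (1.0 - 1e-6):
        return R.copy(), 0.0
    # the unit-diagonal rescale can push the smallest eigenvalue slightly
    # back below the floor, so clip-and-rescale is iterated to a fixed point
    R2 = R
    for _ in range(20):
        w, V = np.linalg.eigh(R2)
        if w[0] >= eps * (1.0 - 1e-6):
            break
        R2 = (V * np.clip(w, eps, None)) @ V.T
        d = np.sqrt(np.diag(R2))
        R2 = R2 / np.outer(d, d)
        np.fill_diagonal(R2, 1.0)
        R2 = 0.5 * (R2 + R2.T)
    return R2, float(np.max(np.abs(R2 - R)))


def _safe_cholesky(R: np.ndarray) -> np.ndarray:
    jitter = 0.0
    for _ in range(6):
        try:
            return cholesky(R + jitter * np.eye(len(R)), lower=True)
        except np.linalg.LinAlgError:
            jitter = max(jitter * 10.0, 1e-10)
    raise np.linalg.LinAlgError("correlation matrix not factorizable after jitter")


@dataclass
class HaplotypeModel:
    """Fitted latent-Gaussian haplotype model.

    Attributes
    ----------
    p : (M,) alternate-allele frequencies
    q : (M,) Gaussian thresholds, Phi^{-1}(p)
    R : (M, M) latent correlation matrix (PD after repair)
    chol : lower-triangular Cholesky factor of R
    variants : variant table the model was fitted on
    pd_deviation : max |R_repaired - R_raw| introduced by the PD repair
    """

    p: np.ndarray
    q: np.ndarray
    R: np.ndarray
    chol: np.ndarray
    variants: pd.DataFrame
    pd_deviation: float = 0.0

    @property
    def n_variants(self) -> int:
        return len(self.p)

    def simulate(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n haplotypes (n, M) int8: allele 1 iff latent Z < q."""
        if n == 0:
            return np.zeros((0, self.n_variants), dtype=np.int8)
        Z = rng.standard_normal((n, self.n_variants)) @ self.chol.T
        return (Z < self.q).astype(np.int8)

    def save(self, path: str) -> None:
        """Serialize (positions, p, R) to a portable .npz archive."""
        np.savez_compressed(
            path,
            p=self.p,
            R=self.R,
            pos=self.variants["pos"].to_numpy(),
            chrom=self.variants["chrom"].astype(str).to_numpy(dtype="U"),
            maf=self.variants["maf"].to_numpy(),
        )

    @classmethod
    def load(cls, path: str) -> "HaplotypeModel":
        with np.load(path, allow_pickle=False) as z:
            p = z["p"]
            R = z["R"]
            variants = pd.DataFrame(
                {
                    "chrom": z["chrom"],
                    "pos": z["pos"],
                    "id": ".",
                    "ref": "A",
                    "alt": "G",
                    "maf": z["maf"],
                }
            )
        R, dev = repair_pd(R)
        return cls(
            p=p, q=ndtri(p), R=R, chol=_safe_cholesky(R), variants=variants,
            pd_deviation=dev,
        )


def fit_model(haps: HaplotypeMatrix) -> HaplotypeModel:
    """Fit the latent-Gaussian model from observed phased haplotypes.

    Marginals come from column means, pairwise latent correlations from the
    haplotypic joint frequencies via the tetrachoric equation, followed by a
    PD repair of the assembled correlation matrix. Cost is O(M^2) in the
    number of variants.
    """
    H = np.asarray(haps.alleles, dtype=np.float64)
    n, M = H.shape
    if n < 2:
        raise ValueError("need at least two haplotypes to fit a model")
    p = H.mean(axis=0)
    bad = (p <= P_LIMIT) | (p >= 1.0 - P_LIMIT)
    if np.any(bad):
        raise ValueError(
            f"{bad.sum()} monomorphic or near-monomorphic variant(s) "
            "(frequency outside (1e-6, 1-1e-6)); apply a MAF pre-filter first"
        )
    q = ndtri(p)

    P11 = (H.T @ H) / n  # haplotypic joint frequencies of the 1/1 cell
    ju, ku = np.triu_indices(M, k=1)
    lo, hi = _frechet_bounds(p[ju], p[ku])
    p_jk = np.clip(P11[ju, ku], lo, hi)
    rho = _solve_latent_corr(q[ju], q[ku], p_jk)

    R = np.eye(M)
    R[ju, ku] = rho
    R[ku, ju] = rho
    R, dev = repair_pd(R)
    return HaplotypeModel(
        p=p, q=q, R=R, chol=_safe_cholesky(R), variants=haps.variants,
        pd_deviation=dev,
    )


@dataclass
class HaplotypePool:
    """Buffered haplotype source: regenerates ``batch_size`` haplotypes on demand.

    A fresh pool is empty; the first draw generates one batch and subsequent
    draws trigger a new batch each time the buffer is exhausted. Each
    delivered haplotype receives a globally unique origin id (used as the
    founder identifier in IBD tracking).
    """

    model: HaplotypeModel
    rng: np.random.Generator
    batch_size: int = DEFAULT_BATCH_SIZE
    _buffer: np.ndarray = field(default=None, repr=False)
    _cursor: int = 0
    _next_origin: int = 0
    batches_generated: int = 0

    def _refill(self) -> None:
        self._buffer = self.model.simulate(self.batch_size, self.rng)
        self._cursor = 0
        self.batches_generated += 1

    def draw(self, n: int) -> tuple[np.ndarray, np.ndarray]:
        """Return (haplotypes (n, M), origin ids (n,))."""
        out = np.empty((n, self.model.n_variants), dtype=np.int8)
        filled = 0
        while filled < n:
            if self._buffer is None or self._cursor >= len(self._buffer):
                self._refill()
            take = min(n - filled, len(self._buffer) - self._cursor)
            out[filled : filled + take] = self._buffer[
                self._cursor : self._cursor + take
            ]
            self._cursor += take
            filled += take
        origins = np.arange(self._next_origin, self._next_origin + n, dtype=np.int64)
        self._next_origin += n
        return out, origins


def generate_haplotypes(pool: HaplotypePool, n: int) -> HaplotypeMatrix:
    """Draw n haplotypes from the pool as a HaplotypeMatrix (n must be even)."""
    if n % 2:
        raise ValueError("n must be even (two haplotypes per sample)")
    H, _ = pool.draw(n)
    sample_ids = [f"sim{i}" for i in range(n // 2)]
    variants = pool.model.variants.copy()
    if n > 0:
        p_obs = H.mean(axis=0)
        variants["maf"] = np.minimum(p_obs, 1 - p_obs)
    return HaplotypeMatrix(H, sample_ids, variants)
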