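"""Synthetic phased-VCF fixtures with known allele frequencies and LD.

Fixture haplotypes are drawn from the same latent-Gaussian threshold
mechanism the simulator fits (allele 1 iff a correlated standard normal falls
below Phi^{-1}(p)), so the generating marginals ``p`` and latent correlation
``R`` are exact ground truth for oracle tests. Two LD geometries are
available: AR-1 decay (rho^|j-k|) and disjoint blocks with a common
within-block correlation. A matching uniform-rate genetic map and a JSON
manifest of the truth are written alongside the VCF.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd
from scipy.special import ndtri

from .genetic_map import GeneticMap
from .vcf_io import HaplotypeMatrix, write_phased_vcf


@dataclass
class FixtureSpec:
    """Recipe for a reproducible synthetic phased VCF.

    ``ld`` selects the latent correlation geometry: ``("ar1", rho)`` or
    ``("block", block_size, rho)``. ``maf_range`` bounds the generating
    alternate-allele frequencies (alternate allele = minor allele).
    """

    n_variants: int = 100
    n_samples: int = 500
    maf_range: tuple[float, float] = (0.02, 0.5)
    ld: tuple = ("ar1", 0.8)
    span_bp: int = 1_000_000
    chrom: str = "1"
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo < hi <= 0.5):
            raise ValueError("need 0 < maf_min < maf_max <= 0.5")
        if self.n_variants < 1 or self.n_samples < 1:
            raise ValueError("n_variants and n_samples must be positive")


def latent_correlation_matrix(spec: FixtureSpec) -> np.ndarray:
    """Ground-truth latent R for the spec's LD geometry (always PD)."""
    M = spec.n_variants
    kind = spec.ld[0]
    if kind == "ar1":
        rho = float(spec.ld[1])
        idx = np.arange(M)
        return rho ** np.abs(idx[:, None] - idx[None, :])
    if kind == "block":
        size, rho = int(spec.ld[1]), float(spec.ld[2])
        block = np.arange(M) // size
        R = np.where(block[:, None] == block[None, :], rho, 0.0)
        np.fill_diagonal(R, 1.0)
        return R
    raise ValueError(f"unknown LD geometry {kind!r}")


def make_fixture(
    spec: FixtureSpec, out_dir: str | Path, prefix: str = "fixture"
) -> dict:
    """Write ``<prefix>.vcf``, ``<prefix>.map`` and ``<prefix>.manifest.json``.

    Returns the manifest dict, which records the generating truth: positions,
    per-variant ``p``, the LD geometry, and the seed. Identical specs produce
    byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    M, N = spec.n_variants, spec.n_samples

    p = rng.uniform(*spec.maf_range, size=M)
    pos = np.sort(rng.choice(np.arange(1, spec.span_bp + 1), size=M, replace=False))
    R = latent_correlation_matrix(spec)
    L = np.linalg.cholesky(R)
    Z = rng.standard_normal((2 * N, M)) @ L.T
    H = (Z < ndtri(p)).astype(np.int8)

    p_obs = H.mean(axis=0)
    variants = pd.DataFrame(
        {
            "chrom": spec.chrom,
            "pos": pos,
            "id": [f"var{j}" for j in range(M)],
            "ref": "A",
            "alt": "G",
            "maf": np.minimum(p_obs, 1 - p_obs),
        }
    )
    haps = HaplotypeMatrix(H, [f"s{i}" for i in range(N)], variants)

    vcf_path = out_dir / f"{prefix}.vcf"
    map_path = out_dir / f"{prefix}.map"
    write_phased_vcf(variants, haps, str(vcf_path))
    gmap = GeneticMap.uniform(spec.chrom, span_bp=float(spec.span_bp))
    gmap.save(str(map_path))

    # file paths are kept relative inside the written manifest so identical
    # specs produce byte-identical files wherever they are materialized
    manifest = {
        "vcf": vcf_path.name,
        "map": map_path.name,
        "seed": spec.seed,
        "chrom": spec.chrom,
        "n_variants": M,
        "n_samples": N,
        "positions": pos.tolist(),
        "p": p.tolist(),
        "p_observed": p_obs.tolist(),
        "maf_range": list(spec.maf_range),
        "ld": list(spec.ld),
    }
    with open(out_dir / f"{prefix}.manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return {**manifest, "vcf": str(vcf_path), "map": str(map_path)}


def make_trio_pedigree() -> pd.DataFrame:
    """Minimal trio pedigree table (two founders and a child)."""
    return pd.DataFrame(
        [
            ["fam1", "dad", "0", "0", 1],
            ["fam1", "mom", "0", "0", 2],
            ["fam1", "kid", "dad", "mom", 1],
        ],
        columns=["fam", "id", "father", "mother", "sex"],
    )
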