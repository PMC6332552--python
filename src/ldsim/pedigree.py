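"""Cohort generation: unrelated individuals, gene-dropped pedigrees, exact IBD.

Founder gametes drawn from the haplotype pool carry globally unique origin
ids; every meiosis splices origin tracks alongside alleles, so the IBD state
of any pair at any genetic position is known exactly rather than inferred.
IBD0/1/2 proportions are genetic-length (cM) weighted, and the mean IBD is
the kinship-scale pi-hat = IBD2 + IBD1/2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .haplotype import HaplotypePool
from .meiosis import Individual, OriginTrack, RecombinationParams, mate
from .vcf_io import HaplotypeMatrix, PedigreeTable


@dataclass
class Cohort:
    """Simulated individuals over a common variant set and genetic region."""

    individuals: list[Individual]
    variants: pd.DataFrame
    variant_cms: np.ndarray
    region_cm: tuple[float, float]
    founder_count: int = 0

    def __len__(self) -> int:
        return len(self.individuals)

    def dosages(self) -> np.ndarray:
        """Additive genotype matrix (N, M)."""
        return np.array([ind.genotype for ind in self.individuals], dtype=np.int16)

    def haplotype_matrix(self) -> HaplotypeMatrix:
        n = len(self.individuals)
        A = np.empty((2 * n, len(self.variants)), dtype=np.int8)
        for i, ind in enumerate(self.individuals):
            A[2 * i] = ind.gamete1
            A[2 * i + 1] = ind.gamete2
        ids = [ind.id or f"ind{i}" for i, ind in enumerate(self.individuals)]
        variants = self.variants.copy()
        if n:
            p = A.mean(axis=0)
            variants["maf"] = np.minimum(p, 1 - p)
        return HaplotypeMatrix(A, ids, variants)


@dataclass
class IBDResult:
    """Genetic-length-weighted IBD sharing proportions for one pair."""

    ibd0: float
    ibd1: float
    ibd2: float

    @property
    def mean_ibd(self) -> float:
        """pi-hat = IBD2 + IBD1/2 (0.25 avuncular, 0.5 sibs/parent-offspring)."""
        return self.ibd2 + 0.5 * self.ibd1


def _region_from_variants(variant_cms: np.ndarray) -> tuple[float, float]:
    return float(variant_cms[0]), float(variant_cms[-1] + 1e-9)


def founder_from_pool(
    pool: HaplotypePool, region_cm: tuple[float, float], id: str = "", sex: int = 0
) -> Individual:
    """New founder: two fresh pool haplotypes with single-segment tracks."""
    haps, origins = pool.draw(2)
    start, end = region_cm
    return Individual(
        gamete1=haps[0],
        gamete2=haps[1],
        track1=OriginTrack.single(int(origins[0]), start, end),
        track2=OriginTrack.single(int(origins[1]), start, end),
        id=id,
        sex=sex,
    )


def generate_unrelated(
    pool: HaplotypePool,
    n: int,
    variant_cms: np.ndarray,
    region_cm: Optional[tuple[float, float]] = None,
) -> Cohort:
    """n unrelated individuals, two pool haplotypes each."""
    variant_cms = np.asarray(variant_cms, dtype=float)
    region = region_cm or _region_from_variants(variant_cms)
    inds = [founder_from_pool(pool, region, id=f"ind{i}") for i in range(n)]
    return Cohort(inds, pool.model.variants, variant_cms, region, founder_count=n)


def simulate_pedigree(
    ped: PedigreeTable,
    pool: HaplotypePool,
    params: RecombinationParams,
    rng: np.random.Generator,
    variant_cms: np.ndarray,
    region_cm: Optional[tuple[float, float]] = None,
) -> Cohort:
    """Gene-drop a pedigree: founders from the pool, children via mate().

    Individuals are produced in parent-before-child order; the returned
    cohort preserves the pedigree file's row order.
    """
    variant_cms = np.asarray(variant_cms, dtype=float)
    region = region_cm or _region_from_variants(variant_cms)
    rows = {r.id: r for r in ped.table.itertuples(index=False)}
    done: dict[str, Individual] = {}
    n_founders = 0
    for iid in ped.order:
        row = rows[iid]
        if row.father == "0" and row.mother == "0":
            done[iid] = founder_from_pool(pool, region, id=iid, sex=int(row.sex))
            n_founders += 1
        elif row.father in done and row.mother in done:
            done[iid] = mate(
                done[row.father], done[row.mother], rng, params,
                variant_cms, region, child_id=iid, sex=int(row.sex),
            )
        else:
            raise ValueError(f"individual {iid}: unresolvable parent")
    inds = [done[i] for i in ped.table["id"]]
    return Cohort(inds, pool.model.variants, variant_cms, region,
                  founder_count=n_founders)


def compute_pair_ibd12(a: Individual, b: Individual) -> IBDResult:
    """Exact IBD0/1/2 proportions for a pair from their origin tracks.

    The four tracks are overlaid; within each refined segment the IBD state is
    the best pairing of the two individuals' founder ids (a 2x2 matching), and
    proportions are segment-length weighted in cM.
    """
    t = (a.track1, a.track2, b.track1, b.track2)
    start, end = t[0].start_cm, t[0].end_cm
    for track in t[1:]:
        if (track.start_cm, track.end_cm) != (start, end):
            raise ValueError("individuals cover different genetic regions")
    cuts = np.unique(np.concatenate(
        [[start, end]] + [tr.breakpoints for tr in t]
    ))
    cuts = cuts[(cuts >= start) & (cuts <= end)]
    mids = 0.5 * (cuts[:-1] + cuts[1:])
    lengths = np.diff(cuts)
    a1, a2, b1, b2 = (tr.source_at(mids) for tr in t)
    straight = (a1 == b1).astype(np.int8) + (a2 == b2)
    crossed = (a1 == b2).astype(np.int8) + (a2 == b1)
    state = np.maximum(straight, crossed)
    total = lengths.sum()
    if total <= 0:
        raise ValueError("degenerate (zero-length) genetic region")
    props = [float(lengths[state == k].sum() / total) for k in (0, 1, 2)]
    return IBDResult(*props)


def ibd_matrix(cohort: Cohort, indices: Optional[list[int]] = None) -> np.ndarray:
    """Symmetric mean-IBD (pi-hat) matrix with unit diagonal.

    This is the relationship matrix B used by the correlated-frailty model.
    """
    idx = indices if indices is not None else range(len(cohort))
    idx = list(idx)
    n = len(idx)
    B = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            r = compute_pair_ibd12(
                cohort.individuals[idx[i]], cohort.individuals[idx[j]]
            )
            B[i, j] = B[j, i] = r.mean_ibd
    return B


def ibd_pair_table(cohort: Cohort) -> pd.DataFrame:
    """All-pairs IBD results as a tidy table (id1, id2, ibd0, ibd1, ibd2, mean_ibd)."""
    rows = []
    for i in range(len(cohort)):
        for j in range(i + 1, len(cohort)):
            a, b = cohort.individuals[i], cohort.individuals[j]
            r = compute_pair_ibd12(a, b)
            rows.append((a.id or f"ind{i}", b.id or f"ind{j}",
                         r.ibd0, r.ibd1, r.ibd2, r.mean_ibd))
    return pd.DataFrame(
        rows, columns=["id1", "id2", "ibd0", "ibd1", "ibd2", "mean_ibd"]
    )
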