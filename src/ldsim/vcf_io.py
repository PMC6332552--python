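"""Phased-VCF and pedigree input/output.

Variants are abstract biallelic records: the allele matrix stores ALT-allele
indicators (1 = ALT), and the minor-allele frequency is derived separately as
``min(p_alt, 1 - p_alt)`` so that phase semantics are stable when REF/ALT
frequencies tie at 0.5. Coordinates are VCF-style 1-based inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

VARIANT_COLUMNS = ["chrom", "pos", "id", "ref", "alt", "maf"]


class VcfFormatError(ValueError):
    """Raised for VCF records that violate the phased-GT contract."""


@dataclass
class HaplotypeMatrix:
    """Phased haplotypes: rows ``2i`` and ``2i+1`` belong to sample ``i``.

    ``alleles`` is a ``(2N, M)`` int8 matrix of ALT-allele indicators and
    ``variants`` a DataFrame with columns chrom/pos/id/ref/alt/maf.
    """

    alleles: np.ndarray
    sample_ids: list[str]
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D matrix")
        if self.alleles.shape[0] != 2 * len(self.sample_ids):
            raise ValueError(
                f"{self.alleles.shape[0]} haplotype rows for "
                f"{len(self.sample_ids)} samples; expected 2 rows per sample"
            )
        if self.alleles.shape[1] != len(self.variants):
            raise ValueError("allele matrix width does not match variant table")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return self.alleles.shape[1]

    def dosages(self) -> np.ndarray:
        """Additive genotype dosages (N, M) in {0, 1, 2}."""
        return self.alleles[0::2] + self.alleles[1::2]


@dataclass
class FilterSpec:
    """Variant filters, applied region -> biallelic -> MAF range -> max_variants."""

    maf_min: float = 0.0
    maf_max: float = 0.5
    max_variants: Optional[int] = None
    region: Optional[tuple[str, int, int]] = None  # 1-based inclusive

    def __post_init__(self) -> None:
        if not (0.0 <= self.maf_min <= self.maf_max <= 0.5):
            raise ValueError("need 0 <= maf_min <= maf_max <= 0.5")
        if self.max_variants is not None and self.max_variants < 1:
            raise ValueError("max_variants must be positive")


def _maf(p_alt: float) -> float:
    return min(p_alt, 1.0 - p_alt)


def read_phased_vcf(
    path: str, filter_spec: Optional[FilterSpec] = None
) -> tuple[pd.DataFrame, HaplotypeMatrix]:
    """Read a phased VCF into a variant table and haplotype matrix.

    Multiallelic records and records with missing genotypes are dropped with a
    logged count; an unphased genotype (``/`` separator) is a hard error.

    Returns
    -------
    (variants, haplotypes)
        ``variants`` is a DataFrame (chrom, pos, id, ref, alt, maf);
        ``haplotypes`` the matching :class:`HaplotypeMatrix`.
    """
    spec = filter_spec or FilterSpec()
    vcf = VCF(path, gts012=False)
    sample_ids = list(vcf.samples)
    if not sample_ids:
        raise VcfFormatError(f"{path}: VCF contains no samples")

    cols: list[np.ndarray] = []
    rows: list[tuple] = []
    n_multi = n_missing = 0
    for rec in vcf:
        if spec.region is not None:
            chrom, start, end = spec.region
            if rec.CHROM != chrom or not (start <= rec.POS <= end):
                continue
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        gts = rec.genotype.array()  # (N, 3): allele a, allele b, phased flag
        a, b, phased = gts[:, 0], gts[:, 1], gts[:, 2]
        if np.any((a < 0) | (b < 0)):
            n_missing += 1
            continue
        if not np.all(phased):
            raise VcfFormatError(
                f"unphased genotype at {rec.CHROM}:{rec.POS} "
                f"({rec.ID or '.'}); ldsim requires '|'-separated GTs"
            )
        hap = np.empty(2 * len(sample_ids), dtype=np.int8)
        hap[0::2] = a
        hap[1::2] = b
        p_alt = hap.mean()
        maf = _maf(p_alt)
        if not (spec.maf_min <= maf <= spec.maf_max):
            continue
        rows.append((rec.CHROM, rec.POS, rec.ID or ".", rec.REF, rec.ALT[0], maf))
        cols.append(hap)
        if spec.max_variants is not None and len(rows) >= spec.max_variants:
            logger.info("max_variants=%d reached; truncating", spec.max_variants)
            break
    vcf.close()

    if n_multi:
        logger.info("dropped %d multiallelic records", n_multi)
    if n_missing:
        logger.info("dropped %d records with missing genotypes", n_missing)
    if not rows:
        raise VcfFormatError(f"{path}: no variants left after filtering")

    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    alleles = np.column_stack(cols)
    return variants, HaplotypeMatrix(alleles, sample_ids, variants)


def write_phased_vcf(variants: pd.DataFrame, haps: HaplotypeMatrix, path: str) -> None:
    """Write a GT-only phased VCF 4.2 file; round-trips through read_phased_vcf."""
    if haps.n_samples == 0:
        raise ValueError("cannot write a VCF with zero samples")
    if len(variants) != haps.n_variants:
        raise ValueError("variant table and haplotype matrix disagree in length")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=ldsim\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(s) for s in haps.sample_ids)
            + "\n"
        )
        A = haps.alleles
        for j, row in enumerate(variants.itertuples(index=False)):
            gts = "\t".join(
                f"{A[2 * i, j]}|{A[2 * i + 1, j]}" for i in range(haps.n_samples)
            )
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


@dataclass
class PedigreeTable:
    """PED-like pedigree: one row per individual, founders have parent id '0'."""

    table: pd.DataFrame = field(repr=False)
    order: list[str] = field(default_factory=list)  # ids in parent-before-child order

    @property
    def n_individuals(self) -> int:
        return len(self.table)

    def founders(self) -> pd.DataFrame:
        t = self.table
        return t[(t.father == "0") & (t.mother == "0")]


MISSING_PARENT = "0"


def read_pedigree(path_or_df) -> PedigreeTable:
    """Parse and validate a whitespace-delimited PED-like file.

    Columns: family id, individual id, father id, mother id, sex (1=male,
    2=female). ``0`` marks a missing parent; parsing is order-independent and a
    parent-before-child topological order is computed (cycles are an error).
    """
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df.copy()
        df.columns = ["fam", "id", "father", "mother", "sex"][: len(df.columns)]
    else:
        df = pd.read_csv(
            path_or_df,
            sep=r"\s+",
            header=None,
            names=["fam", "id", "father", "mother", "sex"],
            dtype=str,
            comment="#",
        )
    for c in ["fam", "id", "father", "mother"]:
        df[c] = df[c].astype(str)
    df["sex"] = df["sex"].astype(int)
    if df["id"].duplicated().any():
        raise ValueError("duplicate individual ids in pedigree")

    ids = set(df["id"])
    for row in df.itertuples(index=False):
        for parent in (row.father, row.mother):
            if parent != MISSING_PARENT and parent not in ids:
                raise ValueError(f"individual {row.id}: unknown parent {parent}")
            if parent == row.id:
                raise ValueError(f"individual {row.id} is its own parent")

    # Kahn traversal over parent -> child edges; leftovers indicate a cycle.
    parents = {
        r.id: {p for p in (r.father, r.mother) if p != MISSING_PARENT}
        for r in df.itertuples(index=False)
    }
    order: list[str] = []
    placed: set[str] = set()
    pending = dict(parents)
    while pending:
        ready = [i for i, ps in pending.items() if ps <= placed]
        if not ready:
            raise ValueError(f"pedigree contains a cycle among {sorted(pending)}")
        for i in ready:
            order.append(i)
            placed.add(i)
            del pending[i]
    return PedigreeTable(table=df, order=order)


def write_pedigree(ped: PedigreeTable, path: str) -> None:
    ped.table.to_csv(path, sep="\t", header=False, index=False)
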