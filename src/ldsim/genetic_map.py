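"""Physical (bp) to genetic (cM) coordinate mapping for one chromosome.

A map is a monotone piecewise-linear lookup over (bp, cumulative cM) nodes,
typically derived from a HapMap-style recombination map. When no map is
available a uniform 1 cM/Mb fallback (the genome-wide human average) keeps
pedigree simulation usable on synthetic fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

UNIFORM_CM_PER_BP = 1e-6  # 1 cM / Mb


@dataclass
class GeneticMap:
    """Sex-averaged genetic map: bp strictly increasing, cM non-decreasing."""

    chrom: str
    bp: np.ndarray
    cm: np.ndarray

    def __post_init__(self) -> None:
        self.bp = np.asarray(self.bp, dtype=float)
        self.cm = np.asarray(self.cm, dtype=float)
        if len(self.bp) < 2:
            raise ValueError("genetic map needs at least two nodes")
        if np.any(np.diff(self.bp) <= 0):
            raise ValueError("bp positions must be strictly increasing")
        if np.any(np.diff(self.cm) < 0):
            raise ValueError("cumulative cM must be non-decreasing")

    @classmethod
    def uniform(cls, chrom: str = "1", span_bp: float = 3e8) -> "GeneticMap":
        """Flat 1 cM/Mb map covering [0, span_bp]."""
        bp = np.array([0.0, span_bp])
        return cls(chrom, bp, bp * UNIFORM_CM_PER_BP)

    def bp_to_cm(self, pos_bp) -> np.ndarray | float:
        """Interpolate cM at physical position(s); extrapolates with the
        terminal segment's rate beyond the map ends."""
        pos = np.asarray(pos_bp, dtype=float)
        out = np.interp(pos, self.bp, self.cm)
        left_rate = (self.cm[1] - self.cm[0]) / (self.bp[1] - self.bp[0])
        right_rate = (self.cm[-1] - self.cm[-2]) / (self.bp[-1] - self.bp[-2])
        out = np.where(
            pos < self.bp[0], self.cm[0] + (pos - self.bp[0]) * left_rate, out
        )
        out = np.where(
            pos > self.bp[-1], self.cm[-1] + (pos - self.bp[-1]) * right_rate, out
        )
        return float(out) if np.isscalar(pos_bp) else out

    def save(self, path: str) -> None:
        pd.DataFrame({"chrom": self.chrom, "bp": self.bp.astype(np.int64),
                      "cm": self.cm}).to_csv(path, sep="\t", index=False)


def load_map(path: str) -> GeneticMap:
    """Load a 3-column (chrom, bp, cumulative cM) plain-text map; header optional."""
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#", dtype=str)
    # drop a header row if the bp column is not numeric
    if not df.iloc[0, 1].replace(".", "", 1).lstrip("-").isdigit():
        df = df.iloc[1:]
    if df.shape[1] < 3:
        raise ValueError("genetic map needs 3 columns: chrom, bp, cM")
    chrom = str(df.iloc[0, 0])
    bp = df.iloc[:, 1].astype(float).to_numpy()
    cm = df.iloc[:, 2].astype(float).to_numpy()
    order = np.argsort(bp)
    return GeneticMap(chrom, bp[order], cm[order])
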