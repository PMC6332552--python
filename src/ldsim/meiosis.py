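"""Meiosis: crossover placement and gamete formation with ancestry tracking.

Crossovers are placed in genetic distance (Morgans); physical positions enter
only through the bp->cM map. Two models are available:

* ``no_interference`` — a Poisson process with intensity 1 per Morgan on the
  gamete (Haldane's model);
* ``chi_squared`` — the two-pathway crossover-interference model: chiasmata of
  the interfering pathway arise on the four-strand bundle as every (m+1)-th
  event of a Poisson stream of rate 2(m+1)(1-p_escape) per Morgan
  (a gamma/chi-squared renewal process, stationarized by a uniformly random
  initial counter phase), each passed to the gamete independently with
  probability 1/2; the escape pathway adds non-interfering crossovers at rate
  p_escape per Morgan directly on the gamete.

Both models are calibrated to one crossover per gamete per Morgan. Each
gamete carries an :class:`OriginTrack` naming, for every genetic-map segment,
the founder haplotype it descends from — the basis for exact IBD computation.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

CHI_SQUARED = "chi_squared"
NO_INTERFERENCE = "no_interference"


@dataclass
class RecombinationParams:
    """Crossover-model choice; m=0 or p_escape=1 reduces chi_squared to Poisson."""

    model: str = CHI_SQUARED
    m: int = 4
    p_escape: float = 0.05

    def __post_init__(self) -> None:
        if self.model not in (CHI_SQUARED, NO_INTERFERENCE):
            raise ValueError(f"unknown recombination model {self.model!r}")
        if self.m < 0 or not (0.0 <= self.p_escape <= 1.0):
            raise ValueError("need m >= 0 and p_escape in [0, 1]")


def crossovers_poisson(L_morgan: float, rng: np.random.Generator) -> np.ndarray:
    """No-interference crossovers: Poisson(L) count, uniform positions in [0, L]."""
    if L_morgan < 0:
        raise ValueError("region length must be non-negative")
    if L_morgan == 0:
        return np.empty(0)
    n = rng.poisson(L_morgan)
    return np.sort(rng.uniform(0.0, L_morgan, n))


def crossovers_chisq(
    L_morgan: float, params: RecombinationParams, rng: np.random.Generator
) -> np.ndarray:
    """Two-pathway chi-squared interference model crossovers on [0, L]."""
    if L_morgan < 0:
        raise ValueError("region length must be non-negative")
    if L_morgan == 0:
        return np.empty(0)
    m, p_esc = params.m, params.p_escape
    out = []
    rate = 2.0 * (m + 1) * (1.0 - p_esc)  # bundle event rate per Morgan
    if rate > 0:
        n_events = rng.poisson(rate * L_morgan)
        events = np.sort(rng.uniform(0.0, L_morgan, n_events))
        # stationary phase: keep events with index == U (mod m+1); the first
        # kept event then has the equilibrium forward-recurrence distribution
        # of the Erlang(m+1) renewal process.
        offset = rng.integers(0, m + 1)
        chiasmata = events[offset :: m + 1]
        keep = rng.random(len(chiasmata)) < 0.5  # chiasma -> this gamete
        out.append(chiasmata[keep])
    if p_esc > 0:
        n_esc = rng.poisson(p_esc * L_morgan)
        out.append(rng.uniform(0.0, L_morgan, n_esc))
    if not out:
        return np.empty(0)
    return np.sort(np.concatenate(out))


def draw_crossovers(
    L_morgan: float, params: RecombinationParams, rng: np.random.Generator
) -> np.ndarray:
    if params.model == NO_INTERFERENCE:
        return crossovers_poisson(L_morgan, rng)
    return crossovers_chisq(L_morgan, params, rng)


@dataclass
class OriginTrack:
    """Founder-haplotype ancestry of one gamete along the region.

    ``breakpoints`` are interior cM positions; ``sources`` has one more entry
    and names the founder haplotype of each segment. Adjacent segments always
    have distinct sources (merged on construction).
    """

    breakpoints: np.ndarray
    sources: np.ndarray
    start_cm: float
    end_cm: float

    def __post_init__(self) -> None:
        self.breakpoints = np.asarray(self.breakpoints, dtype=float)
        self.sources = np.asarray(self.sources, dtype=np.int64)
        if len(self.sources) != len(self.breakpoints) + 1:
            raise ValueError("sources must have one more entry than breakpoints")

    @classmethod
    def single(cls, source: int, start_cm: float, end_cm: float) -> "OriginTrack":
        return cls(np.empty(0), np.asarray([source]), start_cm, end_cm)

    def source_at(self, cm) -> np.ndarray:
        """Founder haplotype id at genetic position(s) cm (vectorized)."""
        idx = np.searchsorted(self.breakpoints, np.asarray(cm, dtype=float),
                              side="right")
        return self.sources[idx]

    def _merged(self) -> "OriginTrack":
        if len(self.breakpoints) == 0:
            return self
        keep = self.sources[1:] != self.sources[:-1]
        return OriginTrack(
            self.breakpoints[keep],
            np.concatenate([self.sources[:1], self.sources[1:][keep]]),
            self.start_cm,
            self.end_cm,
        )


def splice_tracks(
    track_a: OriginTrack,
    track_b: OriginTrack,
    crossovers: np.ndarray,
    start_phase: int,
) -> OriginTrack:
    """Compose a child track from two parental tracks with the given crossovers.

    The child copies ``track_a`` (phase 1) or ``track_b`` (phase 2) up to the
    first crossover, alternating thereafter.
    """
    tracks = (track_a, track_b)
    cuts = np.concatenate([[track_a.start_cm], crossovers, [track_a.end_cm]])
    bks: list[float] = []
    srcs: list[int] = []
    phase = start_phase - 1
    for seg_lo, seg_hi in zip(cuts[:-1], cuts[1:]):
        t = tracks[phase]
        inside = (t.breakpoints > seg_lo) & (t.breakpoints < seg_hi)
        first = np.searchsorted(t.breakpoints, seg_lo, side="right")
        seg_srcs = np.concatenate(
            [[t.sources[first]], t.sources[first + 1 :][inside[first:]]]
        ) if len(t.breakpoints) else t.sources
        seg_bks = t.breakpoints[inside]
        srcs.extend(seg_srcs.tolist())
        bks.extend(seg_bks.tolist())
        bks.append(seg_hi)
        phase = 1 - phase
    bks = bks[:-1]  # last cut is the region end, not an interior breakpoint
    return OriginTrack(
        np.asarray(bks), np.asarray(srcs), track_a.start_cm, track_a.end_cm
    )._merged()


@dataclass
class Individual:
    """Diploid individual: two gametes with their founder-origin tracks."""

    gamete1: np.ndarray
    gamete2: np.ndarray
    track1: OriginTrack
    track2: OriginTrack
    id: str = ""
    sex: int = 0  # 1 male, 2 female, 0 unknown

    @property
    def genotype(self) -> np.ndarray:
        return self.gamete1 + self.gamete2


def make_gamete(
    parent: Individual,
    crossovers: np.ndarray,
    start_phase: int,
    variant_cms: np.ndarray,
) -> tuple[np.ndarray, OriginTrack]:
    """One recombined gamete from a parent.

    Alleles are copied from parental gamete ``start_phase`` up to the first
    crossover and alternate thereafter; the origin track is the parental
    tracks spliced at the same positions, so every allele equals the founder
    allele named by the track.
    """
    crossovers = np.asarray(crossovers, dtype=float)
    if np.any(np.diff(crossovers) < 0):
        raise ValueError("crossover positions must be sorted")
    if start_phase not in (1, 2):
        raise ValueError("start_phase must be 1 or 2")
    n_cross_before = np.searchsorted(crossovers, variant_cms, side="right")
    phase = (start_phase - 1 + n_cross_before) % 2  # 0 -> gamete1, 1 -> gamete2
    alleles = np.where(phase == 0, parent.gamete1, parent.gamete2).astype(np.int8)
    track = splice_tracks(parent.track1, parent.track2, crossovers, start_phase)
    return alleles, track


def meiosis(
    parent: Individual,
    variant_cms: np.ndarray,
    region_cm: tuple[float, float],
    params: RecombinationParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, OriginTrack]:
    """Draw crossovers and a random start phase, return one gamete."""
    start, end = region_cm
    L = (end - start) / 100.0  # cM -> Morgan
    xovers = start + 100.0 * draw_crossovers(L, params, rng)
    phase = int(rng.integers(1, 3))
    return make_gamete(parent, xovers, phase, variant_cms)


def mate(
    father: Individual,
    mother: Individual,
    rng: np.random.Generator,
    params: RecombinationParams,
    variant_cms: np.ndarray,
    region_cm: tuple[float, float],
    child_id: str = "",
    sex: int = 0,
) -> Individual:
    """One offspring: an independent meiosis in each parent.

    gamete1 descends from the father, gamete2 from the mother.
    """
    if father.gamete1.shape != mother.gamete1.shape:
        raise ValueError("parents are defined over different variant sets")
    g1, t1 = meiosis(father, variant_cms, region_cm, params, rng)
    g2, t2 = meiosis(mother, variant_cms, region_cm, params, rng)
    return Individual(g1, g2, t1, t2, id=child_id, sex=sex)
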