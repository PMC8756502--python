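"""Shared domain types for admixture simulation and inference.

Coordinates follow VCF conventions: site positions are 1-based base pairs,
ancestry tracts are half-open ``[start, end)`` intervals in bp. Genetic
lengths are measured in centimorgans (cM) through a piecewise-linear
genetic map; 1 Morgan = 100 cM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: sentinel for a masked / missing allele in a haplotype array
MISSING = np.int8(-1)

#: label for windows whose ancestry posterior does not reach the certainty cutoff
UNKNOWN = "UNKNOWN"

TRACT_COLUMNS = ["haplotype_id", "chrom", "start", "end", "ancestry", "certainty"]


class ParameterError(ValueError):
    """Raised when a model parameter is outside its admissible range."""


@dataclass(frozen=True)
class SiteTable:
    """Biallelic sites shared by all panels and genomes of one study.

    Sites are stored in a single dense index across chromosomes;
    positions must be strictly increasing within a chromosome.
    """

    chrom: np.ndarray  # str per site
    pos: np.ndarray  # 1-based bp per site
    ref_allele: np.ndarray
    alt_allele: np.ndarray

    def __post_init__(self) -> None:
        for c in self.chromosomes:
            p = self.pos[self.chrom == c]
            if not np.all(np.diff(p) > 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def chromosomes(self) -> list[str]:
        # preserve first-appearance order
        return list(dict.fromkeys(self.chrom.tolist()))

    def chrom_slice(self, chrom: str) -> np.ndarray:
        """Indices of the sites on one chromosome."""
        return np.flatnonzero(self.chrom == chrom)


class GeneticMap:
    """Piecewise-linear genetic map, one anchor list per chromosome.

    Queries outside the anchor range are clamped to the boundary map value
    (extrapolation rate zero).
    """

    def __init__(self, anchors: dict[str, tuple[np.ndarray, np.ndarray]]):
        if not anchors:
            raise ValueError("empty genetic map")
        self.anchors = {}
        for chrom, (bp, cm) in anchors.items():
            bp = np.asarray(bp, dtype=float)
            cm = np.asarray(cm, dtype=float)
            if len(bp) < 2:
                raise ValueError(f"need >= 2 anchors on {chrom}")
            if np.any(np.diff(bp) <= 0) or np.any(np.diff(cm) < 0):
                raise ValueError(f"map anchors not monotone on {chrom}")
            self.anchors[chrom] = (bp, cm)

    @classmethod
    def uniform(cls, chrom_lengths: dict[str, int], cm_per_mb: float = 1.0) -> "GeneticMap":
        """Constant-rate map: ``cm_per_mb`` centimorgans per megabase."""
        return cls(
            {
                c: (np.array([1.0, float(n)]), np.array([0.0, (n - 1) * cm_per_mb / 1e6]))
                for c, n in chrom_lengths.items()
            }
        )

    def interpolate(self, chrom: str, pos) -> np.ndarray | float:
        """bp -> cM, clamped at the outermost anchors."""
        bp, cm = self.anchors[chrom]
        return np.interp(pos, bp, cm)

    def inverse(self, chrom: str, cm_query) -> np.ndarray | float:
        """cM -> bp (left inverse; flat map stretches resolve to leftmost bp)."""
        bp, cm = self.anchors[chrom]
        return np.interp(cm_query, cm, bp)

    def chrom_cm(self, chrom: str) -> float:
        """Total genetic length of one chromosome in cM."""
        bp, cm = self.anchors[chrom]
        return float(cm[-1] - cm[0])

    def chrom_bp_span(self, chrom: str) -> tuple[float, float]:
        bp, _ = self.anchors[chrom]
        return float(bp[0]), float(bp[-1])

    def tract_cm(self, chrom, start, end) -> np.ndarray:
        """Genetic length in cM of half-open bp tracts (vectorized per chromosome)."""
        chrom = np.asarray(chrom)
        start = np.asarray(start, dtype=float)
        end = np.asarray(end, dtype=float)
        out = np.empty(len(start))
        for c in np.unique(chrom):
            m = chrom == c
            out[m] = self.interpolate(c, end[m]) - self.interpolate(c, start[m])
        return out


@dataclass
class HaplotypePanel:
    """Phased haplotypes of one labeled reference population.

    ``haplotypes`` is an H x L binary matrix (0 = ref allele, 1 = alt)
    over the sites of a shared :class:`SiteTable`. H is even: haplotypes
    2i and 2i+1 belong to diploid individual i.
    """

    population_label: str
    haplotypes: np.ndarray
    role: str = "training"

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.shape[0] % 2:
            raise ValueError("panel must hold an even number of haplotypes (diploid source)")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[0] // 2

    def allele_frequencies(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)

    def split(self, training_fraction: float = 0.5) -> tuple["HaplotypePanel", "HaplotypePanel"]:
        """Deterministic training/validation split on individual boundaries."""
        n_train = 2 * max(1, int(round(self.n_individuals * training_fraction)))
        return (
            HaplotypePanel(self.population_label, self.haplotypes[:n_train], "training"),
            HaplotypePanel(self.population_label, self.haplotypes[n_train:], "validation"),
        )


def empty_tracts() -> pd.DataFrame:
    return pd.DataFrame(columns=TRACT_COLUMNS)


def validate_tracts(tracts: pd.DataFrame) -> None:
    """Check tract invariants: half-open, positive length, no overlap per haplotype."""
    if np.any(tracts["end"].to_numpy() <= tracts["start"].to_numpy()):
        raise ValueError("tract with end <= start")
    for (_, _), sub in tracts.groupby(["haplotype_id", "chrom"], sort=False):
        s = sub.sort_values("start")
        if np.any(s["start"].to_numpy()[1:] < s["end"].to_numpy()[:-1]):
            raise ValueError("overlapping tracts on one haplotype")


@dataclass
class AdmixedGenome:
    """One simulated or observed phased diploid genome.

    ``haplotypes`` maps haplotype id (``"<ind>.0"`` / ``"<ind>.1"``) to an
    int8 allele vector over the site table; :data:`MISSING` marks masked or
    absent sites (e.g. the second X copy of a male).
    """

    individual_id: str
    haplotypes: dict[str, np.ndarray]
    sex: str = "F"

    def genotypes(self) -> np.ndarray:
        """Diploid dosage vector (0/1/2); MISSING in either copy -> -1."""
        haps = list(self.haplotypes.values())
        g = np.sum(haps, axis=0, dtype=np.int16)
        bad = np.any([h == MISSING for h in haps], axis=0)
        g[bad] = -1
        return g


def simplex_check(p: np.ndarray, name: str = "proportions", atol: float = 1e-9) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any(p < -atol):
        raise ParameterError(f"{name} must be non-negative")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ParameterError(f"{name} must sum to 1 (got {p.sum():.6g})")
    return np.clip(p, 0.0, None)


@dataclass
class SimulationConfig:
    """World parameters for one synthetic study.

    Attributes
    ----------
    n_populations
        K, number of ancestral source populations.
    drift
        Per-population drift F_k in (0, 1): variance of population allele
        frequencies around the shared ancestral frequency under the
        Balding-Nichols parameterization.
    proportions
        Admixture proportion vector m on the simplex.
    generations
        g >= 1, generations since the single admixture pulse.
    n_sites
        Total biallelic sites across the genome.
    chrom_lengths
        bp length per chromosome; chromosome "X" (if present) is treated
        as the sex chromosome downstream.
    seed
        Mandatory; every random draw flows from it.
    """

    n_populations: int
    drift: tuple[float, ...]
    proportions: tuple[float, ...]
    generations: int
    n_sites: int
    chrom_lengths: dict[str, int]
    seed: int
    haplotypes_per_panel: int = 40
    cm_per_mb: float = 1.0
    population_labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ParameterError("seed is mandatory")
        if self.n_populations < 2:
            raise ParameterError("need at least two ancestral populations")
        if self.generations < 1:
            raise ParameterError("generations must be >= 1")
        if len(self.drift) != self.n_populations:
            raise ParameterError("one drift parameter per population")
        if any(not (0.0 < f < 1.0) for f in self.drift):
            raise ParameterError("drift parameters must lie in (0, 1)")
        self.proportions = tuple(simplex_check(np.array(self.proportions), "admixture proportions"))
        if not self.population_labels:
            self.population_labels = tuple(f"POP{k}" for k in range(self.n_populations))
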