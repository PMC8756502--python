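"""Synthetic admixture worlds: drifted founder panels, genetic maps, and
single-pulse admixed diploid genomes with known truth tracts.

The generative model
--------------------
Founder panels follow the Balding-Nichols construction: each site draws an
ancestral frequency p ~ Uniform(0.05, 0.95) and each population k draws its
own frequency from Beta(p (1-F_k)/F_k, (1-p)(1-F_k)/F_k), so F_k controls
how far panel k has drifted from the common ancestor. Haplotypes are
independent Bernoulli draws per site (no within-panel LD).

Admixed genomes follow a Markov single-pulse model: along each haploid
chromosome copy, recombination breakpoints form a Poisson process with rate
g per Morgan on the interpolated genetic map, each inter-breakpoint segment
draws its ancestry i.i.d. from the proportion vector m, and the segment's
alleles are copied from a uniformly chosen training haplotype of that
ancestry. Under this model the genetic length of a maximal same-ancestry
tract of component k is exponential with rate g (1 - m_k) per Morgan.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import (
    AdmixedGenome,
    GeneticMap,
    HaplotypePanel,
    ParameterError,
    SimulationConfig,
    SiteTable,
    TRACT_COLUMNS,
    simplex_check,
)

__all__ = [
    "build_site_table",
    "generate_founder_panels",
    "simulate_admixed_genome",
    "simulate_cohort",
    "generate_validation_cohort",
]


def build_site_table(chrom_lengths: dict[str, int], n_sites: int) -> SiteTable:
    """Evenly spaced biallelic sites, allocated to chromosomes by bp length."""
    total = sum(chrom_lengths.values())
    chroms, positions = [], []
    remaining = n_sites
    items = list(chrom_lengths.items())
    for i, (c, length) in enumerate(items):
        n_c = remaining if i == len(items) - 1 else max(1, round(n_sites * length / total))
        n_c = min(n_c, remaining)
        remaining -= n_c
        # keep sites strictly below the chromosome end so every site falls
        # inside some half-open [start, end) tract of the tiling
        pos = np.unique(np.linspace(1, length - 1, n_c).round().astype(np.int64))
        chroms.extend([c] * len(pos))
        positions.append(pos)
    pos = np.concatenate(positions)
    n = len(pos)
    return SiteTable(
        chrom=np.array(chroms),
        pos=pos,
        ref_allele=np.full(n, "A"),
        alt_allele=np.full(n, "G"),
    )


def generate_founder_panels(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[SiteTable, list[HaplotypePanel]]:
    """Draw K drifted founder panels over a fresh site table.

    Deterministic given ``config.seed``; pass ``rng`` to draw from an
    existing stream instead.
    """
    if config.n_sites < 1:
        raise ParameterError("need at least one site")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    sites = build_site_table(config.chrom_lengths, config.n_sites)
    L = sites.n_sites
    p_anc = rng.uniform(0.05, 0.95, size=L)
    panels = []
    for k in range(config.n_populations):
        F = config.drift[k]
        a = p_anc * (1.0 - F) / F
        b = (1.0 - p_anc) * (1.0 - F) / F
        f_k = rng.beta(a, b)
        haps = (rng.random((config.haplotypes_per_panel, L)) < f_k).astype(np.int8)
        panels.append(HaplotypePanel(config.population_labels[k], haps, "training"))
    return sites, panels


def _merge_segments(bounds_cm: np.ndarray, ancestry: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge adjacent same-ancestry segments; bounds has len(ancestry)+1 entries."""
    keep = np.flatnonzero(np.r_[True, ancestry[1:] != ancestry[:-1]])
    starts = bounds_cm[keep]
    ends = bounds_cm[np.r_[keep[1:], len(ancestry)]]
    return np.column_stack([starts, ends]), ancestry[keep]


def _draw_breakpoints(total_cm: float, g: int, rng: np.random.Generator) -> np.ndarray:
    """Segment bounds in cM: Poisson breakpoint process with rate g per Morgan."""
    n_break = rng.poisson(g * total_cm / 100.0)
    cuts = np.sort(rng.uniform(0.0, total_cm, size=n_break))
    return np.r_[0.0, cuts, total_cm]


def _assign_quota(lengths_cm: np.ndarray, m: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Assign segment ancestries so length shares match m as closely as the
    segmentation allows: longest segments first, each to the component with
    the largest remaining length deficit (random tie order)."""
    order = np.argsort(-lengths_cm + 1e-12 * rng.random(len(lengths_cm)))
    deficit = m * lengths_cm.sum()
    out = np.empty(len(lengths_cm), dtype=np.int64)
    for i in order:
        k = int(np.argmax(deficit))
        out[i] = k
        deficit[k] -= lengths_cm[i]
    return out


def _paint_segments_onto_sites(
    chrom: str,
    seg_bounds_cm: np.ndarray,
    seg_anc: np.ndarray,
    sites: SiteTable,
    gmap: GeneticMap,
    panels: dict[str, HaplotypePanel],
    labels: list[str],
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[tuple[float, float, str]]]:
    """Copy donor alleles segment by segment; returns the chromosome's allele
    vector and merged truth tracts as (start_bp, end_bp, ancestry)."""
    total_cm = gmap.chrom_cm(chrom)
    bp_lo, bp_hi = gmap.chrom_bp_span(chrom)
    merged_bounds, merged_anc = _merge_segments(seg_bounds_cm, seg_anc)
    idx = sites.chrom_slice(chrom)
    pos = sites.pos[idx]
    cm0 = float(gmap.interpolate(chrom, bp_lo))
    pos_cm = gmap.interpolate(chrom, pos) - cm0
    alleles = np.empty(len(idx), dtype=np.int8)
    tracts = []
    # donors switch at every raw breakpoint, ancestry only at merged bounds
    for j in range(len(seg_bounds_cm) - 1):
        s_cm, e_cm = seg_bounds_cm[j], seg_bounds_cm[j + 1]
        label = labels[seg_anc[j]]
        panel = panels[label]
        if panel.n_haplotypes == 0:
            raise ParameterError(f"no training haplotypes for ancestry {label}")
        donor = panel.haplotypes[rng.integers(panel.n_haplotypes)]
        in_seg = (pos_cm >= s_cm) & (pos_cm < e_cm) if e_cm < total_cm else (pos_cm >= s_cm)
        alleles[in_seg] = donor[idx][in_seg]
    for (s_cm, e_cm), a in zip(merged_bounds, merged_anc):
        start_bp = bp_lo if s_cm == 0.0 else float(gmap.inverse(chrom, cm0 + s_cm))
        end_bp = bp_hi if e_cm >= total_cm else float(gmap.inverse(chrom, cm0 + e_cm))
        if end_bp > start_bp:
            tracts.append((start_bp, end_bp, labels[a]))
    return alleles, tracts


def simulate_admixed_genome(
    panels: list[HaplotypePanel],
    config: SimulationConfig,
    sites: SiteTable,
    gmap: GeneticMap,
    rng: np.random.Generator | None = None,
    individual_id: str = "ind0",
    sex: str = "F",
    proportions_x: tuple[float, ...] | None = None,
    exact_proportions: bool = False,
) -> tuple[AdmixedGenome, pd.DataFrame]:
    """Simulate one phased diploid genome plus its truth tract set.

    ``proportions_x`` optionally replaces m on chromosome "X" (sex-biased
    founding: X lineages spend 2/3 of their time in females, so a female
    excess of one ancestry inflates that ancestry on X relative to the
    autosomes). Males (``sex="M"``) carry a single X copy; the second X
    haplotype simply has no sites there.

    With ``exact_proportions=True`` (the validation-cohort mode) segment
    ancestries are assigned by length quota per haploid genome instead of
    i.i.d. draws, so the genome's realized composition matches m up to the
    granularity of the segmentation. Tract lengths are then no longer
    exponential; use the default i.i.d. mode for timing studies.
    """
    if any(p.role != "training" for p in panels):
        raise ParameterError("admixed genomes must copy from training panels")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    m = simplex_check(np.array(config.proportions))
    labels = [p.population_label for p in panels]
    if len(labels) != len(m):
        raise ParameterError("one proportion per panel")
    panel_by_label = {p.population_label: p for p in panels}
    m_x = m if proportions_x is None else simplex_check(np.array(proportions_x))
    g = config.generations

    haps: dict[str, np.ndarray] = {}
    rows = []
    from .core import MISSING

    for copy in (0, 1):
        hap_id = f"{individual_id}.{copy}"
        allele_vec = np.full(sites.n_sites, MISSING, dtype=np.int8)
        chrom_bounds: dict[str, np.ndarray] = {}
        for chrom in sites.chromosomes:
            if chrom == "X" and sex == "M" and copy == 1:
                continue  # males carry one X
            chrom_bounds[chrom] = _draw_breakpoints(gmap.chrom_cm(chrom), g, rng)
        # ancestry assignment: i.i.d. per segment, or length quota per copy
        assignments: dict[str, np.ndarray] = {}
        autosomes = [c for c in chrom_bounds if c != "X"]
        if exact_proportions:
            lens = np.concatenate([np.diff(chrom_bounds[c]) for c in autosomes])
            anc = _assign_quota(lens, m, rng)
            off = 0
            for c in autosomes:
                n_seg = len(chrom_bounds[c]) - 1
                assignments[c] = anc[off:off + n_seg]
                off += n_seg
            if "X" in chrom_bounds:
                lens_x = np.diff(chrom_bounds["X"])
                assignments["X"] = _assign_quota(lens_x, m_x, rng)
        else:
            for c, bounds in chrom_bounds.items():
                p = m_x if c == "X" else m
                assignments[c] = rng.choice(len(labels), size=len(bounds) - 1, p=p)
        for chrom, bounds in chrom_bounds.items():
            alleles, tracts = _paint_segments_onto_sites(
                chrom, bounds, assignments[chrom], sites, gmap, panel_by_label, labels, rng
            )
            allele_vec[sites.chrom_slice(chrom)] = alleles
            for s, e, a in tracts:
                rows.append((hap_id, chrom, s, e, a, 1.0))
        haps[hap_id] = allele_vec
    genome = AdmixedGenome(individual_id, haps, sex=sex)
    tracts = pd.DataFrame(rows, columns=TRACT_COLUMNS)
    return genome, tracts


def simulate_cohort(
    panels: list[HaplotypePanel],
    config: SimulationConfig,
    sites: SiteTable,
    gmap: GeneticMap,
    n_genomes: int,
    rng: np.random.Generator | None = None,
    sexes: list[str] | None = None,
    proportions_x: tuple[float, ...] | None = None,
    prefix: str = "ind",
) -> tuple[list[AdmixedGenome], pd.DataFrame]:
    rng = np.random.default_rng(config.seed) if rng is None else rng
    genomes, tract_frames = [], []
    for i in range(n_genomes):
        sex = sexes[i] if sexes else "F"
        genome, tracts = simulate_admixed_genome(
            panels, config, sites, gmap, rng=rng,
            individual_id=f"{prefix}{i}", sex=sex, proportions_x=proportions_x,
        )
        genomes.append(genome)
        tract_frames.append(tracts)
    return genomes, pd.concat(tract_frames, ignore_index=True) if tract_frames else pd.DataFrame(columns=TRACT_COLUMNS)


def generate_validation_cohort(
    panels: list[HaplotypePanel],
    config: SimulationConfig,
    sites: SiteTable,
    gmap: GeneticMap,
    seed: int,
    genomes_per_point: int = 20,
    grid: np.ndarray | None = None,
) -> list[dict]:
    """Validation cohort over the focal-proportion grid 0.20..0.80 in 0.05 steps.

    For each focal region and each grid value q, the remaining 1-q is split
    evenly over the other regions and ``genomes_per_point`` genomes are
    simulated. Returns one record per genome with the expected proportions.
    """
    if len(panels) < 2:
        raise ParameterError("validation grid needs at least two regions")
    grid = np.round(np.arange(0.20, 0.801, 0.05), 10) if grid is None else np.asarray(grid)
    rng = np.random.default_rng(seed)
    labels = [p.population_label for p in panels]
    K = len(labels)
    cohort = []
    for focal_i, focal in enumerate(labels):
        for q in grid:
            expected = np.full(K, (1.0 - q) / (K - 1))
            expected[focal_i] = q
            cfg = SimulationConfig(
                n_populations=config.n_populations,
                drift=config.drift,
                proportions=tuple(expected),
                generations=config.generations,
                n_sites=config.n_sites,
                chrom_lengths=config.chrom_lengths,
                seed=config.seed,
                haplotypes_per_panel=config.haplotypes_per_panel,
                population_labels=config.population_labels,
            )
            for rep in range(genomes_per_point):
                gid = f"{focal}_q{int(round(q * 100)):02d}_r{rep}"
                genome, tracts = simulate_admixed_genome(
                    panels, cfg, sites, gmap, rng=rng, individual_id=gid,
                    exact_proportions=True,
                )
                cohort.append(
                    {
                        "individual_id": gid,
                        "focal_region": focal,
                        "expected": dict(zip(labels, expected)),
                        "genome": genome,
                        "truth_tracts": tracts,
                    }
                )
    return cohort
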