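import numpy as np
import pytest

from tractmix.core import GeneticMap, SimulationConfig
from tractmix.sim import generate_founder_panels


@pytest.fixture(scope="session")
def small_world():
    """Two well-drifted panels over a 2-chromosome genome (F=0.1, 4k sites)."""
    cfg = SimulationConfig(
        n_populations=2,
        drift=(0.1, 0.1),
        proportions=(0.5, 0.5),
        generations=10,
        n_sites=4000,
        chrom_lengths={"1": 50_000_000, "2": 50_000_000},
        seed=101,
        haplotypes_per_panel=40,
        population_labels=("AFR", "EUR"),
    )
    sites, panels = generate_founder_panels(cfg)
    gmap = GeneticMap.uniform(cfg.chrom_lengths)  # ~50 cM per chromosome
    return cfg, sites, panels, gmap


@pytest.fixture(scope="session")
def morgan_world():
    """Ten 1-Morgan chromosomes: the tract-length / timing test genome."""
    cfg = SimulationConfig(
        n_populations=2,
        drift=(0.1, 0.1),
        proportions=(0.5, 0.5),
        generations=10,
        n_sites=2000,
        chrom_lengths={str(c): 1_000_000 for c in range(1, 11)},
        seed=202,
        haplotypes_per_panel=20,
        population_labels=("A", "B"),
    )
    sites, panels = generate_founder_panels(cfg)
    gmap = GeneticMap.uniform(cfg.chrom_lengths, cm_per_mb=100.0)
    return cfg, sites, panels, gmap


@pytest.fixture(scope="session")
def x_world():
    """Eight 1-Morgan autosomes plus a 1.5-Morgan X chromosome."""
    cfg = SimulationConfig(
        n_populations=2,
        drift=(0.1, 0.1),
        proportions=(0.5, 0.5),
        generations=10,
        n_sites=3000,
        chrom_lengths={**{str(c): 1_000_000 for c in range(1, 9)}, "X": 1_500_000},
        seed=303,
        haplotypes_per_panel=20,
        population_labels=("A", "B"),
    )
    sites, panels = generate_founder_panels(cfg)
    gmap = GeneticMap.uniform(cfg.chrom_lengths, cm_per_mb=100.0)
    return cfg, sites, panels, gmap
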