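"""Founder-panel and admixed-genome simulation: drift calibration, map
interpolation, breakpoint process, truth-tract invariants."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tractmix.core import GeneticMap, ParameterError, SimulationConfig
from tractmix.popstats import FrequencyTable, hudson_fst
from tractmix.sim import (
    build_site_table,
    generate_founder_panels,
    generate_validation_cohort,
    simulate_admixed_genome,
    simulate_cohort,
)


def _cfg(**kw):
    base = dict(
        n_populations=2, drift=(0.1, 0.1), proportions=(0.5, 0.5), generations=10,
        n_sites=2000, chrom_lengths={"1": 10_000_000}, seed=1, haplotypes_per_panel=40,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestFounderPanels:
    def test_no_drift_limit(self):
        # F -> 0: panel frequencies collapse onto the shared ancestral ones
        cfg = _cfg(drift=(1e-6, 1e-6), n_sites=10_000, haplotypes_per_panel=200)
        _, panels = generate_founder_panels(cfg)
        fst, _ = hudson_fst(
            FrequencyTable.from_haplotypes("a", panels[0].haplotypes),
            FrequencyTable.from_haplotypes("b", panels[1].haplotypes),
        )
        assert abs(fst) < 0.005

    def test_fst_matches_drift_parameter(self):
        # brute-force-confirmed oracle: Hudson F_ST between two panels each
        # drifted by F concentrates at F itself (here F = 0.1)
        cfg = _cfg(n_sites=10_000, haplotypes_per_panel=100)
        _, panels = generate_founder_panels(cfg)
        fst, _ = hudson_fst(
            FrequencyTable.from_haplotypes("a", panels[0].haplotypes),
            FrequencyTable.from_haplotypes("b", panels[1].haplotypes),
        )
        assert 0.09 < fst < 0.11

    def test_determinism_same_seed(self):
        a = generate_founder_panels(_cfg())[1]
        b = generate_founder_panels(_cfg())[1]
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.haplotypes, pb.haplotypes)

    def test_invalid_drift_rejected(self):
        with pytest.raises(ParameterError):
            _cfg(drift=(0.0, 0.1))
        with pytest.raises(ParameterError):
            _cfg(drift=(1.0, 0.1))


class TestGeneticMap:
    def test_linear_midpoint_and_anchor_identity(self):
        gmap = GeneticMap({"1": (np.array([0, 1_000_000]), np.array([0.0, 1.0]))})
        assert gmap.interpolate("1", 500_000) == pytest.approx(0.5)
        assert gmap.interpolate("1", 1_000_000) == pytest.approx(1.0)

    def test_clamped_beyond_last_anchor(self):
        gmap = GeneticMap({"1": (np.array([0, 1_000_000]), np.array([0.0, 1.0]))})
        assert gmap.interpolate("1", 5_000_000) == pytest.approx(1.0)
        assert gmap.interpolate("1", -10) == pytest.approx(0.0)

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            GeneticMap({})

    def test_monotone(self):
        gmap = GeneticMap({"1": (np.array([0, 10, 1000]), np.array([0.0, 0.5, 0.5]))})
        q = np.linspace(0, 1000, 50)
        assert np.all(np.diff(gmap.interpolate("1", q)) >= 0)


class TestAdmixedGenome:
    def test_degenerate_proportions_single_ancestry(self, morgan_world):
        cfg, sites, panels, gmap = morgan_world
        cfg2 = _cfg(proportions=(1.0, 0.0), chrom_lengths=cfg.chrom_lengths,
                    n_sites=cfg.n_sites)
        _, tracts = simulate_admixed_genome(panels, cfg2, sites, gmap,
                                            rng=np.random.default_rng(4))
        assert set(tracts["ancestry"]) == {"A"}

    def test_truth_tracts_tile_each_haplotype(self, morgan_world):
        cfg, sites, panels, gmap = morgan_world
        _, tracts = simulate_admixed_genome(panels, cfg, sites, gmap,
                                            rng=np.random.default_rng(5))
        for (hap, chrom), sub in tracts.groupby(["haplotype_id", "chrom"]):
            s = sub.sort_values("start")
            lo, hi = gmap.chrom_bp_span(chrom)
            assert s["start"].iloc[0] == pytest.approx(lo)
            assert s["end"].iloc[-1] == pytest.approx(hi)
            np.testing.assert_allclose(s["end"].to_numpy()[:-1], s["start"].to_numpy()[1:])

    def test_tract_count_matches_switch_process(self, morgan_world):
        # g=10 on 10 one-Morgan chromosomes, m=(1/2,1/2): breakpoints are
        # Poisson(100) per haploid copy and each survives merging w.p. 1/2,
        # so E[tracts per copy] = 10 + 50
        cfg, sites, panels, gmap = morgan_world
        rng = np.random.default_rng(6)
        counts = []
        for i in range(100):
            _, tracts = simulate_admixed_genome(panels, cfg, sites, gmap, rng=rng,
                                                individual_id=f"i{i}")
            for hap, sub in tracts.groupby("haplotype_id"):
                counts.append(len(sub))
        mean = np.mean(counts)
        se = np.std(counts) / np.sqrt(len(counts))
        assert abs(mean - 60.0) < 3 * se + 1e-9

    def test_mean_ancestry_fraction_converges_to_m(self, morgan_world):
        cfg, sites, panels, gmap = morgan_world
        _, tracts = simulate_cohort(panels, cfg, sites, gmap, 100,
                                    rng=np.random.default_rng(7))
        tracts["len"] = tracts["end"] - tracts["start"]
        fracs = []
        for ind, sub in tracts.groupby(tracts["haplotype_id"].str.split(".").str[0]):
            fracs.append(sub.loc[sub["ancestry"] == "A", "len"].sum() / sub["len"].sum())
        fracs = np.array(fracs)
        se = fracs.std() / np.sqrt(len(fracs))
        assert abs(fracs.mean() - 0.5) < 3 * se

    def test_tract_lengths_exponential(self):
        # maximal same-ancestry tract length ~ Exp(g (1 - m_k)) per Morgan;
        # 10-Morgan chromosomes keep end-truncation negligible for the KS check
        cfg = _cfg(n_sites=500, chrom_lengths={"1": 10_000_000, "2": 10_000_000},
                   haplotypes_per_panel=8)
        sites, panels = generate_founder_panels(cfg)
        gmap = GeneticMap.uniform(cfg.chrom_lengths, cm_per_mb=100.0)
        _, tracts = simulate_cohort(panels, cfg, sites, gmap, 25,
                                    rng=np.random.default_rng(8))
        from tractmix.timing import collect_tract_lengths

        samp = collect_tract_lengths(tracts, gmap, "POP0")
        lengths = samp.lengths[~samp.censored]
        assert len(lengths) >= 2000
        rate = cfg.generations * (1 - 0.5)
        p = stats.kstest(lengths, "expon", args=(0, 1 / rate)).pvalue
        assert p > 0.01

    def test_same_rng_seed_bit_identical(self, morgan_world):
        cfg, sites, panels, gmap = morgan_world
        g1, t1 = simulate_admixed_genome(panels, cfg, sites, gmap,
                                         rng=np.random.default_rng(9))
        g2, t2 = simulate_admixed_genome(panels, cfg, sites, gmap,
                                         rng=np.random.default_rng(9))
        for h in g1.haplotypes:
            np.testing.assert_array_equal(g1.haplotypes[h], g2.haplotypes[h])
        pd.testing.assert_frame_equal(t1, t2)


class TestValidationCohort:
    def test_grid_shape_and_simplex(self, small_world):
        cfg, sites, panels, gmap = small_world
        cohort = generate_validation_cohort(panels, cfg, sites, gmap, seed=10,
                                            genomes_per_point=2)
        # 13 proportion levels x 2 genomes x 2 focal regions
        assert len(cohort) == 13 * 2 * 2
        for rec in cohort:
            assert sum(rec["expected"].values()) == pytest.approx(1.0)

    def test_even_split_of_remainder(self):
        cfg = _cfg(n_populations=4, drift=(0.1,) * 4, proportions=(0.25,) * 4,
                   n_sites=400, haplotypes_per_panel=8)
        sites, panels = generate_founder_panels(cfg)
        gmap = GeneticMap.uniform(cfg.chrom_lengths)
        cohort = generate_validation_cohort(panels, cfg, sites, gmap, seed=11,
                                            genomes_per_point=1, grid=np.array([0.80]))
        rec = next(r for r in cohort if r["focal_region"] == "POP0")
        others = [v for k, v in rec["expected"].items() if k != "POP0"]
        np.testing.assert_allclose(others, [0.2 / 3] * 3)

    def test_quota_assignment_hits_target(self, small_world):
        cfg, sites, panels, gmap = small_world
        genome, tracts = simulate_admixed_genome(
            panels, cfg, sites, gmap, rng=np.random.default_rng(12),
            exact_proportions=True,
        )
        tracts["len"] = tracts["end"] - tracts["start"]
        frac = tracts.loc[tracts["ancestry"] == "AFR", "len"].sum() / tracts["len"].sum()
        assert abs(frac - 0.5) < 0.05


def test_site_table_allocation():
    st = build_site_table({"1": 2_000_000, "2": 1_000_000}, 300)
    assert st.n_sites == 300
    assert len(st.chrom_slice("1")) == 200
    assert np.all(np.diff(st.pos[st.chrom_slice("2")]) > 0)
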