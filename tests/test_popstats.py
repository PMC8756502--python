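"""Hudson F_ST, neighbor joining, outgroup f3."""

import numpy as np
import pandas as pd
import pytest

from tractmix.core import ParameterError, SimulationConfig
from tractmix.popstats import (
    FrequencyTable,
    F3Result,
    fst_matrix,
    hudson_fst,
    neighbor_joining,
    outgroup_f3,
    to_newick,
    _bipartitions,
)
from tractmix.sim import generate_founder_panels


def _panel_freq_tables(drift, n_sites=10_000, seed=71, haps=100, k=2):
    cfg = SimulationConfig(
        n_populations=k, drift=tuple([drift] * k), proportions=tuple([1 / k] * k),
        generations=10, n_sites=n_sites, chrom_lengths={"1": 10_000_000},
        seed=seed, haplotypes_per_panel=haps,
    )
    _, panels = generate_founder_panels(cfg)
    return [FrequencyTable.from_haplotypes(p.population_label, p.haplotypes) for p in panels]


class TestHudsonFst:
    def test_identical_tables_near_zero(self):
        # literally identical tables leave only the -1/(n-1) sampling
        # correction, which vanishes for large n
        rng = np.random.default_rng(72)
        f = rng.uniform(0.05, 0.95, 10_000)
        a = FrequencyTable("a", f, 500)
        b = FrequencyTable("b", f, 500)
        raw, _ = hudson_fst(a, b)
        assert abs(raw) < 0.005

    def test_fixed_opposite_alleles_gives_one(self):
        a = FrequencyTable("a", np.zeros(100), 50)
        b = FrequencyTable("b", np.ones(100), 50)
        raw, _ = hudson_fst(a, b)
        assert raw == pytest.approx(1.0)

    def test_small_sample_rejected(self):
        with pytest.raises(ParameterError):
            FrequencyTable("a", np.full(10, 0.5), 1)

    def test_monotone_in_drift(self):
        # stronger drift -> larger F_ST, rank-perfect over replicates
        means = []
        for F in (0.02, 0.05, 0.1, 0.2):
            vals = [hudson_fst(*_panel_freq_tables(F, n_sites=5000, seed=s))[0]
                    for s in range(73, 78)]
            means.append(np.mean(vals))
        assert all(m2 > m1 for m1, m2 in zip(means, means[1:]))

    def test_resampled_population_concentrates_at_zero(self):
        rng = np.random.default_rng(79)
        f = rng.uniform(0.05, 0.95, 8000)
        haps = (rng.random((200, 8000)) < f).astype(np.int8)
        a = FrequencyTable.from_haplotypes("a", haps[:100])
        b = FrequencyTable.from_haplotypes("b", haps[100:])
        raw, _ = hudson_fst(a, b)
        assert abs(raw) < 0.005


def _random_tree_distances(n_taxa, rng):
    """Random binary tree via sequential edge attachment; returns the leaf
    distance matrix and the set of non-trivial bipartitions."""
    import networkx as nx

    G = nx.Graph()
    G.add_edge("L0", "x0", weight=rng.uniform(0.1, 1.0))
    G.add_edge("L1", "x0", weight=rng.uniform(0.1, 1.0))
    G.add_edge("L2", "x0", weight=rng.uniform(0.1, 1.0))
    next_internal = 1
    for i in range(3, n_taxa):
        u, v = list(G.edges())[rng.integers(G.number_of_edges())]
        w = G[u][v]["weight"]
        G.remove_edge(u, v)
        mid = f"x{next_internal}"
        next_internal += 1
        split = rng.uniform(0.2, 0.8)
        G.add_edge(u, mid, weight=w * split)
        G.add_edge(mid, v, weight=w * (1 - split))
        G.add_edge(f"L{i}", mid, weight=rng.uniform(0.1, 1.0))
    leaves = [f"L{i}" for i in range(n_taxa)]
    dist = dict(nx.all_pairs_dijkstra_path_length(G, weight="weight"))
    D = pd.DataFrame(
        [[0.0 if a == b else dist[a][b] for b in leaves] for a in leaves],
        index=leaves, columns=leaves,
    )
    # bipartitions: remove each internal edge, collect leaf side
    bps = set()
    labels = frozenset(leaves)
    for u, v in list(G.edges()):
        H = G.copy()
        H.remove_edge(u, v)
        import networkx as nx2

        comp = frozenset(x for x in nx2.node_connected_component(H, u) if x.startswith("L"))
        if 1 < len(comp) < n_taxa - 1:
            bps.add(min(comp, labels - comp, key=lambda s: (len(s), sorted(s))))
    return D, bps


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        # d(a,b)=3, d(a,c)=4, d(b,c)=5 -> branch lengths 1, 2, 3
        D = pd.DataFrame([[0, 3, 4], [3, 0, 5], [4, 5, 0]],
                         index=list("abc"), columns=list("abc"), dtype=float)
        tree, _ = neighbor_joining(D)
        lens = {t.name: t.length for t in tree.tips()}
        assert lens["a"] == pytest.approx(1.0)
        assert lens["b"] == pytest.approx(2.0)
        assert lens["c"] == pytest.approx(3.0)

    def test_additive_five_taxon_recovery(self):
        rng = np.random.default_rng(80)
        D, true_bps = _random_tree_distances(5, rng)
        tree, _ = neighbor_joining(D)
        labels = frozenset(D.index)
        assert _bipartitions(tree, labels) == true_bps
        for a in D.index:
            for b in D.index:
                if a < b:
                    assert tree.find(a).distance(tree.find(b)) == pytest.approx(
                        D.loc[a, b], abs=1e-9
                    )

    def test_random_trees_topology_recovery(self):
        # four-point-condition matrices: NJ must recover the topology
        rng = np.random.default_rng(81)
        for _ in range(12):
            n = int(rng.integers(4, 9))
            D, true_bps = _random_tree_distances(n, rng)
            tree, _ = neighbor_joining(D)
            assert _bipartitions(tree, frozenset(D.index)) == true_bps

    def test_star_tree_stable_tie_break(self):
        D = pd.DataFrame(1.0 - np.eye(4), index=list("abcd"), columns=list("abcd"))
        t1, _ = neighbor_joining(D)
        t2, _ = neighbor_joining(D)
        assert to_newick(t1) == to_newick(t2)

    def test_asymmetric_matrix_rejected(self):
        D = pd.DataFrame([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]],
                         index=list("abc"), columns=list("abc"), dtype=float)
        with pytest.raises(ParameterError):
            neighbor_joining(D)

    def test_bootstrap_support_on_clear_topology(self):
        tables = _panel_freq_tables(0.05, n_sites=3000, k=4, haps=60, seed=82)
        # make two pairs of close populations by halving drift distances
        D = fst_matrix(tables)
        tree, support = neighbor_joining(D, bootstrap_replicates=25,
                                         frequency_tables=tables, seed=83)
        assert all(0.0 <= v <= 1.0 for v in support.values())
        nwk = to_newick(tree, support)
        assert nwk.endswith(";")


class TestOutgroupF3:
    def _drifted_tables(self, seed=84):
        return _panel_freq_tables(0.1, n_sites=20_000, k=3, haps=80, seed=seed)

    def test_symmetry_in_a_b(self):
        o, a, b = self._drifted_tables()
        r1 = outgroup_f3(o, a, b)
        r2 = outgroup_f3(o, b, a)
        assert r1.f3 == pytest.approx(r2.f3)

    def test_self_comparison_near_zero(self):
        # f3(O; O-sample, B): no drift shared exclusively by the pair beyond
        # the corrected outgroup sampling noise
        rng = np.random.default_rng(85)
        f = rng.uniform(0.05, 0.95, 20_000)
        haps = (rng.random((160, 20_000)) < f).astype(np.int8)
        o = FrequencyTable.from_haplotypes("o", haps[:80])
        a = FrequencyTable.from_haplotypes("a", haps[80:])  # same population
        b = FrequencyTable("b", np.clip(f + rng.normal(0, 0.1, f.size), 0, 1), 80)
        res = outgroup_f3(o, a, b)
        assert abs(res.f3) < 3 * res.se

    def test_shared_branch_increases_f3(self):
        # A,B sharing drift off O score higher than A,B split at the root
        rng = np.random.default_rng(86)
        L = 20_000
        p = rng.uniform(0.1, 0.9, L)

        def drift(freq, F):
            a = freq * (1 - F) / F
            return rng.beta(a, (1 - freq) * (1 - F) / F)

        shared = drift(p, 0.05)  # internal branch shared by A and B
        scenarios = []
        for ab_from in (shared, None):
            base_a = ab_from if ab_from is not None else p
            base_b = ab_from if ab_from is not None else p
            fa, fb, fo = drift(base_a, 0.05), drift(base_b, 0.05), drift(p, 0.05)
            res = outgroup_f3(
                FrequencyTable("O", fo, 100),
                FrequencyTable("A", fa, 100),
                FrequencyTable("B", fb, 100),
            )
            scenarios.append(res)
        close, far = scenarios
        assert close.f3 - far.f3 > 3 * np.hypot(close.se, far.se)

    def test_too_few_sites_flags_se(self):
        o = FrequencyTable("o", np.full(100, 0.5), 10)
        a = FrequencyTable("a", np.full(100, 0.4), 10)
        b = FrequencyTable("b", np.full(100, 0.6), 10)
        res = outgroup_f3(o, a, b, block_size_sites=500)
        assert not res.se_defined

    def test_jackknife_se_shrinks_with_blocks(self):
        rng = np.random.default_rng(87)

        def make(L):
            f = rng.uniform(0.1, 0.9, L)
            return (FrequencyTable("o", np.clip(f + rng.normal(0, 0.05, L), 0, 1), 50),
                    FrequencyTable("a", np.clip(f + rng.normal(0, 0.05, L), 0, 1), 50),
                    FrequencyTable("b", np.clip(f + rng.normal(0, 0.05, L), 0, 1), 50))

        se_small = outgroup_f3(*make(5_000), block_size_sites=250).se
        se_large = outgroup_f3(*make(20_000), block_size_sites=250).se
        assert 1.3 < se_small / se_large < 3.2  # ~2 expected for 4x the blocks
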