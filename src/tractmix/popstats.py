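"""Population comparison statistics: Hudson F_ST, neighbor-joining trees
with site bootstrap, and the outgroup f3 statistic with block-jackknife
standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj

from .core import ParameterError


@dataclass
class FrequencyTable:
    """Alt-allele frequencies and haploid sample size of one population."""

    population_label: str
    freq: np.ndarray
    n: int  # haploid sample size

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        if self.n < 2:
            raise ParameterError("haploid sample size must be >= 2")
        if np.any((self.freq < 0) | (self.freq > 1)):
            raise ParameterError("frequencies must lie in [0, 1]")

    @classmethod
    def from_haplotypes(cls, label: str, haplotypes: np.ndarray) -> "FrequencyTable":
        haps = np.asarray(haplotypes)
        return cls(label, haps.mean(axis=0), haps.shape[0])


def hudson_fst(
    a: FrequencyTable, b: FrequencyTable, site_mask: np.ndarray | None = None
) -> tuple[float, float]:
    """Hudson F_ST as a ratio of averages.

    Per site j: N_j = (p_a - p_b)^2 - p_a(1-p_a)/(n_a-1) - p_b(1-p_b)/(n_b-1)
    and D_j = p_a(1-p_b) + p_b(1-p_a); the estimate is sum(N)/sum(D) over
    sites polymorphic in at least one population. Returns (raw, clamped)
    where the clamped value is max(raw, 0) for use as a distance.
    """
    pa, pb = a.freq, b.freq
    if site_mask is not None:
        pa, pb = pa[site_mask], pb[site_mask]
    poly = ~(((pa == 0) & (pb == 0)) | ((pa == 1) & (pb == 1)))
    pa, pb = pa[poly], pb[poly]
    if len(pa) == 0:
        raise ParameterError("no polymorphic sites shared by the two populations")
    num = (pa - pb) ** 2 - pa * (1 - pa) / (a.n - 1) - pb * (1 - pb) / (b.n - 1)
    den = pa * (1 - pb) + pb * (1 - pa)
    raw = float(num.sum() / den.sum())
    return raw, max(raw, 0.0)


def fst_matrix(
    tables: list[FrequencyTable], site_mask: np.ndarray | None = None
) -> pd.DataFrame:
    """Symmetric pairwise F_ST matrix (clamped to >= 0, zero diagonal)."""
    labels = [t.population_label for t in tables]
    n = len(tables)
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, clamped = hudson_fst(tables[i], tables[j], site_mask)
            M[i, j] = M[j, i] = clamped
    return pd.DataFrame(M, index=labels, columns=labels)


def _bipartitions(tree: TreeNode, labels: frozenset[str]) -> set[frozenset[str]]:
    """Non-trivial unrooted splits of a tree, canonicalized to the smaller side."""
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = labels - side
        if 1 < len(side) < len(labels) - 1:
            out.add(min(side, other, key=lambda s: (len(s), sorted(s))))
    return out


def neighbor_joining(
    distances: pd.DataFrame,
    bootstrap_replicates: int = 0,
    frequency_tables: list[FrequencyTable] | None = None,
    seed: int | None = None,
) -> tuple[TreeNode, dict[frozenset[str], float]]:
    """Canonical neighbor joining on a distance matrix.

    With ``bootstrap_replicates`` > 0 and per-site ``frequency_tables``
    supplied, sites are resampled with replacement, the F_ST matrix and the
    tree recomputed, and each internal split's support reported as its
    frequency across replicates.
    """
    if distances.shape[0] < 3:
        raise ParameterError("neighbor joining needs at least 3 populations")
    M = distances.to_numpy()
    if not np.allclose(M, M.T):
        raise ParameterError("distance matrix must be symmetric")
    dm = DistanceMatrix((M + M.T) / 2.0, ids=list(distances.index))
    tree = nj(dm)
    support: dict[frozenset[str], float] = {}
    if bootstrap_replicates > 0:
        if frequency_tables is None:
            raise ParameterError("bootstrap requires per-site frequency tables")
        rng = np.random.default_rng(seed)
        labels = frozenset(distances.index)
        target = _bipartitions(tree, labels)
        counts = {bp: 0 for bp in target}
        L = len(frequency_tables[0].freq)
        for _ in range(bootstrap_replicates):
            idx = rng.integers(0, L, size=L)
            rep_tables = [
                FrequencyTable(t.population_label, t.freq[idx], t.n) for t in frequency_tables
            ]
            rep_tree = nj(DistanceMatrix(fst_matrix(rep_tables).to_numpy(), ids=list(distances.index)))
            for bp in _bipartitions(rep_tree, labels) & set(counts):
                counts[bp] += 1
        support = {bp: c / bootstrap_replicates for bp, c in counts.items()}
    return tree, support


def to_newick(tree: TreeNode, support: dict[frozenset[str], float] | None = None) -> str:
    """Newick string with 6-decimal branch lengths and bootstrap support
    (fraction) as internal node labels."""
    t = tree.copy()
    labels = frozenset(tip.name for tip in t.tips())
    if support:
        for node in t.non_tips(include_self=False):
            side = frozenset(x.name for x in node.tips())
            key = min(side, labels - side, key=lambda s: (len(s), sorted(s)))
            if key in support:
                node.name = f"{support[key]:.2f}"
    for node in t.traverse():
        if node.length is not None:
            node.length = round(node.length, 6)
    import io

    buf = io.StringIO()
    t.write(buf, format="newick")
    return buf.getvalue().strip()


@dataclass
class F3Result:
    outgroup: str
    pair: tuple[str, str]
    f3: float
    se: float
    z: float
    n_blocks: int
    se_defined: bool = True


def outgroup_f3(
    outgroup: FrequencyTable,
    a: FrequencyTable,
    b: FrequencyTable,
    block_size_sites: int = 500,
) -> F3Result:
    """f3(O; A, B): shared drift of A and B relative to outgroup O.

    Per site: (p_o - p_a)(p_o - p_b) - p_o(1 - p_o)/(n_o - 1); the second
    term removes the bias from sampling the outgroup frequency. The standard
    error comes from a block jackknife over contiguous site blocks.
    """
    po, pa, pb = outgroup.freq, a.freq, b.freq
    terms = (po - pa) * (po - pb) - po * (1 - po) / (outgroup.n - 1)
    f3 = float(terms.mean())
    L = len(terms)
    n_blocks = L // block_size_sites
    if n_blocks < 2:
        return F3Result(outgroup.population_label, (a.population_label, b.population_label),
                        f3, float("nan"), float("nan"), n_blocks, se_defined=False)
    edges = np.linspace(0, L, n_blocks + 1).round().astype(int)
    total = terms.sum()
    loo = np.array([
        (total - terms[edges[i]:edges[i + 1]].sum()) / (L - (edges[i + 1] - edges[i]))
        for i in range(n_blocks)
    ])
    se = float(np.sqrt((n_blocks - 1) / n_blocks * np.sum((loo - loo.mean()) ** 2)))
    z = f3 / se if se > 0 else float("inf")
    return F3Result(outgroup.population_label, (a.population_label, b.population_label),
                    f3, se, z, n_blocks)
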