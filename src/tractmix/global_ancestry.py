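"""Genome-wide (global) ancestry: supervised fraction estimation, admixture
entropy, kinship-based sample exclusion, and PCA.

Supervised ancestry fractions maximize the binomial composite likelihood

    L(q) = sum_j [ g_j log(sum_k q_k f_kj) + (2 - g_j) log(sum_k q_k (1 - f_kj)) ]

over the simplex, where g_j is the diploid alt-allele dosage at site j and
f_kj the alt frequency of reference population k. The EM update treats each
of the 2 allele draws at a site as a mixture observation; the likelihood is
non-decreasing every iteration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ParameterError

FREQ_EPS = 1e-4
EM_TOL = 1e-7
EM_MAX_ITER = 2000


@dataclass
class AncestryFractions:
    """Per-individual simplex vectors over K ancestry components."""

    fractions: pd.DataFrame  # index = individual id, columns = component labels
    identifiable: bool = True

    def population_mean(self) -> np.ndarray:
        return self.fractions.mean(axis=0).to_numpy()


def _em_single(g: np.ndarray, F: np.ndarray, Fc: np.ndarray) -> tuple[np.ndarray, float]:
    """EM for one individual. g: dosage (L,), F: K x L alt freqs (clipped)."""
    K, L = F.shape
    q = np.full(K, 1.0 / K)
    prev_ll = -np.inf
    for _ in range(EM_MAX_ITER):
        num_alt = q[:, None] * F  # K x L
        num_ref = q[:, None] * Fc
        s_alt = num_alt.sum(axis=0)
        s_ref = num_ref.sum(axis=0)
        ll = float(np.dot(g, np.log(s_alt)) + np.dot(2.0 - g, np.log(s_ref)))
        if ll < prev_ll - 1e-9:  # monotonicity guard
            raise AssertionError("EM log-likelihood decreased")
        if ll - prev_ll < EM_TOL:
            break
        prev_ll = ll
        # expected ancestry assignments of the 2L allele draws
        resp = num_alt / s_alt @ g + num_ref / s_ref @ (2.0 - g)
        q = resp / (2.0 * L)
        q = np.clip(q, 0.0, None)
        q /= q.sum()
    return q, ll


def estimate_ancestry_fractions(
    genotypes: np.ndarray,
    panel_frequencies: np.ndarray,
    individual_ids: list[str] | None = None,
    component_labels: list[str] | None = None,
) -> AncestryFractions:
    """Supervised ancestry fractions for each individual.

    Parameters
    ----------
    genotypes
        n x L diploid dosage matrix (0/1/2; -1 = missing, dropped per individual).
    panel_frequencies
        K x L alt-allele frequencies of the reference panels.
    """
    G = np.atleast_2d(np.asarray(genotypes, dtype=float))
    F = np.clip(np.asarray(panel_frequencies, dtype=float), FREQ_EPS, 1.0 - FREQ_EPS)
    K, L = F.shape
    poly = np.ptp(F, axis=0) > 10 * FREQ_EPS
    identifiable = bool(poly.any())
    mono = (F <= 2 * FREQ_EPS).all(axis=0) | (F >= 1 - 2 * FREQ_EPS).all(axis=0)
    if mono.all():
        raise ParameterError("all sites monomorphic across panels: ancestry unidentifiable")
    if not identifiable:
        warnings.warn("reference panels are indistinguishable; fractions not identifiable")
    ids = individual_ids or [f"ind{i}" for i in range(G.shape[0])]
    labels = component_labels or [f"POP{k}" for k in range(K)]
    rows = []
    for i in range(G.shape[0]):
        ok = G[i] >= 0
        q, _ = _em_single(G[i, ok], F[:, ok], 1.0 - F[:, ok])
        rows.append(q)
    out = pd.DataFrame(rows, index=ids, columns=labels)
    return AncestryFractions(out, identifiable=identifiable)


def admixture_entropy(mean_fractions, base: float = 2.0) -> float:
    """Shannon entropy S = -sum_i p_i log(p_i) of mean ancestry fractions.

    The convention 0*log(0) = 0 applies; base 2 reports bits, which is the
    scale on which a uniform 4-component mixture scores 2.0.
    """
    p = np.asarray(mean_fractions, dtype=float)
    if np.any(p < 0):
        raise ParameterError("fractions must be non-negative")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ParameterError("fractions must sum to 1")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum() / np.log(base))


@dataclass
class KinshipRecord:
    id_a: str
    id_b: str
    phi: float
    n_informative: int
    reliable: bool


def king_robust_kinship(g_a: np.ndarray, g_b: np.ndarray) -> tuple[float, int]:
    """KING-robust between-family kinship estimate from two dosage vectors.

    phi = (N_het,het - 2 * N_opposite_hom) / (N_het(a) + N_het(b)),
    counted over sites where both genotypes are observed. Duplicates and MZ
    twins score ~0.5, unrelated pairs ~0.
    """
    ok = (g_a >= 0) & (g_b >= 0)
    a, b = g_a[ok], g_b[ok]
    het_a = a == 1
    het_b = b == 1
    n_hethet = int(np.sum(het_a & het_b))
    n_ibs0 = int(np.sum(((a == 0) & (b == 2)) | ((a == 2) & (b == 0))))
    denom = int(het_a.sum() + het_b.sum())
    n_inf = int(ok.sum())
    if denom == 0:
        return 0.0, n_inf
    return (n_hethet - 2.0 * n_ibs0) / denom, n_inf


def kinship_filter(
    genotypes: np.ndarray,
    individual_ids: list[str],
    threshold: float = 0.25,
    min_informative: int = 100,
) -> tuple[list[str], list[KinshipRecord]]:
    """Greedily exclude one member of each pair with kinship above threshold.

    Pairs with fewer than ``min_informative`` jointly observed sites are
    flagged unreliable and never trigger an exclusion. Removal order: the
    pair with the largest phi first; within a pair, drop the member with
    more missing genotypes, ties broken toward the lexicographically later id.
    """
    G = np.asarray(genotypes)
    n = G.shape[0]
    if n < 1:
        raise ParameterError("need at least one individual")
    records = []
    flagged = []
    for i in range(n):
        for j in range(i + 1, n):
            phi, n_inf = king_robust_kinship(G[i], G[j])
            reliable = n_inf >= min_informative
            rec = KinshipRecord(individual_ids[i], individual_ids[j], phi, n_inf, reliable)
            records.append(rec)
            if reliable and phi > threshold:
                flagged.append(rec)
    missingness = {individual_ids[i]: int(np.sum(G[i] < 0)) for i in range(n)}
    removed: set[str] = set()
    for rec in sorted(flagged, key=lambda r: -r.phi):
        if rec.id_a in removed or rec.id_b in removed:
            continue
        pair = sorted([rec.id_a, rec.id_b], key=lambda s: (missingness[s], s))
        removed.add(pair[-1])
    retained = [s for s in individual_ids if s not in removed]
    return retained, records


def pca_genotypes(
    genotypes: np.ndarray, individual_ids: list[str] | None = None, n_components: int | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of the frequency-standardized genotype matrix.

    Each site is centered by twice its sample frequency and scaled by
    sqrt(p(1-p)); monomorphic sites are dropped. Returns per-individual PC
    coordinates and the explained-variance vector (non-increasing).
    """
    G = np.asarray(genotypes, dtype=float)
    if G.ndim != 2 or G.shape[1] < 1:
        raise ParameterError("need a non-empty genotype matrix")
    p = G.mean(axis=0) / 2.0
    keep = (p > 0) & (p < 1)
    if not keep.any():
        raise ParameterError("no polymorphic sites")
    X = (G[:, keep] - 2 * p[keep]) / np.sqrt(p[keep] * (1 - p[keep]))
    X -= X.mean(axis=0)
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    var = s**2 / max(1, X.shape[0] - 1)
    k = n_components or min(10, len(s))
    ids = individual_ids or [f"ind{i}" for i in range(G.shape[0])]
    coords = pd.DataFrame(
        U[:, :k] * s[:k], index=ids, columns=[f"PC{i + 1}" for i in range(k)]
    )
    return coords, var[:k]
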