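"""Local ancestry: windowed haplotype classification with a certainty
threshold, ancestry-specific masking, and chromosome-set ancestry fractions.

The classifier is a transparent windowed naive-Bayes: within each window of
consecutive sites, a haplotype's log-likelihood under each reference
population treats sites as independent Bernoulli draws from that panel's
allele frequencies. With a uniform prior the posterior is the softmax of the
log-likelihoods; a window is labeled only when the winning posterior reaches
the certainty threshold (default 0.95), otherwise it stays UNKNOWN. Adjacent
same-label windows merge into tracts carrying the minimum window certainty.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    GeneticMap,
    HaplotypePanel,
    MISSING,
    SiteTable,
    TRACT_COLUMNS,
    UNKNOWN,
)

FREQ_EPS = 1e-4


def _window_bounds(n_sites: int, window_sites: int) -> list[tuple[int, int]]:
    if n_sites <= window_sites:
        return [(0, n_sites)]
    n_win = n_sites // window_sites
    edges = np.linspace(0, n_sites, n_win + 1).round().astype(int)
    return list(zip(edges[:-1], edges[1:]))


def infer_local_ancestry(
    haplotypes: dict[str, np.ndarray],
    panels: list[HaplotypePanel],
    sites: SiteTable,
    window_sites: int = 50,
    certainty: float = 0.95,
) -> pd.DataFrame:
    """Assign ancestry labels to haplotype windows; returns a tract table.

    Tracts tile each chromosome exactly: the first window starts at the
    chromosome's first anchor coordinate 0 and window boundaries fall on the
    position of the first site of the next window.
    """
    if window_sites < 5:
        raise ValueError("window_sites must be >= 5")
    labels = [p.population_label for p in panels]
    F = np.clip(
        np.stack([p.allele_frequencies() for p in panels]), FREQ_EPS, 1.0 - FREQ_EPS
    )
    logF, logFc = np.log(F), np.log(1.0 - F)
    rows = []
    for hap_id, hap in haplotypes.items():
        for chrom in sites.chromosomes:
            idx = sites.chrom_slice(chrom)
            h = hap[idx]
            if np.all(h == MISSING):
                continue
            pos = sites.pos[idx]
            chrom_end = float(pos[-1]) + 1  # last site stays inside the half-open tiling
            wins = _window_bounds(len(idx), window_sites)
            win_label, win_cert = [], []
            for a, b in wins:
                hw = h[a:b]
                obs = hw != MISSING
                if not obs.any():
                    win_label.append(UNKNOWN)
                    win_cert.append(0.0)
                    continue
                sub = idx[a:b][obs]
                hv = hw[obs].astype(float)
                ll = logF[:, sub] @ hv + logFc[:, sub] @ (1.0 - hv)
                ll -= ll.max()
                post = np.exp(ll)
                post /= post.sum()
                k = int(np.argmax(post))
                if post[k] >= certainty:
                    win_label.append(labels[k])
                    win_cert.append(float(post[k]))
                else:
                    win_label.append(UNKNOWN)
                    win_cert.append(float(post[k]))
            # windows -> bp intervals tiling [0, chrom_end)
            starts = [0.0] + [float(pos[b]) for _, b in wins[:-1]]
            ends = [float(pos[b]) for _, b in wins[:-1]] + [chrom_end]
            cur: list | None = None  # [hap_id, chrom, start, end, label, certainty]
            for s, e, lab, c in zip(starts, ends, win_label, win_cert):
                if cur is not None and cur[4] == lab:
                    cur[3] = e
                    cur[5] = min(cur[5], c)
                else:
                    if cur is not None:
                        rows.append(tuple(cur))
                    cur = [hap_id, chrom, s, e, lab, c]
            if cur is not None:
                rows.append(tuple(cur))
    out = pd.DataFrame(rows, columns=["haplotype_id", "chrom", "start", "end", "ancestry", "certainty"])
    return out[TRACT_COLUMNS]


@dataclass
class MaskedGenome:
    """A phased genome reduced to one ancestry's haplotype segments."""

    individual_id: str
    target_ancestry: str
    haplotypes: dict[str, np.ndarray]
    retained_sites: dict[str, np.ndarray]  # hap id -> bool over sites


def mask_genome(
    haplotypes: dict[str, np.ndarray],
    tracts: pd.DataFrame,
    target_ancestry: str,
    sites: SiteTable,
    individual_id: str = "",
) -> MaskedGenome:
    """Keep sites inside target-ancestry tracts; everything else (including
    UNKNOWN tracts) becomes MISSING."""
    if target_ancestry not in set(tracts["ancestry"]):
        warnings.warn(f"ancestry {target_ancestry!r} absent from tracts: masked genome is empty")
    masked, retained = {}, {}
    for hap_id, hap in haplotypes.items():
        keep = np.zeros(sites.n_sites, dtype=bool)
        sub = tracts[(tracts["haplotype_id"] == hap_id) & (tracts["ancestry"] == target_ancestry)]
        for _, t in sub.iterrows():
            idx = sites.chrom_slice(t["chrom"])
            pos = sites.pos[idx]
            keep[idx[(pos >= t["start"]) & (pos < t["end"])]] = True
        out = np.where(keep, hap, MISSING).astype(np.int8)
        masked[hap_id] = out
        retained[hap_id] = keep
    return MaskedGenome(individual_id, target_ancestry, masked, retained)


def chromosome_ancestry_fractions(
    tracts: pd.DataFrame,
    gmap: GeneticMap,
    chroms: set[str] | list[str],
    unit: str = "cM",
) -> dict[str, float]:
    """Per-ancestry fraction of labeled genetic length on a chromosome set.

    UNKNOWN tracts are excluded from the denominator. Returns an empty dict
    (flagged by the caller) when no labeled length exists.
    """
    sub = tracts[tracts["chrom"].isin(set(chroms)) & (tracts["ancestry"] != UNKNOWN)]
    if sub.empty:
        warnings.warn("no labeled tracts on requested chromosomes; fractions undefined")
        return {}
    if unit == "cM":
        lengths = gmap.tract_cm(sub["chrom"].to_numpy(), sub["start"].to_numpy(), sub["end"].to_numpy())
    elif unit == "bp":
        lengths = (sub["end"] - sub["start"]).to_numpy(dtype=float)
    else:
        raise ValueError("unit must be 'cM' or 'bp'")
    total = lengths.sum()
    if total <= 0:
        warnings.warn("zero labeled genetic length; fractions undefined")
        return {}
    out: dict[str, float] = {}
    for anc, grp_len in zip(sub["ancestry"], lengths):
        out[anc] = out.get(anc, 0.0) + grp_len
    return {k: v / total for k, v in out.items()}
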