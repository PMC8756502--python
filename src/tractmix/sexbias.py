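"""Sex-biased admixture: the ΔAdmix statistic comparing X-chromosome and
autosomal ancestry fractions.

X chromosomes spend two thirds of their history in females, so an ancestry
contributed preferentially by founding females is enriched on X relative to
the autosomes. For one ancestry component,

    ΔAdmix = F_total * (F_X - F_auto) / (F_X + F_auto)

with F_total, F_X, F_auto the genome-wide, X and autosomal fractions of
that ancestry. Positive values indicate female-biased, negative values
male-biased admixture; when F_X + F_auto = 0 the statistic is defined as 0
(no information, no bias).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GeneticMap, ParameterError
from .local_ancestry import chromosome_ancestry_fractions


@dataclass
class DeltaAdmixRecord:
    individual_id: str
    ancestry_label: str
    f_total: float
    f_x: float
    f_auto: float
    delta: float


def delta_admix(f_total: float, f_x: float, f_auto: float) -> float:
    for name, v in (("F_total", f_total), ("F_X", f_x), ("F_auto", f_auto)):
        if not (0.0 <= v <= 1.0):
            raise ParameterError(f"{name} must lie in [0, 1], got {v}")
    denom = f_x + f_auto
    if denom == 0.0:
        return 0.0
    return f_total * (f_x - f_auto) / denom


def cohort_delta_admix(
    tracts_by_individual: dict[str, pd.DataFrame],
    gmap: GeneticMap,
    x_chrom: str = "X",
) -> tuple[list[DeltaAdmixRecord], pd.Series]:
    """ΔAdmix per individual per ancestry, plus per-ancestry medians.

    Fractions come from labeled tract genetic lengths (cM): F_auto over the
    autosomes, F_X over the X tracts present for the individual (both copies
    for females, the single copy for males — whatever tracts exist), and
    F_total over everything. Individuals with no X tracts are skipped.
    """
    records: list[DeltaAdmixRecord] = []
    for ind, tracts in tracts_by_individual.items():
        chroms = set(tracts["chrom"])
        if x_chrom not in chroms:
            warnings.warn(f"individual {ind} has no X-chromosome tracts; skipped")
            continue
        autosomes = chroms - {x_chrom}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f_x = chromosome_ancestry_fractions(tracts, gmap, {x_chrom})
            f_auto = chromosome_ancestry_fractions(tracts, gmap, autosomes)
            f_tot = chromosome_ancestry_fractions(tracts, gmap, chroms)
        if not f_x or not f_auto:
            warnings.warn(f"individual {ind} lacks labeled X or autosomal tracts; skipped")
            continue
        for anc in sorted(set(f_tot)):
            d = delta_admix(f_tot.get(anc, 0.0), f_x.get(anc, 0.0), f_auto.get(anc, 0.0))
            records.append(
                DeltaAdmixRecord(ind, anc, f_tot.get(anc, 0.0), f_x.get(anc, 0.0),
                                 f_auto.get(anc, 0.0), d)
            )
    if not records:
        return records, pd.Series(dtype=float)
    df = pd.DataFrame([r.__dict__ for r in records])
    medians = df.groupby("ancestry_label")["delta"].median()
    return records, medians


def records_to_frame(records: list[DeltaAdmixRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records]) if records else pd.DataFrame(
        columns=["individual_id", "ancestry_label", "f_total", "f_x", "f_auto", "delta"]
    )
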