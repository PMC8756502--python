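"""Readers and writers for the package's on-disk formats.

Phased genotypes travel as uncompressed VCF (GT with "|"), ancestry tracts
as BED-like TSV (haplotype_id, chrom, start, end, ancestry, certainty),
genetic maps as 3-column TSV (chrom, bp, cM), and frequency / Q-matrix /
report tables as plain TSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import AdmixedGenome, GeneticMap, MISSING, SiteTable, TRACT_COLUMNS


def write_vcf(path, sites: SiteTable, genomes: list[AdmixedGenome]) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in sites.chromosomes:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        ids = [g.individual_id for g in genomes]
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(ids) + "\n")
        haps = [list(g.haplotypes.values()) for g in genomes]
        for j in range(sites.n_sites):
            calls = []
            for pair in haps:
                a = [("." if h[j] == MISSING else str(int(h[j]))) for h in pair]
                calls.append("|".join(a))
            fh.write(
                f"{sites.chrom[j]}\t{sites.pos[j]}\t.\t{sites.ref_allele[j]}\t"
                f"{sites.alt_allele[j]}\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def read_vcf(path) -> tuple[SiteTable, list[AdmixedGenome]]:
    """Read a phased VCF produced by :func:`write_vcf` (biallelic, GT only)."""
    chroms, pos, ref, alt = [], [], [], []
    sample_ids: list[str] = []
    gt_rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            fields = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                sample_ids = fields[9:]
                continue
            chroms.append(fields[0])
            pos.append(int(fields[1]))
            ref.append(fields[3])
            alt.append(fields[4])
            row = []
            for call in fields[9:]:
                gt = call.split(":")[0]
                row.append([(-1 if a == "." else int(a)) for a in gt.split("|")])
            gt_rows.append(row)
    sites = SiteTable(np.array(chroms), np.array(pos, dtype=np.int64),
                      np.array(ref), np.array(alt))
    arr = np.array(gt_rows, dtype=np.int8)  # L x n x ploidy
    genomes = []
    for i, sid in enumerate(sample_ids):
        ploidy = arr.shape[2]
        haps = {f"{sid}.{c}": arr[:, i, c].copy() for c in range(ploidy)}
        genomes.append(AdmixedGenome(sid, haps))
    return sites, genomes


def write_tracts(path, tracts: pd.DataFrame) -> None:
    tracts[TRACT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_tracts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["chrom"] = df["chrom"].astype(str)
    df["haplotype_id"] = df["haplotype_id"].astype(str)
    return df


def write_map(path, gmap: GeneticMap) -> None:
    rows = []
    for chrom, (bp, cm) in gmap.anchors.items():
        for b, c in zip(bp, cm):
            rows.append((chrom, int(b), c))
    pd.DataFrame(rows, columns=["chrom", "bp", "cM"]).to_csv(path, sep="\t", index=False)


def read_map(path) -> GeneticMap:
    df = pd.read_csv(path, sep="\t")
    anchors = {
        str(chrom): (g["bp"].to_numpy(float), g["cM"].to_numpy(float))
        for chrom, g in df.groupby("chrom", sort=False)
    }
    return GeneticMap(anchors)


def write_frequencies(path, labels: list[str], freqs: np.ndarray, sites: SiteTable) -> None:
    df = pd.DataFrame({"chrom": sites.chrom, "pos": sites.pos})
    for lab, f in zip(labels, freqs):
        df[lab] = f
    df.to_csv(path, sep="\t", index=False)


def read_frequencies(path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    labels = [c for c in df.columns if c not in ("chrom", "pos")]
    return labels, df[labels].to_numpy(float).T
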