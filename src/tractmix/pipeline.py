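"""End-to-end pipeline orchestration on synthetic data.

A single YAML/dict config drives the run; all randomness flows from one
root seed through named per-stage substreams, so reruns with the same
config are bit-identical. Stages write their outputs under the run
directory and register them in a manifest (path, sha256, producing stage);
the final summary JSON collects the headline statistics: population mean
ancestry fractions, admixture entropy, ΔAdmix medians, validation R², and
the tract-based generations estimate.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml

from . import io as tio
from .core import GeneticMap, ParameterError, SimulationConfig
from .global_ancestry import admixture_entropy, estimate_ancestry_fractions
from .local_ancestry import infer_local_ancestry
from .painting import validate_inference
from .sexbias import cohort_delta_admix, records_to_frame
from .sim import generate_founder_panels, generate_validation_cohort, simulate_cohort
from .timing import collect_tract_lengths, estimate_pulse_time

log = logging.getLogger("tractmix.pipeline")

DEFAULT_CONFIG = {
    "seed": None,  # mandatory
    "panels": {
        "n_populations": 4,
        "drift": [0.1, 0.1, 0.1, 0.1],
        "haplotypes_per_panel": 40,
        "n_sites": 4000,
        "chrom_lengths": {**{str(c): 1_000_000 for c in range(1, 9)}, "X": 1_500_000},
        "cm_per_mb": 100.0,
    },
    "cohort": {
        "n_genomes": 60,
        "proportions": [0.4, 0.3, 0.2, 0.1],
        "proportions_x": None,
        "generations": 10,
        "sexes": "alternate",
    },
    "local_ancestry": {"window_sites": 50, "certainty": 0.95},
    "validation": {"enabled": True, "genomes_per_point": 2, "grid_step": 0.2},
    "timing": {"bootstrap_replicates": 200},
}


class ConfigError(ValueError):
    pass


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return _merge(DEFAULT_CONFIG, user)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: dict, out_dir) -> dict:
    """Execute all stages; returns {"manifest": [...], "summary": {...}}."""
    if config.get("seed") is None:
        raise ConfigError("seed is mandatory")
    for key in ("panels", "cohort", "local_ancestry", "validation", "timing"):
        if key not in config:
            raise ConfigError(f"missing config section {key!r}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    streams = np.random.SeedSequence(config["seed"]).spawn(5)
    rngs = {name: np.random.default_rng(s) for name, s in
            zip(["panels", "cohort", "validation", "timing", "misc"], streams)}
    manifest: list[dict] = []
    summary: dict = {"seed": config["seed"]}

    def register(path: Path, stage: str) -> None:
        manifest.append({"file": path.name, "sha256": _sha256(path), "stage": stage})

    t_start = time.time()
    # --- stage: panels -------------------------------------------------
    pc = config["panels"]
    cfg = SimulationConfig(
        n_populations=pc["n_populations"],
        drift=tuple(pc["drift"]),
        proportions=tuple(config["cohort"]["proportions"]),
        generations=config["cohort"]["generations"],
        n_sites=pc["n_sites"],
        chrom_lengths={str(k): int(v) for k, v in pc["chrom_lengths"].items()},
        seed=config["seed"],
        haplotypes_per_panel=pc["haplotypes_per_panel"],
    )
    sites, panels = generate_founder_panels(cfg, rng=rngs["panels"])
    gmap = GeneticMap.uniform(cfg.chrom_lengths, cm_per_mb=pc["cm_per_mb"])
    labels = [p.population_label for p in panels]
    tio.write_map(out / "genetic_map.tsv", gmap)
    register(out / "genetic_map.tsv", "panels")
    tio.write_frequencies(out / "panel_frequencies.tsv", labels,
                          np.stack([p.allele_frequencies() for p in panels]), sites)
    register(out / "panel_frequencies.tsv", "panels")
    log.info("panels stage done (%.1fs)", time.time() - t_start)

    # --- stage: cohort -------------------------------------------------
    cc = config["cohort"]
    n = cc["n_genomes"]
    sexes = ["F", "M"] * (n // 2 + 1) if cc["sexes"] == "alternate" else list(cc["sexes"])
    px = tuple(cc["proportions_x"]) if cc.get("proportions_x") else None
    genomes, truth = simulate_cohort(
        panels, cfg, sites, gmap, n, rng=rngs["cohort"], sexes=sexes[:n], proportions_x=px
    )
    tio.write_vcf(out / "cohort.vcf", sites, genomes)
    register(out / "cohort.vcf", "cohort")
    tio.write_tracts(out / "truth_tracts.tsv", truth)
    register(out / "truth_tracts.tsv", "cohort")

    # --- stage: global ancestry ---------------------------------------
    G = np.array([g.genotypes() for g in genomes])
    F = np.stack([p.allele_frequencies() for p in panels])
    fractions = estimate_ancestry_fractions(
        G, F, individual_ids=[g.individual_id for g in genomes], component_labels=labels
    )
    fractions.fractions.to_csv(out / "q_matrix.tsv", sep="\t")
    register(out / "q_matrix.tsv", "global_ancestry")
    mean_q = fractions.population_mean()
    summary["mean_fractions"] = dict(zip(labels, np.round(mean_q, 4).tolist()))
    summary["admixture_entropy"] = round(admixture_entropy(mean_q), 4)

    # --- stage: local ancestry + sex bias ------------------------------
    lc = config["local_ancestry"]
    tract_frames = {}
    for g in genomes:
        tract_frames[g.individual_id] = infer_local_ancestry(
            g.haplotypes, panels, sites,
            window_sites=lc["window_sites"], certainty=lc["certainty"],
        )
    import pandas as pd

    inferred = pd.concat(tract_frames.values(), ignore_index=True)
    tio.write_tracts(out / "inferred_tracts.tsv", inferred)
    register(out / "inferred_tracts.tsv", "local_ancestry")
    records, medians = cohort_delta_admix(tract_frames, gmap)
    records_to_frame(records).to_csv(out / "delta_admix.tsv", sep="\t", index=False)
    register(out / "delta_admix.tsv", "sexbias")
    summary["delta_admix_medians"] = {k: round(v, 4) for k, v in medians.items()}

    # --- stage: timing -------------------------------------------------
    tc = config["timing"]
    timing_out = {}
    samples = {lab: collect_tract_lengths(truth, gmap, lab) for lab in labels}
    grand = sum(s.lengths.sum() for s in samples.values())
    for lab, samp in samples.items():
        if samp.empty or samp.n_uncensored < 30:
            continue
        frac = samp.lengths.sum() / grand
        est = estimate_pulse_time(
            samp, ancestry_fraction=frac,
            bootstrap_replicates=tc["bootstrap_replicates"],
            seed=int(rngs["timing"].integers(2**31)),
        )
        timing_out[lab] = {
            "g_hat": round(est.g_hat, 3),
            "ci": [round(est.ci_low, 3), round(est.ci_high, 3)],
            "n_tracts": est.n_tracts,
        }
    summary["timing"] = timing_out

    # --- stage: validation grid ---------------------------------------
    vc = config["validation"]
    if vc["enabled"]:
        grid = np.round(np.arange(0.20, 0.801, vc["grid_step"]), 10)
        cohort = generate_validation_cohort(
            panels, cfg, sites, gmap,
            seed=int(rngs["validation"].integers(2**31)),
            genomes_per_point=vc["genomes_per_point"], grid=grid,
        )
        report = validate_inference(
            cohort, panels, sites, gmap, generations=cfg.generations,
            seed=int(rngs["validation"].integers(2**31)),
        )
        report.pairs.to_csv(out / "validation_pairs.tsv", sep="\t", index=False)
        register(out / "validation_pairs.tsv", "validation")
        summary["validation_r2"] = round(report.pooled_r2, 4)

    # runtime is informational only; keep it out of the checksummed summary
    log.info("pipeline done in %.1fs", time.time() - t_start)
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    register(out / "summary.json", "summary")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {"manifest": manifest, "summary": summary}
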