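# tractmix

Simulation and inference toolkit for admixed genomes: an end-to-end,
fully synthetic re-implementation of the analysis pipeline used to study
admixed Latin American populations — global and local ancestry, ancestry-
specific masking, chromosome painting with NNLS conversion, sex-biased
admixture, population comparison statistics, and tract-length admixture
dating.

It is aimed at population geneticists who want a transparent, oracle-
testable version of that workflow: every stage runs on genomes simulated
from a stated generative model with known truth, so each estimator can be
validated against the parameters that produced its input.

## The models in brief

**Founder panels.** K reference populations drift from a common ancestor
under the Balding–Nichols model: per site, an ancestral frequency
p ~ U(0.05, 0.95) and population frequencies
f_k ~ Beta(p(1−F_k)/F_k, (1−p)(1−F_k)/F_k). Hudson's F_ST between two
panels each drifted by F concentrates at F itself.

**Admixed genomes.** Single-pulse admixture g generations ago: breakpoints
along each haploid chromosome form a Poisson process with rate g per
Morgan on an interpolated genetic map; each segment draws its ancestry from
the proportion vector m and copies a random training haplotype of that
ancestry. Maximal same-ancestry tracts of component k then have genetic
length ~ Exp(g(1−m_k)) per Morgan, which is what the dating module inverts:

    rate_hat = n_uncensored / sum(lengths),   g_hat = rate_hat / (1 − m_k)

with tracts running into a chromosome end treated as right-censored.

**Global ancestry.** Supervised maximum likelihood on the simplex by EM:

    L(q) = Σ_j [ g_j log Σ_k q_k f_kj + (2 − g_j) log Σ_k q_k (1 − f_kj) ]

Population mean fractions p feed the admixture entropy
S = −Σ p_i log2 p_i (bits; 2.0 for a uniform 4-way mixture). Relatives are
removed with the KING-robust kinship estimator at the 0.25 threshold.

**Local ancestry and masking.** A windowed naive-Bayes classifier labels
haplotype windows only when the posterior reaches 95% certainty (UNKNOWN
otherwise); masked genomes keep one ancestry's segments and set everything
else missing.

**Painting + NNLS.** Masked haplotypes are painted by greedy
longest-exact-match copying against reference panels; non-negative least
squares converts the copying vector into subcontinental ancestry
percentages. The validation harness replays the published design — focal
proportions 20%–80% in 5% steps, 20 genomes per step — and reports
expected-vs-observed Pearson r and R².

**Sex bias.** For each ancestry, ΔAdmix = F_total (F_X − F_auto)/(F_X + F_auto);
positive values indicate female-biased admixture, negative male-biased.

**Population comparisons.** Hudson F_ST (ratio of averages), neighbor-
joining trees with site-bootstrap support, and outgroup f3 with
block-jackknife standard errors.

## Worked example

```sh
tractmix pipeline run --config examples/demo.yaml --out demo_out
```

simulates four drifted founder panels (F = 0.1) over eight 1-Morgan
autosomes plus an X, admixes 60 genomes 10 generations ago at
m = (0.45, 0.25, 0.20, 0.10) with a female-biased founding for the first
two components, and runs every inference stage. It prints (seed 42,
~15 s on one CPU):

```json
{
  "admixture_entropy": 1.8118,
  "delta_admix_medians": {
    "POP0": 0.0699, "POP1": 0.0043, "POP2": -0.0974, "POP3": -0.0711
  },
  "mean_fractions": {
    "POP0": 0.4605, "POP1": 0.2378, "POP2": 0.1955, "POP3": 0.1062
  },
  "timing": {
    "POP0": {"g_hat": 9.951, "ci": [9.56, 10.353], "n_tracts": 3206},
    "POP1": {"g_hat": 10.153, "ci": [9.722, 10.625], "n_tracts": 2359},
    "POP2": {"g_hat": 10.01, "ci": [9.505, 10.413], "n_tracts": 1844},
    "POP3": {"g_hat": 9.815, "ci": [9.262, 10.409], "n_tracts": 1046}
  },
  "validation_r2": 0.9994
}
```

Reading it: the EM fractions recover the simulated proportions within
~0.01; the entropy of the mean fractions is 1.81 bits (a fairly even 4-way
mixture); ΔAdmix medians are positive for the female-introduced components
and negative for the male-introduced ones; tract-length dating recovers
the 10-generation pulse for all four ancestries; and the painting+NNLS
validation grid is essentially on the diagonal (R² = 0.9994).

Each stage is also exposed individually (`tractmix simulate`, `global-q`,
`entropy`, `kinship`, `pca`, `local-ancestry`, `mask`, `chrom-fractions`,
`paint`, `validate-grid`, `delta-admix`, `timing`) and as plain library
functions; see `docs/methods.md` for the modelling choices and their
limits.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, with the installed package, the admixture-entropy values of
six published admixed American populations from their published mean
ancestry fractions (the fractions are inputs; the entropies are computed
at run time and rounded to the reported precision), writing one JSON
record per target.
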