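# Methods

This note records the generative models, estimators, numerical choices and
design decisions behind tractmix, and what the synthetic world does and
does not establish about each green test.

## Synthetic world

### Founder panels

Panels are drawn under the Balding–Nichols construction: one ancestral
frequency per site, p ~ Uniform(0.05, 0.95), then per population k a
frequency f_k ~ Beta(p(1−F_k)/F_k, (1−p)(1−F_k)/F_k), and haplotypes as
independent Bernoulli(f_k) draws per site. The drift parameter F_k is the
standardized variance of f_k around p: Var(f_k) = F_k p(1−p).

A consequence used throughout the tests and fixed by brute-force
simulation before any test band was frozen: Hudson's F_ST (ratio of
averages) between two panels each drifted by F has numerator expectation
2F p(1−p) and denominator expectation 2 p(1−p), so it concentrates at F
itself (empirically 0.0998 ± 0.0015 at F = 0.1, 10,000 sites, 100
haplotypes). Test bands use [0.09, 0.11] at F = 0.1. When a target
between-panel F_ST is wanted (the subcontinental painting regimes), the
per-panel drift is set equal to that target.

Panels deliberately carry **no linkage disequilibrium**: sites are
independent given the frequencies. This keeps every estimator analytically
checkable, but it removes the haplotype sharing that real reference panels
have; the consequences for the painting design are discussed below.

### Genetic maps and coordinates

Positions are 1-based bp as in VCF; tracts are half-open [start, end) bp
intervals; genetic lengths come from piecewise-linear interpolation of
(bp, cM) anchors, clamped outside the anchor range (extrapolation rate 0).
Site grids are laid out evenly in bp and stop one bp short of the
chromosome end so that every site falls inside the half-open tract tiling.
Default synthetic chromosomes are uniform-rate; tests use 1 cM/Mb for
"physical-scale" worlds and 100 cM/Mb for compact 1-Morgan chromosomes.

### Admixed genomes

Single-pulse Markov model: per haploid chromosome copy, breakpoints form a
Poisson process with rate g per Morgan along the map; segment ancestries
are i.i.d. categorical(m); each segment copies a uniformly drawn training
haplotype of its ancestry; adjacent same-ancestry segments merge in the
truth tracts (certainty 1). Under this model the genetic length of a
maximal ancestry-k tract is Exp(g(1−m_k)) per Morgan — the (1−m_k) factor
comes from merging, since a breakpoint only ends a tract when the next
segment's ancestry differs.

Two assignment modes exist:

* **i.i.d. segments** (default): the general model; realized genome-wide
  fractions fluctuate around m with a variance set by the number of
  segments. This is the mode the timing and tract-statistics tests use.
* **length-quota assignment** (`exact_proportions=True`): segments are
  assigned (longest first, to the component with the largest remaining
  length deficit) so the genome's composition matches m up to segment
  granularity. The validation grid and parameter-recovery cohorts use this
  mode because their "expected" value must describe the genome actually
  simulated: on a desk-scale genome the i.i.d. mode's realized-fraction
  noise (sd ≈ 0.03–0.1) would dominate the comparison and measure the
  segment process rather than the estimator. Tract lengths are *not*
  exponential in this mode.

Sex-biased founding is modelled by an optional separate proportion vector
for the X chromosome: X lineages spend 2/3 of their history in females, so
a founding in which females carry ancestry A and males ancestry B puts
m_X(A) = 2/3 against m_auto(A) = 1/2. Males carry a single X copy; no
pseudo-autosomal region is modelled.

The validation cohort replays the published grid: focal proportions 0.20
to 0.80 in 0.05 steps, the remainder split evenly over the other regions
(the source is silent on the split; even is the symmetric choice), 20
genomes per grid point.

Non-goals of the simulator: coalescent realism (within-panel LD,
mutation), multi-pulse admixture, sex-specific recombination maps.

## Estimators

### Supervised ancestry fractions (EM)

The likelihood treats the 2L allele draws of an individual as a mixture
over K panels with known frequencies (clipped to [1e−4, 1−1e−4]). EM on
the simplex, uniform start, convergence when the log-likelihood improves
by < 1e−7 or at 2,000 iterations; monotonicity is asserted every
iteration. EM was preferred to quasi-Newton for its guaranteed monotone
likelihood and because the per-individual problems are small.
Indistinguishable panels are reported (`identifiable=False`, a warning) —
the returned vector is still a simplex point, as any point on the optimum
line is a maximizer.

### Admixture entropy

S = −Σ p_i log p_i of the *population mean* fractions. The log base is 2:
that choice reproduces all six published entropy values checked before the
tests were written (and a seventh row as an extra check), and gives the
natural "bits" reading where a uniform 4-way mixture scores 2.0.

### Kinship

KING-robust between-family estimator,
φ = (N_HetHet − 2 N_OppositeHom) / (N_Het(i) + N_Het(j)), verified against
the direct identity-state count on a duplicated genome (φ = 0.5). Greedy
exclusion above φ > 0.25: worst pair first; within a pair the member with
more missing genotypes is dropped, ties toward the lexicographically later
id. Pairs with fewer than 100 jointly observed sites are flagged
unreliable and never trigger an exclusion.

### PCA

Frequency-standardized genotypes ((g − 2p̂)/√(p̂(1−p̂)), monomorphic sites
dropped, column-centered), SVD, components ordered by explained variance.

### Local ancestry

Windowed naive-Bayes with windows of 50 consecutive sites (site-count
windows, not cM — simpler on a dense synthetic grid; configurable). Sites
in a window are treated as independent Bernoulli draws under each panel's
frequencies; with a uniform prior the posterior is the softmax of
log-likelihoods. A window is labeled only when the top posterior reaches
0.95, else UNKNOWN; same-label neighbours merge into tracts carrying the
minimum window certainty. This replaces a random-forest classifier in the
original workflow; the preserved contract is the 95%-certainty rule and
the masking semantics, not the classifier internals. UNKNOWN regions are
excluded from every downstream denominator. Chromosome ancestry fractions
are measured in cM by default (bp optional) because all downstream tract
statistics live in map units.

### Painting and NNLS

The copying model is greedy longest-exact-match: walk left to right over
unmasked sites; at each position the reference haplotype with the longest
identical run is the donor; the run's cM length (half a site-gap on each
open side) is credited to the donor's population, ties split equally; the
walk resumes at the mismatch. Sites no reference carries are skipped
without attribution. This is a transparent stand-in for an HMM copying
model; the NNLS conversion it feeds is unchanged.

Because the panels have no LD, a held-out haplotype of a population shares
nothing but frequencies with the simulation donors. Measured consequence:
painting a simulated genome against a *disjoint* validation split leaves
only frequency signal (per-genome NNLS error sd ≈ 0.22 at 2,000 sites),
and no feasible scale reaches the published validation accuracy. The
harness therefore paints cohort genomes against the same panels their
segments were copied from — donor sharing is the synthetic analog of the
haplotype sharing real panels provide — and the painting then recovers the
genome's realized composition to ~0.002.

Two design matrices for NNLS are provided:

* `self_copy_matrix`: leave-one-individual-out mean copying profiles of
  the raw panel members (the classical construction).
* `calibration_matrix`: mean normalized painting vectors of *pure
  simulated genomes* (m = e_k), painted exactly as the cohort is painted.
  The validation harness uses this one, because the cohort genomes are
  painted in the donors-present regime while LOO panel members are not;
  calibrating in a different regime than the measurement would misconvert.

NNLS is solved with `scipy.optimize.nnls` on sum-normalized vectors and
renormalized to a simplex; it is cross-checked against an exhaustive
0.01-step simplex grid search. A component whose genome-wide fraction is
≤ 3% is skipped in per-ancestry painting applications (mirroring the
minimum-ancestry rule of the original analysis). Validation reports both
per-region Pearson r and the pooled R² over all focal pairs, since the
source is ambiguous about which was quoted.

What a green validation R² establishes: that the painting + NNLS
conversion correctly recovers composition when donors are identifiable and
regions are drift-separated at F_ST 0.01–0.05. It does not establish
performance under phasing error, panel misspecification, or frequency-only
signal.

### ΔAdmix

ΔAdmix = F_total (F_X − F_auto)/(F_X + F_auto) per ancestry per
individual, fractions tract-derived in cM (genome-wide for F_total, so the
statistic is internally consistent; an externally supplied F_total is also
accepted). F_X + F_auto = 0 returns 0 — no information, no bias — which
preserves continuity and the antisymmetry and |Δ| ≤ F_total invariants.
Medians are reported per ancestry.

### F_ST, neighbor joining, outgroup f3

Hudson's ratio-of-averages estimator with finite-sample corrections;
monomorphic-in-both sites dropped; the raw (possibly negative) value is
reported alongside a zero-clamped value used for tree distances. Note the
corrections assume two *independent* samples: feeding the same sample
twice yields exactly −1/(n−1), not 0.

Neighbor joining is delegated to scikit-bio's canonical Saitou–Nei
implementation behind the module surface (negative branch lengths
disallowed); additive matrices are recovered exactly (verified against
random trees built by edge attachment, distances by Dijkstra). Bootstrap
support resamples sites with replacement, recomputes the F_ST matrix and
tree, and counts bipartition frequencies; Newick output carries 6-decimal
branch lengths and support as internal labels.

Outgroup f3(O; A, B) is the site-mean of (p_o−p_a)(p_o−p_b) minus the
outgroup sampling correction p_o(1−p_o)/(n_o−1); the SE is a block
jackknife over contiguous fixed-size site blocks (physical-map blocks are
unnecessary on LD-free synthetic data). Fewer than two blocks flags the SE
as undefined rather than erroring.

### Admixture dating

Censoring-aware exponential MLE on tract genetic lengths:
rate = n_uncensored / Σ(all lengths). Only tracts reaching the *far*
chromosome end are censored: in the left-to-right Poisson construction the
tract at the chromosome start is a complete draw, and flagging both ends
was measured to bias ĝ down by ~20%. The generations estimate is
ĝ = rate/(1−m_k) when the ancestry's proportion is supplied (the merge
correction; exact under the single-pulse model), or the raw rate
otherwise, appropriate for rare ancestries. 95% CIs by percentile
bootstrap over tracts (1,000 replicates by default; fewer in tests for
speed). At least 30 uncensored tracts are required. Single-pulse only:
multi-pulse fitting and pulse-ordering searches are an explicit extension
point, and the simulator emits single pulses, so the estimator is matched
to testable truth.

## Reproducibility

Seeds are mandatory everywhere randomness enters; no default seeds exist.
The pipeline derives named per-stage substreams from one root seed via
`numpy.random.SeedSequence.spawn`, writes a manifest of sha256 checksums,
and two runs with the same config are bit-identical (asserted in tests;
the only non-deterministic quantity, wall-clock timing, is logged rather
than written into checksummed outputs).

## Known limitations

* No within-panel LD: local-ancestry windows and painting runs exploit
  frequency and donor-identity signal only; accuracies here do not
  transfer quantitatively to real panels.
* No phasing error, genotyping error or missingness models.
* The windowed classifier's tract boundaries are window-quantized;
  boundary precision is limited to the window span.
* Dating assumes a single pulse; under continuous or multi-pulse
  admixture ĝ is an effective (length-weighted) time.
* The quota assignment mode trades tract-length realism for compositional
  exactness; never use it for tract-statistics studies.
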