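# Methods

`triadscan` implements an inference chain for detecting *recent polygenic
selection* in a "triad" sampling design: a putatively selected population
(for example a site warmed by a power station's thermal effluent, below
"TE") flanked by two reference populations along the same coastline. The
premise of the design is that under purely neutral or demographic forces
the two flanking references should differ from each other at least as much
as either differs from the geographically intermediate TE site; loci where
the TE population is an outlier against *both* references but the
references agree with each other are candidates for selection unique to the
TE environment. This note records the models, the tunable parameters, the
numerical choices, and what the synthetic-data validation does and does not
establish.

## Genotype model and filtering

Genotypes are biallelic SNP dosages (0/1/2, missing) coded on the globally
minor allele (ties at frequency 0.5 keep the alternate allele). Depth-based
calling follows the binomial-likelihood rule of tag-based GBS genotypers:
with allele depths (a, b), the genotype maximizing the binomial likelihood
of b among {hom-ref (expected alt fraction ε), het (0.5), hom-alt (1−ε)} is
called; cells with fewer than `min_reads` (default 5) total reads are
missing; per-allele depth is capped at 127 reads, so total depth per cell
ranges over 0–254.

The filtering cascade applies, in order: (1) drop individuals missing more
than 12.5% of calls; (2) drop loci called in under 85% of the remaining
individuals; (3) drop loci with global minor-allele frequency below 1%
(strict inequality; recomputed after stages 1–2); (4) drop loci with
observed heterozygosity *above* expectation whose exact Hardy–Weinberg
p-value falls below 0.01 — the excess-het direction only, because excess
heterozygosity is the signature of paralog collapse, while deficits are
expected under population structure. The HWE test enumerates the exact
conditional (Levene) distribution of heterozygote counts rather than
sampling it by Markov chain: for biallelic loci the enumeration is cheap
and removes Monte Carlo nondeterminism with the identical inference target.
The cascade is idempotent. MAF is computed over called genotypes only.

## Core statistics

Pairwise F_ST is Weir & Cockerham's (1984) θ, per locus and genome-wide as
the ratio of summed numerators to summed denominators; per-locus negative
values are retained. π per SNP is the unbiased 2p(1−p)·n/(n−1) over called
gene copies (panel-conditional: inflated relative to genome-wide diversity,
usable for comparisons within a dataset). Tajima's D uses the standard 1989
constants per tag-sized window (default 75 bp, the read length). r² is the
squared Pearson correlation of dosages (composite LD, no phasing), defined
over individuals with both loci called (default ≥ 20). AMOVA is the
three-level hierarchical decomposition on gene copies with allelic-mismatch
distance; for 0/1 data the within-set sum of squares at a locus is
k(n−k)/n, so no distance matrix is formed. Permutation p-values throughout
use the (1+k)/(1+B) convention. Mantel tests permute the row/column order
of one matrix (exhaustive enumeration available for small matrices).
Rank-sum tests and BH/BY FDR control are delegated to scipy/statsmodels.

## The outlier scan

The null is a symmetric finite-island model simulated at the discrete
Wright–Fisher level (not a beta/diffusion approximation): ancestral
frequency x per locus with density ∝ 1/(x(1−x)), all demes starting at x,
then `generations` (default 90) rounds of migration toward the
metapopulation mean and binomial resampling of 2N gene copies. Three
deliberate design points, each of which proved necessary for calibration
against realistic data:

- **Dynamic differentiation.** Starting undifferentiated and letting the
  run build between-deme variance reproduces the finite-time, finite-N
  behaviour of rare variants (young alleles are geographically clumped),
  which a stationary beta draw misses.
- **Shared migration history.** Realized migrant fractions are drawn once
  per generation and deme and shared across loci: a genome-wide dataset
  experiences one demographic history, which narrows its across-locus F_ST
  dispersion relative to integrating over histories independently per
  locus.
- **Matched sampling and observation.** Genotypes are sampled without
  replacement from the finite deme (hypergeometric, not binomial), and when
  the data's depth/calling parameters are known the same GBS observation
  model and call-rate filter are applied to the simulated loci.

The migration parameter Nm is solved by a bracketed multiplicative search
with common random numbers so that the surface's trimmed mean θ (loci
inside the conditional 5–95% envelope) matches the target; the target
itself comes from a two-pass "neutral mean" refinement that culls
provisional outliers from the data with the same envelope, making the
comparison trim-for-trim. Conditional p-values are empirical within
equal-count H_e bins (default 50 bins, pooled below 500 simulations each).
Loci with pair-level MAF below 2.5% are excluded from the test (their θ
takes only a handful of discrete values — an atom, not a usable p-value —
and they carry no outlier power); the null applies the same threshold.

Two outlier definitions are reported. The *envelope* call (p outside
[0.05, 0.95]) is the operational definition of simulation-based scans: it
has a ~5% per-comparison false-positive rate by construction, which is
exactly what the triad intersection is designed to absorb — the
reference-vs-reference comparison runs the same scan and vetoes loci that
are "outliers" for reasons shared across comparisons. The *FDR* call
adjusts upper-tail p-values (reported at the surface's simulation
resolution, 1/(1+n_sims), when a locus exceeds every simulated value at its
heterozygosity) by step-up FDR; with realistic effect sizes it is extremely
stringent and serves as a high-confidence tier. Candidate calling defaults
to the envelope definition; the FDR criterion is available by flag.

**Known limitation.** On neutral synthetic data the FDR-tier false-positive
rate is at nominal (usually zero) and the conditional p-values are uniform
within every heterozygosity range we examined, but the *pooled*
Kolmogorov–Smirnov test across ~3–5k loci detects a residual narrowing of
the observed distribution (D ≈ 0.03–0.04): both extreme deciles are mildly
depleted. We attribute this to across-locus correlation that the
independent-locus null cannot fully represent — linked loci share local
genealogies and all loci share one realized pedigree — only part of which
the shared-migration device recovers. The direction of the residual is
conservative (slightly too few extreme p-values), which is the right
failure mode for a selection scan.

## Candidates and follow-ups

A candidate is a locus that is a directional outlier in both TE-vs-
reference comparisons but not in the reference-vs-reference comparison; a
locus without a verdict in any comparison is ineligible. The neutral panel
is 0.05 < p < 0.95 in all three comparisons. Because the two TE comparisons
share the TE sample, their errors are positively correlated; the neutral-
mode candidate count therefore exceeds the naive product of marginal
outlier rates, and enrichment of true targets is assessed against the
hypergeometric null rather than by the raw candidate count.

Allele-frequency change is polarized on the global major allele and
measured as p_TE minus the unweighted mean of the two reference
frequencies (the unweighted mean matches the axis definition of the
figure-style summaries; sample-size weighting is available by computing
pooled frequencies directly). The MAF-matched bootstrap resamples neutral-
panel loci within MAF bins (default width 0.02) so each draw matches the
target set's MAF histogram exactly.

## Ordination

PCA is on centered (not scaled) mean-imputed dosages; Kaiser–Guttman
retention (eigenvalue above the mean) is the default rule. DAPC is linear
discriminant analysis on retained PC scores with sampling locations as
priors; the a-score is the observed correct-reassignment rate minus its
mean under random relabelings. K-means cluster number is profiled by
BIC = n·ln(WSS/n) + k·d·ln(n); note this spherical-Gaussian form tends to
over-split tight low-dimensional clusters and is best read, as in common
practice, for its elbow rather than its argmin. dbMEMs truncate the
distance matrix at the longest minimum-spanning-tree edge, take the PCoA of
the Gower-centered squared distances, and keep positive-eigenvalue axes
with Moran's I above −1/(n−1) (connectivity weights within the truncation
distance). RDA/pRDA regress the response on the explanatory block
(residualizing both on the conditioning block first) and test by
permutation of response rows, with optional strata restricting permutations
to within blocks. Variance partitioning uses unadjusted R², so the
pure + pure + joint identity holds exactly. "F_ST explained" is
(explained fraction × retained-PC fraction) / F_ST-denominator; both the
mean-pairwise and multi-population θ denominators can be supplied — the
conversion is deliberately a pure function of its three inputs.

A calibration caveat that shapes the validation: permuting *individual*
rows answers "is there any population structure", which is true under pure
drift, so the effluent term would be "significant" in every neutral
dataset. The exchangeable units for the effluent question are demes; the
calibration experiment therefore uses deme-centroid responses, conditions
on triad membership (the leading spatial eigenvector for this geometry),
and permutes demes within triads — a scheme under which permuted responses
remain exactly orthogonal to the conditioning block. When the within-block
permutation group is small, `rda` enumerates it exhaustively, which makes
the test exact but its p-value discrete (here nine atoms, because the F
statistic is invariant to swapping the two reference rows of a triad);
uniformity of a discrete exact test is checked on the randomized
probability integral transform, which is continuous-uniform when the test
is calibrated.

## Local decay profiles

F_ST decay collects, for every non-candidate SNP within `max_dist` of a
candidate on the same scaffold, the pair (distance, mean of the two
TE-comparison θ values), smooths it with tricube local-linear regression
whose span minimizes AICc = n·ln(σ̂²) + n(n+tr H)/(n−tr H−2), and reports
the crossing distance: the first distance at which the 95% CI of the curve
reaches down to the genome-wide baseline, 0 when the fitted curve starts at
or below baseline, undefined when fewer than `min_pairs` neighbor pairs
exist. Candidate–candidate pairs are recorded but excluded from the fit.
LD decay reports r²-vs-distance for candidate-containing and other pairs,
per-pair significance by correlation test with BY control at q = 0.1, the
maximum distance of any significant candidate pair, and the half-decay
distance of the smoothed candidate-pair curve.

## P_ST

One-way ANOVA variance components with the unbalanced-design n₀
coefficient; P_ST(c/h²) = (c/h²)σ²_B / ((c/h²)σ²_B + 2σ²_W) over a grid
(default 0.1–2.0 by 0.1), negative σ²_B truncated to zero with a flag;
stratified individual bootstrap with percentile CIs at 95%. The comparison
against genome-wide F_ST reports, per grid point, whether the CI lower
bound exceeds F_ST.

## The synthetic-triad generator

The generator is first-class, tested code; its defaults are the study
conditions of the validation experiments. Six demes at coastal positions
(0, 30, 60, 460, 490, 520) km form two triads with the TE deme in the
middle of each. Within a triad, gene flow is symmetric among all three
demes (they sit tens of km apart, inside the dispersal scale — which is
also why no within-triad isolation by distance is expected); between
triads, only the inner demes exchange migrants at a much lower rate, so
isolation by distance appears among triads only. Key defaults and the
reasoning behind them:

- `N = 150` diploids per deme, `m_within = 0.022` per neighbor: within-
  triad genome-wide F_ST ≈ 0.01–0.04 (the scale of the real triads) with a
  drift regime strong enough for selection-plus-drift jackpots at a
  minority of loci. These are desk-scale stand-ins for wild effective sizes
  of 10⁴–10⁵; Nm is what the statistics see.
- `fst_between_init = 0.02` plus ~90 generations of drift produce
  among-triad F_ST around 0.1–0.17, bracketing the real between-triad
  scale.
- 2000 loci on 150 scaffolds of 2 kb; meiotic recombination 5×10⁻⁵ per bp.
  Ancestral LD is planted at initialization by Li–Stephens-style mosaic
  copying from a pool of 8 founder haplotypes per triad with a switch scale
  of 0.03/bp, giving r² that decays over tens of bp. Sharing one founder
  pool per triad is essential: per-deme pools would quantize initial deme
  frequencies to multiples of 1/K and distort the within-triad F_ST
  distribution; with a shared pool the quantization cancels in all
  within-triad contrasts and the burn-in builds within-triad
  differentiation to its own Wright–Fisher equilibrium.
- Selection: 100 loci drawn from standing variants (metapopulation MAF
  ≥ 0.02 at onset), additive fitness (1, 1+s, 1+2s) with s = 0.05 at the
  TE demes only, for 50 generations. Under migration–selection balance
  this yields a median |Δp| (TE vs reference mean, true frequencies) of
  ≈ 0.06–0.09 — the "small allele-frequency changes at many loci" regime —
  with a tail of loci reaching 0.2–0.35 that powers candidate detection.
- Hard-sweep mode plants a single allele at frequency 0.02 on one shared
  haplotype background (the whole scaffold copied from one founder) and
  sweeps it with s = 0.5 at one TE deme, for contrasting the spatial
  footprint of a sweep with the polygenic default.
- Observation model: per-cell total depth ~ negative binomial (mean 26,
  shape 3 — overdispersed with a long tail), random dropout 3%, sequencing
  error 1%, per-allele cap 127, binomial-likelihood calling with ≥ 5 reads.
  Realized mean depth over called cells is ≈ 26–27 and the call rate
  ≈ 94%.
- Traits: an additive score over the first 30 selected loci plus Gaussian
  environmental noise scaled to within-population h² = 0.5, emitted for the
  first TE deme and its northern reference.

What the generator does *not* emulate: chromosome-scale recombination maps,
mutation during the selection phase (standing variation only), linked
background selection, and any non-equilibrium demography beyond the
two-triad split. Passing the validation therefore shows that the pipeline
recovers the targeted signatures under a faithful but idealized version of
the sampling design; it does not certify behaviour under demographic
histories the generator does not produce.

## Validation experiments and problem sizes

The experiments in `triadscan.experiments` (shared by the test suite and
`scripts/acceptance.py`) use these sizes, chosen to make each property
measurable in minutes on one core: neutral calibration on one 5000-locus
dataset with 40 samples/deme and 50k-locus null surfaces; candidate
recovery on 10 replicate default datasets with 15k-locus surfaces;
sweep-vs-polygenic discrimination on 20 paired replicates at N = 120 with
900 loci on 30 scaffolds; P_ST coverage on 100 replicates of 2×50
individuals with 500 bootstrap draws; pRDA calibration on 200 replicates at
N = 60 with 200 loci. Seeds are explicit everywhere; repeated runs are
bit-identical.
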