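# Methods

admixkit dissects admixed genomes hierarchically: continental-level local
ancestry is decoded first, the genome is then split into per-ancestry
"virtual genomes", and each ancestral component is analysed separately —
for within-continent substructure (subspace PCA), admixture timing
(ancestry-block counts) and recent positive selection (ancestry-aware
EHH/iHS).  A synthetic-cohort simulator provides ground truth for every
stage.  This note records the models, the parameters that matter, and the
design choices made where the design was genuinely open.

## Local-ancestry model

Each phased haplotype is decoded independently with a hidden Markov model
whose states are the K ancestral populations.  Over a gap of `d` Morgans
the chance of an ancestry switch is `1 − exp(−τ·d)`; the post-switch state
is redrawn from the individual's ancestry-proportion vector `q`.  This
"stay-or-redraw" kernel is the stationary description of a single admixture
pulse τ generations ago: it reproduces the property that only a fraction
`2·z(1−z)` of recombination events join haplotypes of different ancestry.
τ defaults to 12 generations, the point estimate the dating module
typically returns for a recent-admixture cohort; when the dating stage has
run, its estimate should be fed back in.

Emissions are ancestry-specific allele frequencies (`markov_order=0`) or
two-site conditional haplotype frequencies (`markov_order=1`), the latter
absorbing part of the background LD within ancestral populations.
Frequencies are clipped to [0.001, 0.999] so a finite reference panel can
never zero out a path.  Forward/backward vectors are rescaled per marker;
the log-likelihood is exact (it matches brute-force path enumeration to
1e−8 on small instances, which the test suite verifies).

The full decision-tree haplotype emission of the autoregressive variant
used on real cohorts is not reproducible from public descriptions; orders
0/1 are provided instead and the simulation tests quantify what label
accuracy they achieve.  Decoding accuracy at the default synthetic
conditions (FST 0.15, T=12, 20,000 markers) is ~6–7% per-marker label
error.  This is essentially the Bayes floor of those conditions, not an
implementation gap: the generator matches the HMM exactly, so posterior
argmax is optimal, and the error is concentrated in switch-boundary
localization (~200 effective boundaries per haploid genome, each resolvable
only to within a handful of markers given ~0.15 nats of frequency
information per marker).  Real 550k-SNP panels are ~6× denser and
correspondingly more accurate.

Reference panels nominally drawn from one ancestry may carry foreign
segments; `refine_reference_panel` iterates frequency estimation →
re-decoding → masking of foreign segments until assignments change at fewer
than 0.1% of cells (max 10 rounds).

## Virtual genomes and blocks

Masking keeps an allele iff its haplotype's ancestry call equals the target
(and, when posteriors are present, the call's posterior is ≥ 0.9;
below-threshold calls are masked in *all* virtual genomes — conservative).
The two alleles of an individual form a pair of N×M matrices (G1, G2) with
NaN at masked entries.

Ancestry blocks are maximal constant-ancestry runs per haplotype per
chromosome.  Runs shorter than `min_snps` (default 10) are absorbed into
their flanks; when the flanks disagree the left flank's ancestry wins — a
deterministic tie-break.  A chromosome-leading short run is absorbed into
the first long run to its right.  Diploid block count sums both haplotypes
over all 22 autosomes; a switch-free genome counts 44 blocks by convention.

## Subspace PCA

For masked matrices, covariance PCA with mean imputation biases the leading
components: the sampling noise of covariance entries scales with
missingness, so high-missingness individuals drift outward along every PC.
Subspace PCA instead minimizes the reconstruction error

    R = Σ_h Σ_{observed (n,m)} (G^h_nm − (A Sᵀ)_nm)²

over a shared N×d score matrix A (one score vector per individual, fed by
both allele matrices) and M×d loadings S, using observed entries only.
Columns are standardized per matrix to observed mean 0 and sample variance
1 (n−1 denominator; the choice is conventional, the objective does not
depend on it qualitatively); columns monomorphic in their observed entries
are dropped, as they carry no signal and make R degenerate.

Two solvers are provided.  The default alternates exact per-row /
per-column least-squares solves; each half-step solves its normal equations
exactly, so R is monotonically non-increasing (asserted per half-step in the
tests) and no learning rate is needed.  A gradient solver with backtracking
on the learning rate is retained as the simpler-to-describe alternative;
both reach the same optimum on test problems.  Initialization is a fixed-
seed Gaussian A; the objective is rotation-invariant, so only the spanned
subspace is identified, and all comparisons are made between subspaces.
Convergence is declared at relative ΔR < 1e−8 (default) or 500 iterations.
After convergence A is orthonormalized and S orthogonalized through a thin
SVD of the factor pair, giving ordered PCs; the sign convention makes each
component's largest-magnitude loading positive.  On complete data the
result matches covariance-eigendecomposition PCA to principal angles
< 1e−6.

Substructure separation is scored by the confusion fraction ξ: the minimum
fraction of individuals on the wrong side of the best single threshold on a
component, scanned over all midpoints and both polarities; ξ ∈ [0, 0.5].

## Admixture dating

Under hybrid isolation (one admixture pulse T generations ago, no later
gene flow), a haploid genome of L = 3435 cM accumulates 0.01·T·L expected
recombinations, of which 2·z(1−z) join opposite-ancestry haplotypes, so the
expected diploid block count is `B = 0.04·T·L·z(1−z) + 2·22`.  T is
estimated by pooled least squares of observed per-individual diploid counts
against this curve over an integer grid (default 5–25 generations), ties
breaking toward smaller T; a quadratic refinement of the residual profile
optionally reports fractional T, flagged as an extrapolation.  The
hybrid-isolation model is used for its closed form; under continuous gene
flow the estimate reads as a gene-flow-weighted average admixing time.

At 20,000 markers, counting blocks from marker labels slightly undercounts
switches (two switches inside one marker gap cancel), and the <10-SNP
filter removes some genuinely short blocks, together biasing T̂ down by
~2 generations at T = 12.  The simulator therefore also records the
continuous (marker-free) switch counts, which match the formula exactly and
are used to validate the law itself; filter-robustness (±1 generation) is
validated at 45,000 markers, a density at which <10-SNP runs are
predominantly artifacts, as on the dense arrays the filter was designed
for.

## Selection scan

EHH at distance x from a core SNP is the probability that two random
haplotypes carrying the core allele are identical over [core, x], computed
as Σ_g C(n_g,2)/C(n,2) over extended-haplotype classes.  Two
ancestry-aware modifications: homozygosity is computed only on haplotypes
whose core SNP derives from the target ancestry, and a haplotype hit by an
ancestry switch during extension becomes a singleton class from the switch
point on ("truncate" mode; the "exclude400" alternative drops haplotypes
with a switch within 400 SNPs of the core — on switch-free data the modes
coincide exactly, and the tests assert it).

iHH integrates EHH by the trapezoid rule over physical distance, outward in
both directions, to the interpolated crossing of the 0.05 cutoff; inter-SNP
gaps above 20 kb contribute proportionally less (scaled by 20 kb/gap, the
standard guard against assuming homozygosity across large gaps).  Cores
whose curve never reaches the cutoff before the chromosome end are
edge-flagged and excluded from normalization.  Raw iHS is
`ln(iHH_ancestral / iHH_derived)` for SNPs with derived frequency in
[0.05, 0.95]; it is exactly antisymmetric under swapping the allele labels.

Raw scores are standardized within each chromosome: the 25th and 75th
percentiles of the raw scores are fitted by quantile regression as
functions of minor allele frequency, each score is centered at the fitted
mid-quartile and scaled by the fitted IQR divided by 1.34898 (the IQR of a
standard normal — without this constant the scores could not be on a unit
normal scale).  The default regression basis is [1, 1/MAF]: empirically the
raw-score dispersion grows close to inversely with MAF, because the smaller
allele class contributes an iHH estimated from few haplotypes; a linear
basis (also available) crosses zero inside the observed MAF range and
triggers the frequency-bin fallback.  Chromosomes with fewer than 200
scores are pooled.

One caveat the synthetic null makes visible: under neutrality the raw-score
*location* is antisymmetric in derived allele frequency — the rarer allele
class marks more recent coancestry and carries inflated iHH.  Conditioning
the normalization on MAF folds the two branches together, so each MAF
stratum is a mixture of two location-shifted components; after IQR scaling
the standardized scores are mildly under-dispersed (sd ≈ 0.91, KS distance
to N(0,1) ≈ 0.04) while the |iHS| > 2.5 tail holds at ≈ 1%.  An opt-in
centering mode (`IhsConfig(centering="daf_median")`) removes the fitted
derived-frequency median trend first and yields a visibly normal null
(KS ≈ 0.007), at the cost of a heavier measured tail (≈ 1.7%); the
published-style mid-quartile centering remains the default.

Candidate regions are seeded by 50-kb windows around every |iHS| > 2.5 SNP,
extended 50 kb at a time while the adjacent window still contains an
above-threshold SNP (so boundaries can extend up to 75 kb beyond the
outermost hot SNP), merged when overlapping, filtered to ≥ 20 scored SNPs
with ≥ 10% above threshold, and ranked by maximum |iHS|.  Overlap between
SNP sets is assessed against the hypergeometric null (expected = nA·nB/M)
and, optionally, a circular-shift permutation null that preserves the local
clustering of scores along the genome; the two can differ strongly when
extreme scores cluster in LD, which is why both are reported rather than
one claimed exact.

## Synthetic cohorts

The generator reproduces the statistical structure the analyses assume:

- **Differentiation.** Per-population allele frequencies follow the
  Balding–Nichols model, Beta(p(1−F)/F, (1−p)(1−F)/F) around an ancestral
  frequency drawn U(0.1, 0.9), clipped to [0.01, 0.99].  Continental-level
  pairs default to FST 0.15; within-continent subgroups to FST 0.01.
- **Haplotype LD.** A Markov copying process: 20% of each source's
  haplotypes are independent site-wise draws ("founders"); the rest copy a
  random founder, switching template between adjacent markers with
  probability min(1, 0.3·ΔcM).  Template runs of ~3 cM give EHH decay
  resolved over ~10–20 markers at the default 20,000-marker density —
  mirroring how a dense array resolves real sub-cM decay scales — while
  adjacent-marker r² stays modest (~0.02–0.05), as on a pruned genotyping
  array.
- **Admixture.** Hybrid isolation: per haplotype and chromosome, switch
  points form a Poisson process at rate T per Morgan over the full
  configured chromosome length (22 human-like autosomes summing to
  3435 cM); the ancestry after each point is redrawn from the individual's
  proportion vector, and each segment copies a single randomly chosen
  donor haplotype of that ancestry.  Defaults: T = 12, z fixed at 0.5.
- **Sweeps.** A founder-copy construction: a chosen fraction of haplotypes
  takes one founder's alleles around a core marker, truncated at
  exponential distances (mean span/2, capped at span/2) so homozygosity
  decays away from the core.  This creates the long-haplotype signal iHS
  detects without forward simulation.
- **Mask errors.** Each maximal constant-ancestry segment flips with
  probability ε (to the other ancestry for K = 2, uniformly otherwise).

What the generator does *not* emulate: mutation-age structure (the
"derived" allele is a label, not a younger allele), background selection,
genotyping error, real recombination-map heterogeneity, and trio phasing
error.  Passing tests therefore demonstrate correctness of the algorithms
under the stated model, not performance guarantees on real cohorts;
real-data error rates (e.g. of local-ancestry decoding) depend on marker
density and reference quality in ways the note above quantifies only for
the synthetic conditions.

## Problem sizes and determinism

The test suite runs every stage at the smallest size where the property
being tested is stable: scale-free algebraic properties on toy matrices;
frequency-dependent calibrations (the neutral iHS tail, admixing-time
recovery with the short-block filter) at the full 20,000-marker density
they are defined at.  The acceptance script runs the two headline
experiments at full scale (400 genomes × 5 seeds; 200 haplotypes ×
20,000 SNPs).  All randomness flows from numpy `SeedSequence` spawning off
a single seed; pipelines rerun with the same configuration and seed produce
byte-identical artifacts, which the manifest checksums make auditable.
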