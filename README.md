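# admixkit

Hierarchical analysis of admixed genomes: infer where each chromosomal
segment of an admixed individual comes from, split the genome into
per-ancestry **virtual genomes**, and study each ancestral component on its
own — for fine-scale population structure, admixture timing, and signatures
of recent positive selection in populations for which no intact reference
panel exists.

The package is aimed at population geneticists working with phased
genotype panels of admixed cohorts (e.g. Latino cohorts mixing Indigenous
American, European and African ancestry), and at method developers who need
a fully synthetic, ground-truthed test bed for local-ancestry-aware
analyses.

## What it computes

1. **Local ancestry** (`local_ancestry`): per-haplotype, per-marker
   ancestry posteriors from a hidden Markov model with switch rate
   `1 − exp(−τ·d)` per `d` Morgans and emissions from ancestry-specific
   allele (or two-site haplotype) frequencies. Global ancestry is the
   average of local ancestry across markers.
2. **Virtual genomes** (`virtual_genomes`): masking to one ancestry turns a
   cohort into a pair of N×M allele matrices G¹, G² with missing entries;
   ancestry blocks are maximal constant-ancestry runs (blocks with <10 SNPs
   are absorbed into their flanks).
3. **Subspace PCA** (`sspca`): PCs from the low-rank factorization
   minimizing the reconstruction error
   `R = Σ_h Σ_observed (G^h_nm − (A·Sᵀ)_nm)²`
   over observed entries only — robust to the massive, individual-specific
   missingness of virtual genomes that breaks mean-imputed covariance PCA.
   Separation of known groups is scored by the confusion fraction ξ ∈ [0, ½].
4. **Admixture dating** (`dating`): under hybrid isolation, the expected
   diploid ancestry-block count is `B = 0.04·T·L·z(1−z) + 2·22`
   (L = 3435 cM); T̂ is the least-squares fit of observed counts to these
   curves.
5. **Selection scan** (`selection`): ancestry-aware EHH/iHS — haplotype
   homozygosity on ancestry-qualified haplotypes with truncation at
   ancestry switches, `iHS = ln(iHH_A/iHH_D)` standardized within
   chromosome by a quantile-regression IQR null in minor allele frequency
   (scaled by 1.34898 so neutral scores are ~N(0,1), |iHS| > 2.5 ≈ top 1%),
   candidate regions from 50-kb seed/extend/merge window calling, and
   hypergeometric / permutation overlap enrichment between scans.
6. **Simulator** (`simulate`): Balding–Nichols differentiated sources at a
   chosen FST, Markov-copying haplotype LD, hybrid-isolation admixture with
   per-individual ancestry proportions, founder-copy selective sweeps, and
   segment-level ancestry-mask corruption — every stage's ground truth.

## Worked example

```python
import numpy as np
import admixkit as ak
from admixkit import simulate as sim

# two source populations at FST 0.15, 6000 markers over 22 autosomes
rng = np.random.default_rng(42)
markers = sim.simulate_markers(6000, sim.DEFAULT_CHROM_LENGTHS_CM, rng)
freqs = sim.draw_population_freqs(rng.uniform(0.1, 0.9, 6000), 0.15, 2, rng)
mats = sim.simulate_source_haplotypes(freqs, 160, 0.3, markers, rng)

# 40 admixed genomes, one pulse 12 generations ago, z ~ U(0.1, 0.9)
cfg = sim.SimulationConfig(K=2, M=6000, T=12, n_individuals=40,
                           z_dist=(0.1, 0.9), seed=7)
panel, truth, z, info = sim.simulate_admixed_cohort(
    cfg, {"anc0": mats[0], "anc1": mats[1]}, markers,
    rng=np.random.default_rng(7))

# decode local ancestry against the source panels
params = ak.estimate_hmm_params(
    {"anc0": mats[0].astype(float), "anc1": mats[1].astype(float)},
    q=np.array([0.5, 0.5]), tau=12.0)
track = ak.decode_ancestry(panel, params)
ga = ak.global_ancestry_from_local(track)
print("r(global ancestry, true z) =", round(np.corrcoef(ga[:, 0], z)[0, 1], 3))

# date the admixture from the diploid block counts of the true tracks
blocks, counts = ak.extract_blocks(truth, panel.markers, min_snps=1)
print("T estimate:", ak.estimate_admixing_time(z, counts).T_hat,
      "generations (true: 12)")
```

Output:

```
r(global ancestry, true z) = 0.991
T estimate: 11 generations (true: 12)
```

The correlation shows that averaging decoded local ancestry recovers each
individual's admixture proportion almost exactly; the block-count fit
recovers the simulated admixing time to within one generation.  (Dating
from *decoded* tracks needs the dense-marker regime — see the short-block
filter discussion in `docs/methods.md`.)

The same stages are available from the shell via the `admixkit` console
script (`admixkit simulate`, `infer-ancestry`, `mask`, `blocks`,
`date-admixture`, `sspca`, `ihs-scan`, `regions`, `overlap`, and `run` for
the seeded end-to-end pipeline with a checksummed output manifest).

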