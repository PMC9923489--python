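# holopop

Joint population genomics of a reef-building coral and its algal
endosymbionts from low-coverage whole-colony sequencing.

Shotgun libraries of coral colonies capture two genomes at once: the
cnidarian host's and, co-sampled, its *Cladocopium* symbionts'. `holopop`
implements both sides of that analysis for ~5x data, where genotypes
cannot be called reliably and everything must stay probabilistic:

**Host side** — genotype likelihoods under the standard biallelic error
model; site/individual filtering; clone detection by thresholding 1 − IBS
distances at the upper 95% confidence limit of technical-replicate
distances; PCA and admixture clustering directly on likelihoods (cluster
assignment at q ≥ 0.85); folded site-frequency spectra by EM (realSFS
style), π and Watterson's θ; weighted Hudson/Bhatia F_ST genome-wide and
in 50-kb/10-kb sliding windows; isolation-by-distance Mantel tests on
Vincenty geodesics; and two-population demographic inference — strict
isolation (div), isolation-with-migration (IM, symmetric or asymmetric)
and secondary contact (SC) — by Poisson composite likelihood on the folded
joint SFS, with an in-house Wright–Fisher diffusion solver for expected
spectra, multi-round perturbed optimization, physical-unit conversion
(N_ref = θ/(4 μ_gen L), times via a generation interval) and block
bootstrap intervals.

**Symbiont side** — the pooled-sample view of within-colony communities:
ITS2 genus screening (reference present at ≥ 3 mapped reads), plastid
allele counts per colony and locus, a linear mixed model for alleles per
locus, N_A ~ counts + latitude + shelf + host cluster + (1|locus) +
(1|colony), and a partial redundancy analysis of allele composition,
Y = latitude + shelf + host cluster | per-locus read counts, with
permutation inference.

A first-class synthetic-data generator (`holopop.synth`) reproduces the
statistical structure all of this assumes — diverged host clusters with
gene flow, 5x reads with planted clones and technical replicates, and
latitude/shelf-structured symbiont pools that are independent of host
cluster — so every stage is testable without any external data.

## Worked example

The numbered scripts under `analysis/` run the full synthetic study
(`python analysis/01_simulate_study.py`, then 02…07; each takes an
optional seed argument and writes tables under `results/`). A condensed
version in code:

```python
import numpy as np
from holopop import synth, gl, structure, sfs

cfg = synth.HostSimConfig(n_pops=3, sample_sizes=(14, 14, 14),
                          nu=(1.0, 1.0, 0.6), T_div=1.0,
                          M=0.5 * (1 - np.eye(3)), theta=2500.0,
                          seq_length=5e6, n_chunks=200, seed=1)
geno, true_sfs, pos, pops = synth.simulate_host_genotypes(cfg)
reads = synth.ReadSimConfig(mean_depth=5.0, n_clone_groups=3,
                            n_tech_replicates=4, seed=2)
pileup, glm, truth = synth.simulate_reads_and_gls(geno, reads, pos)

dists = gl.ibs_distance_matrix(glm, seed=3)
reps = [(a, b) for a, b, r in truth.itertuples(index=False)
        if r == "replicate"]
thr = gl.clone_threshold(dists, reps)
report = gl.prune_clones(dists, thr,
                         coverage=glm.coverage_per_individual(),
                         replicate_pairs=reps)
print(f"threshold {thr:.3f}: {len(report.groups)} clone groups")
```

This prints `threshold 0.091: 3 clone groups` — all three planted clone
pairs recovered, no false positives. The numbered scripts run the same
study (seed 1; script 02 prints `clone threshold 0.0894: 3 clone groups,
7 libraries removed, 42 kept`) and report per-cluster diversity π of 0.137/0.137/0.114 per variable
site (the third cluster is simulated at ν = 0.6), pairwise weighted F_ST
of 0.232/0.288/0.298, admixture at K = 3 assigning every colony to its
cluster with zero admixed individuals at q ≥ 0.85, and a demographic
model comparison in which strict isolation fits far worse than the
gene-flow models (logL −4052.5 against −3257.3 for asymmetric migration
and −3250.7 for secondary contact, which are statistically
indistinguishable from each other — the expected outcome when contact
spans most of the history). The symbiont analysis finds shelf position
explaining 41.8% of compositional variance (p = 0.001), latitude
significant but small (3.7%), and the host genetic cluster not
significant (p = 0.85) — the planted structure, since the generator ties
symbiont communities to geography and never to host cluster.

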