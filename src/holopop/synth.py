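"""Synthetic host and symbiont data with the statistical structure the
pipeline assumes.

Host genotypes come from a coalescent simulation of 2-3 diverged populations
(optionally with continuous or secondary-contact migration), read pileups are
Poisson-depth draws with per-base sequencing error at ~5x, and clonal ramets /
technical replicates are planted so clone detection can be exercised end to
end.  Symbiont "pools" are per-colony plastid allele-count tables whose
allele richness and composition vary with latitude and shelf position but not
with the host's genetic cluster.

Time and rate units follow the diffusion convention used by the demographic
models: sizes ``nu`` are relative to a reference size N_ref implied by
``theta = 4 N_ref mu L``, times are in units of 2 N_ref generations, and
migration entries ``M[i, j]`` are 2 N_ref m_ij (expected migrant lineages
into population i per 2 N_ref generations).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import msprime
import numpy as np
import pandas as pd

from .gl import PileupCounts, compute_genotype_likelihoods, GLMatrix

__all__ = [
    "HostSimConfig",
    "ReadSimConfig",
    "SymbiontSimConfig",
    "simulate_host_genotypes",
    "simulate_reads_and_gls",
    "simulate_symbiont_pools",
    "make_study_metadata",
    "true_joint_sfs",
]

SHELF_LEVELS = ("inshore", "midshelf", "offshore")


@dataclass
class HostSimConfig:
    """Coalescent configuration for the host populations."""

    n_pops: int = 3
    sample_sizes: tuple = (20, 20, 20)  # diploid individuals per population
    nu: tuple | None = None  # sizes relative to N_ref (default: all 1)
    T_div: float = 1.0  # split time, units of 2 N_ref generations
    T_sc: float | None = None  # secondary-contact onset (None: migration always on)
    M: np.ndarray | None = None  # scaled migration matrix, 2 N_ref m_ij
    theta: float = 4000.0  # 4 N_ref mu L
    seq_length: float = 5e6
    mu_per_gen: float = 1e-8
    recombination_rate: float = 1e-8
    n_chunks: int = 1  # >1: simulate as independent (unlinked) blocks
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_pops < 1:
            raise ValueError("n_pops must be >= 1")
        if len(self.sample_sizes) != self.n_pops:
            raise ValueError("sample_sizes must have one entry per population")
        if any(s < 2 for s in self.sample_sizes):
            raise ValueError("sample_sizes entries must be >= 2")
        if self.nu is None:
            self.nu = tuple([1.0] * self.n_pops)
        if len(self.nu) != self.n_pops:
            raise ValueError("nu must have one entry per population")
        if any(v <= 0 for v in self.nu):
            raise ValueError("nu entries must be positive")
        if self.T_div < 0:
            raise ValueError("T_div must be >= 0")
        if self.T_sc is not None and not 0 <= self.T_sc <= self.T_div:
            raise ValueError("T_sc must satisfy 0 <= T_sc <= T_div")
        if self.theta <= 0 or self.mu_per_gen <= 0 or self.seq_length <= 0:
            raise ValueError("theta, mu_per_gen and seq_length must be positive")
        if self.M is not None:
            m = np.asarray(self.M, dtype=float)
            if m.shape != (self.n_pops, self.n_pops):
                raise ValueError("M must be n_pops x n_pops")
            off = m[~np.eye(self.n_pops, dtype=bool)]
            if np.any(off < 0):
                raise ValueError("migration rates M must be >= 0")

    @property
    def n_ref(self) -> float:
        return self.theta / (4.0 * self.mu_per_gen * self.seq_length)


@dataclass
class ReadSimConfig:
    """Read-level configuration: depth, error, planted clones/replicates."""

    mean_depth: float = 5.0
    error_rate: float = 0.01
    n_clone_groups: int = 0
    ramets_per_group: int = 2
    n_tech_replicates: int = 0
    replicate_error_factor: float = 3.0
    seed: int = 1

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        if self.n_clone_groups < 0 or self.n_tech_replicates < 0:
            raise ValueError("clone/replicate counts must be >= 0")
        if self.ramets_per_group < 2:
            raise ValueError("ramets_per_group must be >= 2")


@dataclass
class SymbiontSimConfig:
    """Pooled plastid community configuration.

    Allele richness per colony-locus follows a linear model on the identity
    scale (intercept + latitude slope per SD of latitude + shelf offsets +
    locus offset + Gaussian noise, rounded and clipped to the locus's allele
    pool), so the mixed-model estimand for the latitude effect is exactly
    ``latitude_effect``.  Which alleles are present, and their proportions
    (Dirichlet), are tilted by shelf- and latitude-linked loadings to plant
    compositional structure.  Host cluster never enters the generator.
    """

    n_colonies: int = 100
    n_loci: int = 19
    alleles_min: int = 2
    alleles_max: int = 17
    base_richness: float = 3.0
    latitude_effect: float = 0.3  # alleles per SD of latitude
    shelf_richness_effects: dict = field(
        default_factory=lambda: {"inshore": 0.0, "midshelf": 0.2, "offshore": 0.8}
    )
    latitude_comp_effect: float = 0.5
    shelf_comp_effect: float = 2.0
    richness_noise_sd: float = 1.0
    locus_sd: float = 0.5
    colony_sd: float = 0.5
    depth_mean: float = 90.0
    depth_min: int = 25
    dirichlet_conc: float = 5.0
    evenness_floor: float = 0.35  # mixture weight of the uniform component
    seed: int = 1

    def __post_init__(self) -> None:
        if not 1 <= self.alleles_min <= self.alleles_max <= 17:
            raise ValueError("allele range must satisfy 1 <= min <= max <= 17")
        for name in ("latitude_effect", "latitude_comp_effect", "shelf_comp_effect"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if not all(np.isfinite(v) for v in self.shelf_richness_effects.values()):
            raise ValueError("shelf_richness_effects must be finite")


def _demography(cfg: HostSimConfig) -> msprime.Demography:
    n_ref = cfg.n_ref
    demog = msprime.Demography()
    for i in range(cfg.n_pops):
        demog.add_population(name=f"pop{i}", initial_size=cfg.nu[i] * n_ref)
    if cfg.n_pops > 1:
        demog.add_population(name="anc", initial_size=n_ref)
        t_gen = cfg.T_div * 2.0 * n_ref
        demog.add_population_split(
            time=t_gen,
            derived=[f"pop{i}" for i in range(cfg.n_pops)],
            ancestral="anc",
        )
        if cfg.M is not None:
            m = np.asarray(cfg.M, dtype=float) / (2.0 * n_ref)
            for i in range(cfg.n_pops):
                for j in range(cfg.n_pops):
                    if i != j and m[i, j] > 0:
                        demog.set_migration_rate(
                            source=f"pop{i}", dest=f"pop{j}", rate=m[i, j]
                        )
            if cfg.T_sc is not None and cfg.T_sc < cfg.T_div:
                # contact only during the last T_sc time units
                demog.add_migration_rate_change(
                    time=cfg.T_sc * 2.0 * n_ref, rate=0.0
                )
        demog.sort_events()
    return demog


def simulate_host_genotypes(
    cfg: HostSimConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Simulate diploid genotypes under the configured demography.

    Returns ``(genotypes, sfs, positions, pop_of_individual)`` where
    ``genotypes`` is sites x individuals in {0, 1, 2} derived copies,
    ``sfs`` is the joint derived-allele-count histogram (one axis per
    population, shape prod(2 n_i + 1)), and ``positions`` are integer base
    positions.  Multi-allelic sites are discarded so every retained site is
    a biallelic SNP.
    """
    demog = _demography(cfg)
    samples = {f"pop{i}": cfg.sample_sizes[i] for i in range(cfg.n_pops)}
    chunk_len = cfg.seq_length / cfg.n_chunks
    keep, positions = [], []
    reps = msprime.sim_ancestry(
        samples=samples,
        demography=demog,
        sequence_length=chunk_len,
        recombination_rate=cfg.recombination_rate if cfg.n_chunks == 1 else 0.0,
        num_replicates=cfg.n_chunks if cfg.n_chunks > 1 else None,
        random_seed=cfg.seed,
    )
    if cfg.n_chunks == 1:
        reps = [reps]
    for chunk, ts in enumerate(reps):
        mts = msprime.sim_mutations(
            ts,
            rate=cfg.mu_per_gen,
            random_seed=cfg.seed + 1 + chunk,
            model=msprime.BinaryMutationModel(),
        )
        offset = int(chunk * chunk_len)
        for var in mts.variants():
            if len(var.alleles) == 2 and var.genotypes.max() <= 1:
                keep.append(var.genotypes.copy())
                positions.append(offset + int(var.site.position))
    if not keep:
        hap = np.zeros((0, 2 * sum(cfg.sample_sizes)), dtype=np.int8)
    else:
        hap = np.asarray(keep, dtype=np.int8)
    positions = np.asarray(positions, dtype=int)
    # collapse haplotype pairs to diploid genotypes (msprime orders samples
    # by population, two consecutive haplotypes per individual)
    genotypes = hap[:, 0::2] + hap[:, 1::2]
    pop_of_individual = np.repeat(np.arange(cfg.n_pops), cfg.sample_sizes)
    sfs = true_joint_sfs(genotypes, pop_of_individual, cfg.sample_sizes)
    return genotypes.astype(np.int8), sfs, positions, pop_of_individual


def true_joint_sfs(
    genotypes: np.ndarray, pop_of_individual: np.ndarray, sample_sizes
) -> np.ndarray:
    """Joint derived-allele-count histogram of a genotype matrix."""
    n_pops = len(sample_sizes)
    shape = tuple(2 * n + 1 for n in sample_sizes)
    sfs = np.zeros(shape)
    counts = np.stack(
        [genotypes[:, pop_of_individual == p].sum(axis=1) for p in range(n_pops)],
        axis=1,
    )
    if counts.size:
        np.add.at(sfs, tuple(counts[:, p] for p in range(n_pops)), 1.0)
    return sfs


def simulate_reads_and_gls(
    genotypes: np.ndarray,
    cfg: ReadSimConfig,
    positions: np.ndarray | None = None,
    sample_ids: list[str] | None = None,
) -> tuple[PileupCounts, GLMatrix, pd.DataFrame]:
    """Poisson-depth reads with sequencing error, plus planted clones and
    technical replicates.

    Clonal ramets are appended as new columns that copy a source genotype but
    receive independent reads (distinct physical samples).  Technical
    replicates are an independent re-sequencing of an existing sample with an
    extra library-error component (``replicate_error_factor`` x the base
    error rate): re-preps accumulate batch artifacts, so replicate pairs are
    slightly noisier than clone pairs — the margin the replicate-derived
    clone threshold relies on.  (Copying the exact read set and re-noising
    it would instead make replicates *more* similar than clones at
    heterozygous sites, because the two draws would share binomial sampling
    noise.)  Returns (pileup, GLMatrix, truth table of clone/replicate
    pairs).
    """
    rng = np.random.default_rng(cfg.seed)
    S, N = genotypes.shape
    if sample_ids is None:
        sample_ids = [f"ind{i:03d}" for i in range(N)]
    sample_ids = list(sample_ids)
    geno = genotypes.astype(np.int8)

    truth = []
    # plant clone groups: extra ramets copying a source genotype
    clone_sources = rng.choice(N, size=min(cfg.n_clone_groups, N), replace=False)
    extra_cols, extra_ids = [], []
    for g, src in enumerate(clone_sources):
        members = [sample_ids[src]]
        for r in range(1, cfg.ramets_per_group):
            name = f"{sample_ids[src]}_ramet{r}"
            extra_cols.append(geno[:, src])
            extra_ids.append(name)
            members.append(name)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                truth.append((members[i], members[j], "clone"))
    if extra_cols:
        geno = np.column_stack([geno] + extra_cols)
        sample_ids = sample_ids + extra_ids

    n_total = geno.shape[1]
    depth = rng.poisson(cfg.mean_depth, size=(S, n_total))
    counts = _draw_reads(geno, depth, cfg.error_rate, rng)

    # technical replicates: independent re-sequencing with extra library error
    rep_sources = rng.choice(N, size=min(cfg.n_tech_replicates, N), replace=False)
    rep_err = min(cfg.replicate_error_factor * cfg.error_rate, 0.45)
    rep_cols, rep_ids = [], []
    for src in rep_sources:
        name = f"{sample_ids[src]}_rep"
        rep_depth = rng.poisson(cfg.mean_depth, size=(S, 1))
        rep_counts = _draw_reads(
            geno[:, src : src + 1], rep_depth, rep_err, rng
        )
        rep_cols.append(rep_counts[:, 0, :])
        rep_ids.append(name)
        truth.append((sample_ids[src], name, "replicate"))
    if rep_cols:
        counts = np.concatenate(
            [counts, np.stack(rep_cols, axis=1)], axis=1
        )
        geno = np.column_stack([geno] + [geno[:, s] for s in rep_sources])
        sample_ids = sample_ids + rep_ids

    if positions is None:
        positions = np.arange(S)
    pileup = PileupCounts(
        counts=counts,
        major=np.zeros(S, dtype=int),
        minor=np.ones(S, dtype=int),
        positions=np.asarray(positions),
        sample_ids=sample_ids,
    )
    err = max(cfg.error_rate, 1e-6)  # GL model needs a positive error rate
    glm = compute_genotype_likelihoods(pileup, error_rate=err)
    truth_df = pd.DataFrame(truth, columns=["sample_a", "sample_b", "relation"])
    return pileup, glm, truth_df


def _draw_reads(
    geno: np.ndarray, depth: np.ndarray, error_rate: float, rng
) -> np.ndarray:
    """Base counts (S, N, 4): major=base 0, minor=base 1, errors spread to all."""
    S, N = geno.shape
    p_minor_true = geno / 2.0
    n_minor_true = rng.binomial(depth, p_minor_true)
    n_major_true = depth - n_minor_true
    counts = np.zeros((S, N, 4), dtype=np.int32)
    e = error_rate
    if e > 0:
        # each true-allele read is misread to one of the other 3 bases w.p. e
        maj_err = rng.binomial(n_major_true, e)
        min_err = rng.binomial(n_minor_true, e)
        counts[:, :, 0] = n_major_true - maj_err
        counts[:, :, 1] = n_minor_true - min_err
        for src_err, other in ((maj_err, (1, 2, 3)), (min_err, (0, 2, 3))):
            split = rng.multinomial(
                src_err.ravel(), [1 / 3] * 3
            ).reshape(S, N, 3)
            for k, b in enumerate(other):
                counts[:, :, b] += split[:, :, k]
    else:
        counts[:, :, 0] = n_major_true
        counts[:, :, 1] = n_minor_true
    return counts



def make_study_metadata(
    n_colonies: int,
    n_reefs: int = 12,
    lat_range: tuple = (-23.5, -11.0),
    host_clusters: tuple = ("cluster1A", "cluster1B", "cluster2"),
    seed: int = 1,
) -> pd.DataFrame:
    """Sample metadata: reef, coordinates, shelf position, host cluster.

    Reefs are spread along the latitude range with shelf positions cycling
    inshore/midshelf/offshore; host clusters are assigned independently of
    location (the generator's symbiont structure must not track them).
    """
    rng = np.random.default_rng(seed)
    lats = np.linspace(lat_range[0], lat_range[1], n_reefs)
    lons = 145.5 + 0.35 * np.arange(n_reefs) % 3 + rng.normal(0, 0.2, n_reefs)
    shelf = [SHELF_LEVELS[i % 3] for i in range(n_reefs)]
    reef_of = rng.integers(0, n_reefs, size=n_colonies)
    return pd.DataFrame(
        {
            "sample": [f"col{i:03d}" for i in range(n_colonies)],
            "reef": [f"reef{r:02d}" for r in reef_of],
            "latitude": lats[reef_of] + rng.normal(0, 0.05, n_colonies),
            "longitude": lons[reef_of],
            "shelf": [shelf[r] for r in reef_of],
            "host_cluster": rng.choice(host_clusters, size=n_colonies),
        }
    )


def simulate_symbiont_pools(
    cfg: SymbiontSimConfig, metadata: pd.DataFrame
) -> pd.DataFrame:
    """Pooled plastid allele counts per colony and locus (long format).

    Returns a DataFrame with columns (sample, locus, allele, count).  Allele
    richness follows the configured latitude/shelf effects; allele identity
    and proportions are tilted by shelf- and latitude-linked loadings.  The
    ``host_cluster`` metadata column is required but never used, so any
    downstream association with it is spurious by construction.
    """
    for col in ("sample", "latitude", "shelf"):
        if col not in metadata.columns:
            raise KeyError(f"metadata missing required column: {col!r}")
    if "host_cluster" not in metadata.columns:
        raise KeyError("metadata missing required column: 'host_cluster'")
    rng = np.random.default_rng(cfg.seed)
    n_col = len(metadata)
    if cfg.n_colonies != n_col:
        raise ValueError(
            f"metadata has {n_col} rows but config expects {cfg.n_colonies}"
        )
    lat = metadata["latitude"].to_numpy(float)
    lat_z = (lat - lat.mean()) / max(lat.std(), 1e-12)
    shelf = metadata["shelf"].to_numpy()

    pool_sizes = rng.integers(cfg.alleles_min, cfg.alleles_max + 1, cfg.n_loci)
    locus_offsets = rng.normal(0.0, cfg.locus_sd, cfg.n_loci)
    colony_offsets = rng.normal(0.0, cfg.colony_sd, n_col)
    # allele loadings planting compositional (beta-diversity) structure
    shelf_load = {
        lev: [rng.normal(0, 1, a) for a in pool_sizes] for lev in SHELF_LEVELS
    }
    lat_load = [rng.normal(0, 1, a) for a in pool_sizes]
    base_load = [rng.normal(0, 1, a) for a in pool_sizes]

    rows = []
    for c in range(n_col):
        sre = cfg.shelf_richness_effects.get(shelf[c], 0.0)
        for l in range(cfg.n_loci):
            a_pool = int(pool_sizes[l])
            mean_k = (
                cfg.base_richness
                + cfg.latitude_effect * lat_z[c]
                + sre
                + locus_offsets[l]
                + colony_offsets[c]
            )
            k = int(np.clip(round(mean_k + rng.normal(0, cfg.richness_noise_sd)),
                            1, a_pool))
            # allele inclusion tilted by shelf/latitude loadings
            score = (
                base_load[l]
                + cfg.shelf_comp_effect * shelf_load[shelf[c]][l]
                + cfg.latitude_comp_effect * lat_z[c] * lat_load[l]
                + rng.gumbel(0, 1, a_pool)
            )
            present = np.argsort(score)[::-1][:k]
            w = np.exp(
                base_load[l][present]
                + cfg.shelf_comp_effect * shelf_load[shelf[c]][l][present]
                + cfg.latitude_comp_effect * lat_z[c] * lat_load[l][present]
            )
            w /= w.sum()
            # mixing in a uniform floor keeps every present allele at a
            # detectable expected share, so observed richness tracks the
            # planted richness rather than sequencing depth
            pi = rng.dirichlet(cfg.dirichlet_conc * k * w)
            pi = (1.0 - cfg.evenness_floor) * pi + cfg.evenness_floor / k
            depth = cfg.depth_min + rng.poisson(max(cfg.depth_mean - cfg.depth_min, 0))
            counts = rng.multinomial(depth, pi)
            for a in range(k):
                if counts[a] > 0:
                    rows.append(
                        (
                            metadata["sample"].iloc[c],
                            f"locus{l:02d}",
                            f"a{present[a]:02d}",
                            int(counts[a]),
                        )
                    )
    return pd.DataFrame(rows, columns=["sample", "locus", "allele", "count"])
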