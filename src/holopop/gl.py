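"""Genotype likelihoods, dataset filtering, allele inference and clone detection.

This module is the entry point of the host pipeline: it turns per-site read
pileups from low-coverage (~5x) sequencing into genotype likelihoods under the
standard biallelic error model, applies the two-stage site/individual
filters used for SNP discovery and analysis, estimates per-site minor allele
frequencies by EM, and detects clonal ramets from an identity-by-state (IBS)
distance matrix thresholded on technical-replicate distances.

Genotypes are coded as g in {0, 1, 2} copies of the minor allele.  All
likelihoods are stored in log10 units and normalized so the per-entry maximum
is 0; entries with zero reads are flat (all zeros) and flagged in a mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PileupCounts",
    "GLMatrix",
    "SiteAlleleInfo",
    "IBSMatrix",
    "FilterReport",
    "CloneReport",
    "compute_genotype_likelihoods",
    "filter_dataset",
    "infer_site_alleles",
    "estimate_site_frequencies",
    "ibs_distance_matrix",
    "clone_threshold",
    "prune_clones",
]


@dataclass
class PileupCounts:
    """Quality-filtered base counts per site and individual.

    ``counts`` has shape (sites, individuals, 4) over bases A, C, G, T.
    ``major`` / ``minor`` give the base index (0..3) of the two alleles at
    each site.
    """

    counts: np.ndarray
    major: np.ndarray
    minor: np.ndarray
    positions: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        if np.any(self.counts < 0):
            raise ValueError("pileup base counts must be non-negative")
        if np.any(self.major == self.minor):
            raise ValueError("major and minor alleles must be distinct")

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=2)


@dataclass
class GLMatrix:
    """Sites x individuals x 3 genotype log10-likelihoods.

    ``gl[s, i, g]`` is the log10 likelihood of g copies of the minor allele,
    normalized so that max_g gl[s, i, g] = 0.  ``mask`` is True where the
    entry carries no reads (flat likelihoods).  ``depth`` and ``minor_count``
    retain read counts where known (needed for read-sampled IBS); they may be
    None when the matrix was read from a likelihood-only file.
    """

    gl: np.ndarray
    mask: np.ndarray
    positions: np.ndarray
    sample_ids: list[str]
    depth: np.ndarray | None = None
    minor_count: np.ndarray | None = None
    stages_applied: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.gl)):
            raise ValueError("genotype likelihoods must be finite")

    @property
    def n_sites(self) -> int:
        return self.gl.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.gl.shape[1]

    def coverage_per_individual(self, min_depth: int = 3) -> np.ndarray:
        """Number of sites covered by >= min_depth reads per individual."""
        if self.depth is None:
            return (~self.mask).sum(axis=0)
        return (self.depth >= min_depth).sum(axis=0)

    def subset(self, sites=None, individuals=None) -> "GLMatrix":
        s = np.arange(self.n_sites) if sites is None else np.asarray(sites)
        i = (
            np.arange(self.n_individuals)
            if individuals is None
            else np.asarray(individuals)
        )
        return GLMatrix(
            gl=self.gl[np.ix_(s, i)],
            mask=self.mask[np.ix_(s, i)],
            positions=self.positions[s],
            sample_ids=[self.sample_ids[j] for j in i],
            depth=None if self.depth is None else self.depth[np.ix_(s, i)],
            minor_count=(
                None
                if self.minor_count is None
                else self.minor_count[np.ix_(s, i)]
            ),
            stages_applied=set(self.stages_applied),
        )

    def linear(self) -> np.ndarray:
        """Likelihoods on the linear scale (per-entry max = 1)."""
        return 10.0 ** self.gl


@dataclass
class SiteAlleleInfo:
    """Per-site allele summary: ML minor allele frequency and polymorphism LRT."""

    maf: np.ndarray
    lrt_pvalue: np.ndarray
    keep: np.ndarray
    swapped: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "maf": self.maf,
                "lrt_pvalue": self.lrt_pvalue,
                "keep": self.keep,
                "swapped": self.swapped,
            }
        )


@dataclass
class IBSMatrix:
    """Pairwise genetic distance d = 1 - IBS with joint-coverage counts.

    ``dist`` is symmetric with zero diagonal; entries with fewer than
    ``min_sites`` jointly covered sites are NaN and flagged unreliable.
    """

    dist: np.ndarray
    n_sites: np.ndarray
    sample_ids: list[str]
    min_sites: int

    @property
    def reliable(self) -> np.ndarray:
        return self.n_sites >= self.min_sites

    def pair(self, a: str, b: str) -> float:
        ia, ib = self.sample_ids.index(a), self.sample_ids.index(b)
        return float(self.dist[ia, ib])


@dataclass
class FilterReport:
    stage: str
    sites_in: int
    sites_out: int
    individuals_in: int
    individuals_out: int
    sites_removed_depth: int
    individuals_removed_rank: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


@dataclass
class CloneReport:
    kept: list[str]
    removed: list[str]
    groups: list[list[str]]
    threshold: float

    @property
    def n_clonal_pairs(self) -> int:
        return sum(len(g) * (len(g) - 1) // 2 for g in self.groups)


def compute_genotype_likelihoods(
    pileup: PileupCounts, error_rate: float = 0.01
) -> GLMatrix:
    """Biallelic genotype likelihoods from base counts.

    Under the standard model a read from a homozygote shows the carried
    allele with probability 1 - e and each other base with e/3; a heterozygote
    emits either allele with probability 1/2.  With counts (n_major, n_minor,
    n_other) the per-genotype likelihood is a product over reads, computed
    here in log10 and normalized per entry.
    """
    if not 0.0 < error_rate < 0.5:
        raise ValueError(f"error_rate must be in (0, 0.5), got {error_rate}")
    counts = pileup.counts
    n_sites, n_ind, _ = counts.shape
    idx = np.arange(n_sites)
    n_major = counts[idx, :, pileup.major]
    n_minor = counts[idx, :, pileup.minor]
    depth = counts.sum(axis=2)
    n_other = depth - n_major - n_minor

    e = error_rate
    # P(base | genotype): rows g=0,1,2 copies of minor; cols major/minor/other
    p_major = np.array([1 - e, 0.5 * (1 - e) + 0.5 * (e / 3), e / 3])
    p_minor = np.array([e / 3, 0.5 * (1 - e) + 0.5 * (e / 3), 1 - e])
    p_other = np.array([2 * e / 3, 2 * e / 3, 2 * e / 3])

    gl = (
        n_major[..., None] * np.log10(p_major)
        + n_minor[..., None] * np.log10(p_minor)
        + n_other[..., None] * np.log10(p_other)
    )
    gl -= gl.max(axis=2, keepdims=True)
    mask = depth == 0
    gl[mask] = 0.0
    return GLMatrix(
        gl=gl,
        mask=mask,
        positions=np.asarray(pileup.positions),
        sample_ids=list(pileup.sample_ids),
        depth=depth,
        minor_count=n_minor,
    )


def filter_dataset(
    gl: GLMatrix,
    stage: str,
    min_depth: int = 3,
    discovery_site_fraction: float = 0.40,
    discovery_individual_fraction: float = 0.65,
    analysis_site_fraction: float = 0.85,
) -> tuple[GLMatrix, FilterReport]:
    """Two-stage site/individual filtering.

    discovery: retain sites with >= 3 reads in >= 40% of individuals, then
    keep only the top 65% of individuals ranked by the number of positions
    covered by >= 3 reads (floor of 0.65*n; ties broken by sample id).
    analysis: retain sites with >= 3 reads in >= 85% of individuals.

    The individual cut is recorded on the returned matrix so re-applying the
    same stage is a no-op on individuals (idempotence).
    """
    if stage not in ("discovery", "analysis"):
        raise ValueError(f"unknown filter stage: {stage!r}")
    if gl.depth is None:
        raise ValueError("filtering requires per-entry depth information")

    n_sites, n_ind = gl.n_sites, gl.n_individuals
    covered = gl.depth >= min_depth

    # site criterion is evaluated over the full individual set (a site with
    # 3+ reads in 4 of 10 individuals meets the 40% discovery cut), then
    # the individual cut is applied
    frac = (
        discovery_site_fraction if stage == "discovery" else analysis_site_fraction
    )
    site_frac = covered.mean(axis=1)
    keep_sites = np.flatnonzero(site_frac >= frac - 1e-12)
    sites_removed = n_sites - keep_sites.size

    individuals_removed = 0
    keep_ind = np.arange(n_ind)
    if stage == "discovery" and "discovery_individuals" not in gl.stages_applied:
        n_keep = int(np.floor(discovery_individual_fraction * n_ind))
        cov_counts = covered.sum(axis=0)
        # rank by total covered positions descending, ties by sample id
        order = sorted(
            range(n_ind), key=lambda j: (-cov_counts[j], gl.sample_ids[j])
        )
        keep_ind = np.sort(np.array(order[:n_keep], dtype=int))
        individuals_removed = n_ind - n_keep

    if keep_sites.size == 0 or keep_ind.size == 0:
        raise ValueError(
            f"{stage} filtering removed everything "
            f"({sites_removed}/{n_sites} sites, {individuals_removed} individuals)"
        )

    out = gl.subset(sites=keep_sites, individuals=keep_ind)
    out.stages_applied = set(gl.stages_applied) | {stage}
    if stage == "discovery":
        out.stages_applied.add("discovery_individuals")
    report = FilterReport(
        stage=stage,
        sites_in=n_sites,
        sites_out=keep_sites.size,
        individuals_in=n_ind,
        individuals_out=keep_ind.size,
        sites_removed_depth=sites_removed,
        individuals_removed_rank=individuals_removed,
    )
    return out, report


def estimate_site_frequencies(
    gl: GLMatrix, max_iter: int = 100, tol: float = 1e-10
) -> tuple[np.ndarray, np.ndarray]:
    """ML per-site frequency of the minor-coded allele by EM over individuals.

    Returns (freq, loglik) where loglik is the per-site natural-log
    likelihood at the estimate, assuming Hardy-Weinberg genotype proportions.
    """
    lik = gl.linear()  # (S, N, 3)
    freq = np.full(gl.n_sites, 0.2)
    for _ in range(max_iter):
        f = freq[:, None]
        prior = np.stack(
            [(1 - f) ** 2, 2 * f * (1 - f), f**2], axis=2
        )  # (S, N via broadcast, 3)
        w = lik * prior
        denom = w.sum(axis=2)
        eg = (w[:, :, 1] + 2 * w[:, :, 2]) / np.maximum(denom, 1e-300)
        new = eg.mean(axis=1) / 2.0
        new = np.clip(new, 0.0, 1.0)
        if np.max(np.abs(new - freq)) < tol:
            freq = new
            break
        freq = new
    ll = _freq_loglik(lik, freq)
    return freq, ll


def _freq_loglik(lik: np.ndarray, freq: np.ndarray) -> np.ndarray:
    f = freq[:, None]
    prior = np.stack([(1 - f) ** 2, 2 * f * (1 - f), f**2], axis=2)
    per_ind = (lik * prior).sum(axis=2)
    return np.log(np.maximum(per_ind, 1e-300)).sum(axis=1)


def infer_site_alleles(
    gl: GLMatrix, maf_min: float = 0.05, lrt_alpha: float = 1e-6
) -> SiteAlleleInfo:
    """Minor allele frequency and polymorphism test per site.

    The frequency is the ML estimate from the genotype likelihoods (EM over
    individuals under Hardy-Weinberg).  The polymorphism likelihood-ratio
    test compares the ML frequency with the best monomorphic model
    (frequency 0 or 1); sites are kept iff p < lrt_alpha and MAF >= maf_min.
    If the estimated frequency of the minor-coded allele exceeds 0.5 the
    allele labels are swapped (flagged in ``swapped``).
    """
    freq, ll_hat = estimate_site_frequencies(gl)
    lik = gl.linear()
    ll_0 = _freq_loglik(lik, np.zeros(gl.n_sites))
    ll_1 = _freq_loglik(lik, np.ones(gl.n_sites))
    ll_null = np.maximum(ll_0, ll_1)
    lrt = np.maximum(2.0 * (ll_hat - ll_null), 0.0)
    pval = stats.chi2.sf(lrt, df=1)
    swapped = freq > 0.5
    maf = np.where(swapped, 1.0 - freq, freq)
    keep = (pval < lrt_alpha) & (maf >= maf_min)
    return SiteAlleleInfo(maf=maf, lrt_pvalue=pval, keep=keep, swapped=swapped)


def ibs_distance_matrix(
    gl: GLMatrix,
    seed: int | None = None,
    mode: str = "sample",
    min_sites: int = 100,
) -> IBSMatrix:
    """Pairwise 1 - IBS distances from single sampled (or called) alleles.

    In ``sample`` mode one read is drawn per covered site and individual and
    its allele is used as a haploid call, the standard approach for
    low-coverage data.  In ``call`` mode the most likely genotype is used and
    heterozygotes contribute a randomly sampled allele.  The distance for a
    pair is the proportion of jointly covered sites whose haploid calls
    differ; pairs sharing fewer than ``min_sites`` sites are NaN.
    """
    if gl.n_individuals < 2:
        raise ValueError("IBS requires at least two individuals")
    rng = np.random.default_rng(seed)
    S, N = gl.n_sites, gl.n_individuals
    if mode == "sample":
        if gl.depth is None or gl.minor_count is None:
            raise ValueError("sample mode requires read counts; use mode='call'")
        depth = gl.depth
        p_minor = np.divide(
            gl.minor_count, depth, out=np.zeros((S, N)), where=depth > 0
        )
        calls = (rng.random((S, N)) < p_minor).astype(np.int8)
    elif mode == "call":
        g = np.argmax(gl.gl, axis=2)
        calls = np.where(g == 2, 1, 0).astype(np.int8)
        het = g == 1
        calls[het] = (rng.random(int(het.sum())) < 0.5).astype(np.int8)
    else:
        raise ValueError(f"unknown IBS mode: {mode!r}")

    covered = ~gl.mask
    callsf = calls.astype(float)
    # joint coverage and mismatch counts via matrix products
    cov = covered.astype(float)
    n_joint = cov.T @ cov
    # mismatches: sum over sites of [a != b] on jointly covered sites
    a1 = callsf * cov
    a0 = (1.0 - callsf) * cov
    mism = a1.T @ a0 + a0.T @ a1
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = np.where(n_joint > 0, mism / np.maximum(n_joint, 1), np.nan)
    dist[n_joint == 0] = np.nan
    np.fill_diagonal(dist, 0.0)
    return IBSMatrix(
        dist=dist,
        n_sites=n_joint.astype(int),
        sample_ids=list(gl.sample_ids),
        min_sites=min_sites,
    )


def clone_threshold(
    dists: IBSMatrix,
    replicate_pairs: list[tuple[str, str]],
    method: str = "t",
) -> float:
    """Clone-calling threshold from technical-replicate distances.

    The threshold is the upper 95% confidence limit of the mean replicate
    distance: mean + t_{0.975, n-1} * sd / sqrt(n) (``method='t'``), or the
    normal-approximation variant mean + 1.96 * sd (``method='normal'``).
    Requires at least two replicate pairs; with fewer, supply a threshold
    explicitly to :func:`prune_clones`.
    """
    if len(replicate_pairs) < 2:
        raise ValueError(
            "need >= 2 replicate pairs to derive a threshold; "
            "supply an explicit threshold instead"
        )
    d = np.array([dists.pair(a, b) for a, b in replicate_pairs])
    if np.any(np.isnan(d)):
        raise ValueError("replicate pair without jointly covered sites")
    n = d.size
    sd = d.std(ddof=1)
    if method == "t":
        thr = d.mean() + stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
    elif method == "normal":
        thr = d.mean() + 1.96 * sd
    else:
        raise ValueError(f"unknown threshold method: {method!r}")
    return float(np.clip(thr, 0.0, 1.0))


def prune_clones(
    dists: IBSMatrix,
    threshold: float,
    coverage: np.ndarray | dict | None = None,
    replicate_pairs: list[tuple[str, str]] | None = None,
) -> CloneReport:
    """Collapse clone groups to a single representative.

    Technical replicates are removed first (the lower-coverage member of each
    pair).  Clone groups are the connected components of the graph whose
    edges join pairs with distance < threshold; each group keeps its
    highest-coverage member (ties broken by sample id).
    """
    ids = list(dists.sample_ids)
    if coverage is None:
        cov = {s: 0.0 for s in ids}
    elif isinstance(coverage, dict):
        cov = {s: float(coverage[s]) for s in ids}
    else:
        cov = {s: float(c) for s, c in zip(ids, np.asarray(coverage))}

    removed = []
    active = set(ids)
    for a, b in replicate_pairs or []:
        drop = b if cov[a] >= cov[b] else a
        if drop in active:
            active.discard(drop)
            removed.append(drop)

    g = nx.Graph()
    g.add_nodes_from(active)
    idx = {s: i for i, s in enumerate(ids)}
    act = sorted(active)
    for i, a in enumerate(act):
        for b in act[i + 1 :]:
            d = dists.dist[idx[a], idx[b]]
            if np.isfinite(d) and d < threshold:
                g.add_edge(a, b)

    groups, kept = [], []
    for comp in nx.connected_components(g):
        members = sorted(comp)
        rep = max(members, key=lambda s: (cov[s], s))
        kept.append(rep)
        if len(members) > 1:
            groups.append(members)
        removed.extend(m for m in members if m != rep)
    return CloneReport(
        kept=sorted(kept), removed=sorted(removed), groups=groups,
        threshold=float(threshold),
    )
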