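"""Population structure from genotype likelihoods: covariance/PCA and
admixture clustering.

Both methods work directly on genotype likelihoods rather than called
genotypes, which is essential at ~5x coverage.  The PCA iteratively
estimates individual allele frequencies from a low-rank model (the PCAngsd
approach): posterior genotype dosages given the current frequencies are
decomposed by truncated SVD, the reconstruction updates the frequencies,
and the final covariance is computed from standardized posterior dosages.
The admixture model is the standard GL-aware likelihood (NGSadmix):
P(data_ij) = sum_g GL_ij(g) Binom(g; 2, pi_ij) with pi = Q F^T, maximized
by EM from multiple random starts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gl import GLMatrix, estimate_site_frequencies

__all__ = [
    "CovarianceResult",
    "AdmixtureResult",
    "gl_pca",
    "admixture_em",
    "assign_clusters",
]


@dataclass
class CovarianceResult:
    """Individual covariance matrix with its eigen-decomposition and the
    inferred individual allele-frequency matrix (0 = major homozygote,
    0.5 = heterozygote, 1 = minor homozygote) used downstream as the
    ordination response."""

    cov: np.ndarray
    eigenvalues: np.ndarray
    scores: np.ndarray
    pct_variance: np.ndarray
    indiv_allele_freq: np.ndarray  # sites x individuals, in [0, 1]
    site_freq: np.ndarray
    sample_ids: list[str]
    converged: bool
    n_iter: int


@dataclass
class AdmixtureResult:
    """Ancestry proportions Q (individuals x K), cluster allele
    frequencies F (sites x K) and the final log-likelihood."""

    Q: np.ndarray
    F: np.ndarray
    loglik: float
    K: int
    sample_ids: list[str]
    converged: bool
    n_iter: int


def _posterior_dosage(lik: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """E[g | GL, Binom(2, pi) prior] per site x individual."""
    w0 = lik[:, :, 0] * (1.0 - pi) ** 2
    w1 = lik[:, :, 1] * 2.0 * pi * (1.0 - pi)
    w2 = lik[:, :, 2] * pi**2
    denom = np.maximum(w0 + w1 + w2, 1e-300)
    return (w1 + 2.0 * w2) / denom


def gl_pca(
    gl: GLMatrix,
    maf_min: float = 0.05,
    n_latent: int = 2,
    max_iter: int = 100,
    tol: float = 1e-5,
) -> CovarianceResult:
    """PCAngsd-style covariance and individual allele frequencies.

    Sites are pre-filtered to MAF >= maf_min using the EM frequency
    estimate.  ``n_latent`` is the rank of the individual-allele-frequency
    model (number of leading PCs used in the iteration; typically the
    number of clusters minus one).
    """
    if gl.n_individuals < 2 or gl.n_sites < 2:
        raise ValueError("PCA requires at least 2 individuals and 2 sites")
    freq, _ = estimate_site_frequencies(gl)
    maf = np.minimum(freq, 1.0 - freq)
    keep = maf >= maf_min
    if keep.sum() < 2:
        raise ValueError("fewer than 2 sites pass the MAF filter")
    sub = gl.subset(sites=np.flatnonzero(keep))
    f = freq[keep]
    lik = sub.linear()
    S, N = sub.n_sites, sub.n_individuals

    pi = np.repeat(f[:, None], N, axis=1)
    n_latent = min(n_latent, N - 1)
    converged = False
    it = 0
    dosage = _posterior_dosage(lik, pi)
    for it in range(1, max_iter + 1):
        centered = dosage - 2.0 * f[:, None]
        # truncated SVD reconstruction -> low-rank individual frequencies
        u, s, vt = np.linalg.svd(centered, full_matrices=False)
        recon = (u[:, :n_latent] * s[:n_latent]) @ vt[:n_latent]
        pi_new = np.clip((recon + 2.0 * f[:, None]) / 2.0, 1e-4, 1.0 - 1e-4)
        dosage = _posterior_dosage(lik, pi_new)
        diff = float(np.sqrt(np.mean((pi_new - pi) ** 2)))
        pi = pi_new
        if diff < tol:
            converged = True
            break

    norm = np.sqrt(2.0 * f * (1.0 - f))[:, None]
    std = (dosage - 2.0 * f[:, None]) / norm
    cov = (std.T @ std) / S
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    total = eigval.sum()
    pct = 100.0 * eigval / total if total > 0 else np.zeros_like(eigval)
    scores = eigvec * np.sqrt(np.maximum(eigval, 0.0))
    return CovarianceResult(
        cov=cov, eigenvalues=eigval, scores=scores, pct_variance=pct,
        indiv_allele_freq=dosage / 2.0, site_freq=f,
        sample_ids=list(sub.sample_ids), converged=converged, n_iter=it,
    )


def admixture_em(
    gl: GLMatrix,
    K: int,
    maf_min: float = 0.05,
    seed: int = 0,
    n_starts: int = 5,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> AdmixtureResult:
    """GL-aware admixture model maximized by EM; best of ``n_starts`` runs.

    The likelihood is invariant under permuting cluster labels, so Q/F
    columns are reported in the arbitrary order of the best run.
    """
    if not 1 <= K <= gl.n_individuals:
        raise ValueError(
            f"K must be between 1 and the number of individuals "
            f"({gl.n_individuals}), got {K}"
        )
    freq, _ = estimate_site_frequencies(gl)
    maf = np.minimum(freq, 1.0 - freq)
    keep = maf >= maf_min
    sub = gl.subset(sites=np.flatnonzero(keep))
    lik = sub.linear()
    S, N = sub.n_sites, sub.n_individuals
    f = freq[keep]

    best = None
    seeds = np.random.SeedSequence(seed).spawn(n_starts)
    for ss in seeds:
        rng = np.random.default_rng(ss)
        Q = rng.dirichlet(np.ones(K), size=N)
        F = np.clip(
            f[:, None] + rng.uniform(-0.1, 0.1, size=(S, K)), 1e-4, 1 - 1e-4
        )
        ll_prev = -np.inf
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            pi = np.clip(F @ Q.T, 1e-9, 1.0 - 1e-9)  # (S, N)
            w0 = lik[:, :, 0] * (1.0 - pi) ** 2
            w1 = lik[:, :, 1] * 2.0 * pi * (1.0 - pi)
            w2 = lik[:, :, 2] * pi**2
            denom = np.maximum(w0 + w1 + w2, 1e-300)
            ll = float(np.log(denom).sum())
            e_minor = (w1 + 2.0 * w2) / denom  # expected minor copies
            e_major = 2.0 - e_minor
            # attribute allele copies to source clusters
            for_k_minor = np.empty((K, S, N))
            for_k_major = np.empty((K, S, N))
            for k in range(K):
                share = F[:, k][:, None] * Q[:, k][None, :] / pi
                for_k_minor[k] = e_minor * share
                share0 = (1.0 - F[:, k])[:, None] * Q[:, k][None, :] / (1.0 - pi)
                for_k_major[k] = e_major * share0
            minor_k = for_k_minor.sum(axis=2)  # (K, S)
            major_k = for_k_major.sum(axis=2)
            F = np.clip(
                (minor_k / np.maximum(minor_k + major_k, 1e-300)).T,
                1e-4, 1.0 - 1e-4,
            )
            q_num = (for_k_minor + for_k_major).sum(axis=1)  # (K, N)
            Q = (q_num / (2.0 * S)).T
            Q = np.clip(Q, 1e-8, 1.0)
            Q /= Q.sum(axis=1, keepdims=True)
            if abs(ll - ll_prev) < tol * max(1.0, abs(ll)):
                converged = True
                break
            ll_prev = ll
        if best is None or ll > best.loglik:
            best = AdmixtureResult(
                Q=Q, F=F, loglik=ll, K=K, sample_ids=list(sub.sample_ids),
                converged=converged, n_iter=it,
            )
    return best


def assign_clusters(adm: AdmixtureResult, q_min: float = 0.85) -> list[str]:
    """Assign each individual to its majority cluster if max q >= q_min
    (boundary inclusive), else label it 'admixed'."""
    labels = []
    for row in adm.Q:
        k = int(np.argmax(row))
        labels.append(f"cluster_{k + 1}" if row[k] >= q_min else "admixed")
    return labels
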