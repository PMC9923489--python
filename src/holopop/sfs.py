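"""Site-frequency spectra from genotype likelihoods, diversity statistics,
and Hudson/Bhatia FST.

The SFS estimator follows the realSFS approach: per site, the likelihood of
every possible population minor-allele count is computed by a dynamic
programme over individuals' genotype likelihoods (hypergeometric sampling of
alleles without replacement), and the spectrum maximizing the product over
sites is found by EM.  Spectra are estimated unfolded with respect to the
per-site minor-allele coding and folded afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .gl import GLMatrix

__all__ = [
    "FoldedSFS",
    "DiversityStats",
    "FstResult",
    "site_count_likelihoods",
    "estimate_folded_sfs",
    "joint_folded_sfs",
    "fold_sfs",
    "project_sfs",
    "diversity_from_sfs",
    "fst_from_counts",
    "fst_from_sfs2d",
    "sfs_from_genotypes",
]


def _log_binom(n: int) -> np.ndarray:
    k = np.arange(n + 1)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def fold_sfs(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fold a spectrum over the (joint) minor allele.

    Entries whose total derived count exceeds half the total sample size are
    added to their complement and zeroed; entries exactly on the hinge
    receive half of (entry + complement).  Returns (folded, mask) where mask
    marks cells that are redundant after folding (and the fixed corners).
    The total count is preserved.
    """
    data = np.asarray(data, dtype=float)
    shape = data.shape
    ns = [s - 1 for s in shape]
    total = sum(ns)
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    tot_per_entry = sum(grids)
    rev = data[tuple(slice(None, None, -1) for _ in shape)]
    folded = data + rev
    folded[tot_per_entry > total / 2] = 0.0
    hinge = tot_per_entry == total / 2
    folded[hinge] *= 0.5
    mask = tot_per_entry > total / 2
    # fixed cells carry no polymorphism information
    mask[tuple(0 for _ in shape)] = True
    mask[tuple(s - 1 for s in shape)] = True
    return folded, mask


def project_sfs(data: np.ndarray, n_to: tuple) -> np.ndarray:
    """Hypergeometric projection of an (unfolded) spectrum to smaller sample
    sizes, axis by axis."""
    out = np.asarray(data, dtype=float)
    for axis, m in enumerate(n_to):
        n = out.shape[axis] - 1
        if m > n:
            raise ValueError(f"cannot project axis {axis} from {n} up to {m}")
        if m == n:
            continue
        proj = np.zeros((n + 1, m + 1))
        lbn = _log_binom(n)
        lbm = _log_binom(m)
        lbnm = _log_binom(n - m)
        for i in range(n + 1):
            j = np.arange(max(0, i - (n - m)), min(i, m) + 1)
            logp = lbm[j] + lbnm[i - j] - lbn[i]
            proj[i, j] = np.exp(logp)
        out = np.tensordot(out, proj, axes=([axis], [0]))
        out = np.moveaxis(out, -1, axis)
    return out


@dataclass
class FoldedSFS:
    """Minor-allele-frequency spectrum, 1D or 2D.

    ``data`` is indexed by minor-allele count per population; ``mask`` marks
    folded-out and fixed cells; ``n`` holds the haploid sample sizes.
    """

    data: np.ndarray
    n: tuple
    mask: np.ndarray | None = None
    folded: bool = True
    converged: bool = True

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if np.any(self.data < -1e-9):
            raise ValueError("SFS entries must be >= 0")
        if self.mask is None:
            self.mask = np.zeros_like(self.data, dtype=bool)

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def n_sites(self) -> float:
        return float(self.data.sum())

    @property
    def segregating(self) -> float:
        """Sites that are polymorphic in the sample (unmasked, nonfixed)."""
        d = self.data.copy()
        d[tuple(0 for _ in d.shape)] = 0.0
        if not self.folded:
            d[tuple(s - 1 for s in d.shape)] = 0.0
        return float(d.sum())

    def fold(self) -> "FoldedSFS":
        if self.folded:
            return self
        folded, mask = fold_sfs(self.data)
        return FoldedSFS(folded, self.n, mask=mask, folded=True,
                         converged=self.converged)


def site_count_likelihoods(gl: GLMatrix, individuals=None) -> np.ndarray:
    """P(site data | k minor alleles among 2n) for k = 0..2n, per site.

    Computed by polynomial multiplication over individuals: each individual
    contributes GL(0) + 2 GL(1) z + GL(2) z^2 and the coefficient of z^k is
    divided by C(2n, k) (hypergeometric allele sampling).  Rows are
    normalized to sum 1 (per-site scale factors cancel in the EM).
    """
    sub = gl if individuals is None else gl.subset(individuals=individuals)
    lik = sub.linear()  # (S, N, 3)
    S, N, _ = lik.shape
    n2 = 2 * N
    poly = np.zeros((S, n2 + 1))
    poly[:, 0] = 1.0
    cur = 0
    for i in range(N):
        new = np.zeros((S, n2 + 1))
        new[:, : cur + 1] += poly[:, : cur + 1] * lik[:, i, 0][:, None]
        new[:, 1 : cur + 2] += 2.0 * poly[:, : cur + 1] * lik[:, i, 1][:, None]
        new[:, 2 : cur + 3] += poly[:, : cur + 1] * lik[:, i, 2][:, None]
        poly = new
        cur += 2
        norm = poly[:, : cur + 1].sum(axis=1, keepdims=True)
        poly[:, : cur + 1] /= np.maximum(norm, 1e-300)
    lb = _log_binom(n2)
    poly /= np.exp(lb)[None, :]
    poly /= np.maximum(poly.sum(axis=1, keepdims=True), 1e-300)
    return poly


def _em_sfs(site_lik: np.ndarray, max_iter: int, tol: float):
    """EM for the spectrum maximizing sum_s log sum_k eta_k L_s(k)."""
    S, K = site_lik.shape
    eta = np.full(K, 1.0 / K)
    last = -np.inf
    converged = False
    for _ in range(max_iter):
        w = site_lik * eta[None, :]
        denom = w.sum(axis=1, keepdims=True)
        ll = float(np.log(np.maximum(denom, 1e-300)).sum())
        post = w / np.maximum(denom, 1e-300)
        eta = post.sum(axis=0)
        eta /= eta.sum()
        if abs(ll - last) < tol * max(1.0, abs(ll)):
            converged = True
            break
        last = ll
    return eta * S, converged


def estimate_folded_sfs(
    gl: GLMatrix,
    individuals=None,
    fold: bool = True,
    max_iter: int = 500,
    tol: float = 1e-10,
) -> FoldedSFS:
    """ML (folded) 1D SFS from genotype likelihoods by EM."""
    site_lik = site_count_likelihoods(gl, individuals)
    eta, converged = _em_sfs(site_lik, max_iter, tol)
    n = site_lik.shape[1] - 1
    out = FoldedSFS(eta, (n,), folded=False, converged=converged)
    return out.fold() if fold else out


def joint_folded_sfs(
    gl: GLMatrix,
    pop1,
    pop2,
    fold: bool = True,
    project_to: tuple | None = None,
    max_iter: int = 300,
    tol: float = 1e-9,
    chunk: int = 4096,
) -> FoldedSFS:
    """ML (folded) joint 2D SFS for two population subsets by EM.

    ``project_to`` optionally projects the estimated unfolded spectrum down
    to smaller haploid sizes (hypergeometric), the standard way to balance
    unequal samples before model fitting.
    """
    l1 = site_count_likelihoods(gl, pop1)
    l2 = site_count_likelihoods(gl, pop2)
    S = l1.shape[0]
    k1, k2 = l1.shape[1], l2.shape[1]
    eta = np.full((k1, k2), 1.0 / (k1 * k2))
    last = -np.inf
    converged = False
    for _ in range(max_iter):
        acc = np.zeros((k1, k2))
        ll = 0.0
        for s0 in range(0, S, chunk):
            a = l1[s0 : s0 + chunk]
            b = l2[s0 : s0 + chunk]
            joint = np.einsum("si,sj->sij", a, b) * eta[None, :, :]
            denom = joint.sum(axis=(1, 2), keepdims=True)
            ll += float(np.log(np.maximum(denom[:, 0, 0], 1e-300)).sum())
            acc += (joint / np.maximum(denom, 1e-300)).sum(axis=0)
        eta = acc / acc.sum()
        if abs(ll - last) < tol * max(1.0, abs(ll)):
            converged = True
            break
        last = ll
    data = eta * S
    if project_to is not None:
        data = project_sfs(data, project_to)
        n = project_to
    else:
        n = (k1 - 1, k2 - 1)
    out = FoldedSFS(data, n, folded=False, converged=converged)
    return out.fold() if fold else out


@dataclass
class DiversityStats:
    pi: float
    theta_w: float
    segregating: float
    n_sites: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def diversity_from_sfs(sfs: FoldedSFS, n_sites: float | None = None) -> DiversityStats:
    """Per-site nucleotide diversity pi and Watterson's theta from a 1D SFS.

    pi = sum_k k (2n - k) eta_k / (C(2n, 2) L); theta_W = S / (a_n L) with
    a_n = sum_{i=1}^{2n-1} 1/i.  Both weights are symmetric under
    k -> 2n - k, so folded spectra give the same answer as unfolded.
    """
    if sfs.ndim != 1:
        raise ValueError("diversity_from_sfs expects a 1D spectrum")
    L = float(sfs.n_sites if n_sites is None else n_sites)
    if L <= 0:
        raise ValueError("number of sites L must be positive")
    n2 = sfs.n[0]
    k = np.arange(n2 + 1)
    eta = sfs.data
    seg = sfs.segregating
    pi = float((k * (n2 - k) * eta).sum() / (n2 * (n2 - 1) / 2.0) / L)
    a_n = (1.0 / np.arange(1, n2)).sum()
    theta_w = float(seg / (a_n * L))
    return DiversityStats(pi=pi, theta_w=theta_w, segregating=seg, n_sites=L)


@dataclass
class FstResult:
    """Hudson/Bhatia FST: per-site numerator/denominator, genome-wide
    weighted ratio of averages, and sliding-window values."""

    fst_weighted: float
    per_site: pd.DataFrame
    windows: pd.DataFrame
    window: int
    step: int


def _bhatia_site_terms(p1, n1, p2, n2):
    num = (
        (p1 - p2) ** 2
        - p1 * (1 - p1) / (n1 - 1)
        - p2 * (1 - p2) / (n2 - 1)
    )
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def fst_from_counts(
    ac1: np.ndarray,
    n1: int,
    ac2: np.ndarray,
    n2: int,
    positions: np.ndarray | None = None,
    window: int = 50_000,
    step: int = 10_000,
    min_sites_per_window: int = 10,
) -> FstResult:
    """Weighted Hudson/Bhatia FST from per-site allele counts.

    ``ac1``/``ac2`` are counts of one allele (consistently coded across
    populations) out of ``n1``/``n2`` sampled haploids.  The genome-wide
    value is the ratio of summed numerators to summed denominators; windows
    are 0-based half-open [start, start + window) every ``step`` bp and
    reported only with >= ``min_sites_per_window`` variable sites.
    """
    if window < step:
        raise ValueError("window must be >= step")
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 haploid samples per population")
    p1 = np.asarray(ac1, dtype=float) / n1
    p2 = np.asarray(ac2, dtype=float) / n2
    num, den = _bhatia_site_terms(p1, n1, p2, n2)
    variable = den > 0
    fst_w = float(num[variable].sum() / den[variable].sum()) if variable.any() else np.nan

    if positions is None:
        positions = np.arange(p1.size)
    positions = np.asarray(positions)
    per_site = pd.DataFrame(
        {"position": positions, "numerator": num, "denominator": den}
    )

    rows = []
    if variable.any():
        pos_v = positions[variable]
        num_v, den_v = num[variable], den[variable]
        max_pos = int(pos_v.max())
        start = 0
        while start <= max_pos:
            in_w = (pos_v >= start) & (pos_v < start + window)
            nsites = int(in_w.sum())
            if nsites >= min_sites_per_window:
                rows.append(
                    (
                        start,
                        start + window,
                        float(num_v[in_w].sum() / den_v[in_w].sum()),
                        nsites,
                    )
                )
            start += step
    windows = pd.DataFrame(rows, columns=["start", "end", "fst", "n_sites"])
    return FstResult(
        fst_weighted=fst_w, per_site=per_site, windows=windows,
        window=window, step=step,
    )


def fst_from_sfs2d(sfs: FoldedSFS) -> float:
    """Weighted Hudson/Bhatia FST from a (possibly folded) joint SFS.

    Both the numerator and denominator are invariant under jointly swapping
    allele labels in the two populations, so folding does not change the
    ratio.
    """
    if sfs.ndim != 2:
        raise ValueError("fst_from_sfs2d expects a 2D spectrum")
    n1, n2 = sfs.n
    i, j = np.meshgrid(np.arange(n1 + 1), np.arange(n2 + 1), indexing="ij")
    p1, p2 = i / n1, j / n2
    num, den = _bhatia_site_terms(p1, n1, p2, n2)
    w = sfs.data
    ok = den > 0
    return float((w * num)[ok].sum() / (w * den)[ok].sum())


def sfs_from_genotypes(
    genotypes: np.ndarray, fold: bool = True
) -> FoldedSFS:
    """Direct allele-count histogram of a genotype matrix (error-free
    oracle for the EM estimator)."""
    S, N = genotypes.shape
    counts = genotypes.sum(axis=1)
    eta = np.bincount(counts, minlength=2 * N + 1).astype(float)
    out = FoldedSFS(eta, (2 * N,), folded=False)
    return out.fold() if fold else out
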