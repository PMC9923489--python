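"""Reproducible simulation experiments over the pipeline.

Each function runs one self-contained experiment on synthetic data at the
study's default conditions (sizes are parameters so the analysis scripts
and the test suite can scale them) and returns plain dictionaries of
numbers.  These are the computations behind the numbered analysis scripts
and the acceptance checks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import gl as glmod
from . import sfs as sfsmod
from . import structure as structmod
from . import symbiont as symmod
from . import synth
from .demography import (
    DemographicModelSpec,
    EnginePrecision,
    OptimizerConfig,
    expected_sfs,
    fit_model,
)
from .sfs import FoldedSFS, fold_sfs
from .spatial import mantel_test

__all__ = [
    "sfs_em_fidelity",
    "fst_window_consistency",
    "demographic_recovery",
    "model_nesting_error",
    "clone_detection_experiment",
    "mantel_calibration",
    "rda_null_calibration",
    "rda_power_experiment",
    "alpha_model_recovery",
    "light_optimizer",
]


def _seed_stream(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def sfs_em_fidelity(
    seed: int = 1,
    n_diploid: int = 10,
    n_sites: int = 50_000,
    depth: float = 20.0,
    error_rate: float = 0.01,
) -> dict:
    """Estimate the folded SFS from simulated high-depth GLs and measure
    total-variation distance from the true allele-count histogram."""
    cfg = synth.HostSimConfig(
        n_pops=1, sample_sizes=(n_diploid,), nu=(1.0,), T_div=0.0,
        theta=n_sites / 3.0, seq_length=5e7, seed=seed,
    )
    geno, _, pos, _ = synth.simulate_host_genotypes(cfg)
    if geno.shape[0] > n_sites:
        geno = geno[:n_sites]
        pos = pos[:n_sites]
    rc = synth.ReadSimConfig(mean_depth=depth, error_rate=error_rate,
                             seed=seed + 1)
    _, glm, _ = synth.simulate_reads_and_gls(geno, rc, pos)
    est = sfsmod.estimate_folded_sfs(glm)
    true = sfsmod.sfs_from_genotypes(geno)
    a = est.data / est.data.sum()
    b = true.data / true.data.sum()
    return dict(
        tv_distance=float(0.5 * np.abs(a - b).sum()),
        n_sites=int(geno.shape[0]),
        converged=bool(est.converged),
    )


def fst_window_consistency(seed: int = 1, n_sites: int = 100) -> dict:
    """Hudson/Bhatia FST on a random toy count table: direct per-site hand
    computation and windowed-aggregation consistency."""
    rng = np.random.default_rng(seed)
    n1, n2 = 20, 16
    ac1 = rng.integers(0, n1 + 1, n_sites)
    ac2 = rng.integers(0, n2 + 1, n_sites)
    positions = np.sort(rng.choice(200_000, n_sites, replace=False))
    res = sfsmod.fst_from_counts(ac1, n1, ac2, n2, positions=positions,
                                 window=50_000, step=10_000,
                                 min_sites_per_window=1)
    # independent hand computation
    p1, p2 = ac1 / n1, ac2 / n2
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    ok = den > 0
    direct = num[ok].sum() / den[ok].sum()
    # windows tiling with step == window partition the genome; their summed
    # numerators/denominators must reproduce the genome-wide ratio
    tiled = sfsmod.fst_from_counts(ac1, n1, ac2, n2, positions=positions,
                                   window=10_000, step=10_000,
                                   min_sites_per_window=1)
    per = tiled.per_site
    agg_num = agg_den = 0.0
    for _, row in tiled.windows.iterrows():
        sel = (per["position"] >= row["start"]) & (per["position"] < row["end"])
        agg_num += per.loc[sel, "numerator"].sum()
        agg_den += per.loc[sel, "denominator"].sum()
    return dict(
        fst=float(res.fst_weighted),
        abs_error_vs_direct=float(abs(res.fst_weighted - direct)),
        abs_error_windows_vs_genome=float(abs(agg_num / agg_den - direct)),
        n=n_sites,
    )


def light_optimizer(seed: int = 0, model: str = "im_asym") -> OptimizerConfig:
    """Reduced-size optimization schedule used by the analysis scripts:
    two rounds of perturbed restarts with a coarser engine, then a final
    polish at the default engine precision."""
    coarse = EnginePrecision(pts=40, n_ref=6, y_min=1e-5, dt0=0.0125)
    fine = EnginePrecision(pts=55, n_ref=10, y_min=1e-7, dt0=0.01)
    reps = 3 if model in ("im_asym", "sc") else 2
    return OptimizerConfig(
        rounds=((reps, 2, 90), (1, 0.5, 100)),
        seed=seed, engine=coarse, final_engine=fine,
    )


def demographic_recovery(
    seed: int = 1,
    n_seeds: int = 10,
    n_diploid_per_pop: int = 8,
    target_snps: float = 1e5,
    true_params: dict | None = None,
) -> dict:
    """Parameter-recovery experiment for the asymmetric-migration model.

    For each seed, simulates a two-population history at the true
    parameters, builds the folded joint SFS from the true genotypes, fits
    both the asymmetric-migration and strict-isolation models, and reports
    relative errors of T and nu plus the log-likelihood ordering.
    """
    truth = true_params or dict(nu1=1.0, nu2=0.3, T=0.8, m12=2.0, m21=0.5)
    n_hap = 2 * n_diploid_per_pop
    rows = []
    for i, s in enumerate(_seed_stream(seed, n_seeds)):
        cfg = synth.HostSimConfig(
            n_pops=2, sample_sizes=(n_diploid_per_pop, n_diploid_per_pop),
            nu=(truth["nu1"], truth["nu2"]), T_div=truth["T"],
            M=np.array([[0.0, truth["m12"]], [truth["m21"], 0.0]]),
            theta=target_snps / 4.5, seq_length=5e7, n_chunks=2000, seed=s,
        )
        geno, joint, pos, pops = synth.simulate_host_genotypes(cfg)
        folded, mask = fold_sfs(joint)
        obs = FoldedSFS(folded, (n_hap, n_hap), mask=mask, folded=True)
        # nested ladder: the cheap strict-isolation fit seeds the
        # migration-model starts
        fit_div = fit_model(
            obs, DemographicModelSpec("div"),
            config=light_optimizer(seed=s + 1, model="div"),
        )
        im_start = dict(
            nu1=fit_div.params["nu1"], nu2=fit_div.params["nu2"],
            T=min(fit_div.params["T"] * 1.5, 5.0), m12=0.5, m21=0.5,
        )
        fit_im = fit_model(
            obs, DemographicModelSpec("im_asym"),
            config=light_optimizer(seed=s, model="im_asym"),
            start=im_start,
        )
        rows.append(
            dict(
                seed=s,
                n_snps=float(joint.sum() - joint[0, 0] - joint[-1, -1]),
                T_hat=fit_im.params["T"], nu1_hat=fit_im.params["nu1"],
                nu2_hat=fit_im.params["nu2"],
                m12_hat=fit_im.params["m12"], m21_hat=fit_im.params["m21"],
                ll_im=fit_im.loglik, ll_div=fit_div.loglik,
            )
        )
    tab = pd.DataFrame(rows)
    return dict(
        table=tab,
        median_T_rel_err=float(np.median(tab["T_hat"]) / truth["T"] - 1.0),
        median_nu1_rel_err=float(np.median(tab["nu1_hat"]) / truth["nu1"] - 1.0),
        median_nu2_rel_err=float(np.median(tab["nu2_hat"]) / truth["nu2"] - 1.0),
        im_beats_div=int((tab["ll_im"] > tab["ll_div"]).sum()),
        n_seeds=n_seeds,
    )


def model_nesting_error(n: int = 12) -> dict:
    """Entrywise relative agreement of nested model limits: migration -> 0
    reduces isolation-with-migration to strict isolation, and contact over
    the whole history reduces secondary contact to continuous migration."""
    base = dict(nu1=1.0, nu2=0.5, T=0.7)
    im0 = expected_sfs(
        DemographicModelSpec("im_asym"),
        (n, n), params={**base, "m12": 0.0, "m21": 0.0},
    )
    div = expected_sfs(DemographicModelSpec("div"), (n, n), params=base)
    sc_full = expected_sfs(
        DemographicModelSpec("sc"), (n, n),
        params={**base, "m12": 1.5, "m21": 0.5, "f_sc": 1.0},
    )
    im = expected_sfs(
        DemographicModelSpec("im_asym"), (n, n),
        params={**base, "m12": 1.5, "m21": 0.5},
    )

    def max_rel(a: FoldedSFS, b: FoldedSFS) -> float:
        sel = ~a.mask & (b.data > 1e-12)
        return float(np.max(np.abs(a.data[sel] - b.data[sel]) / b.data[sel]))

    return dict(
        im_vs_div_max_rel=max_rel(im0, div),
        sc_vs_im_max_rel=max_rel(sc_full, im),
        n=n,
    )


def clone_detection_experiment(
    seed: int = 1,
    n_seeds: int = 20,
    n_diploid_per_pop: int = 10,
    n_clone_groups: int = 3,
    n_tech_replicates: int = 4,
    mean_depth: float = 5.0,
) -> dict:
    """Planted-clone recovery: across seeds, count clone pairs falling
    below the replicate-derived threshold and unrelated pairs falsely
    below it."""
    results = []
    for s in _seed_stream(seed, n_seeds):
        # the emulated SNP panel is genome-wide, so its loci are effectively
        # unlinked: simulate as independent blocks (a single short
        # chromosome would give individuals artificially variable
        # heterozygosity through long shared tracts).  The panel must also
        # be large: the replicate-vs-clone distance margin is the extra
        # library error (~0.9% mismatch), so per-pair scatter — driven by
        # between-individual heterozygosity spread ~ sqrt(het/L) and read
        # sampling ~ sqrt(d/L) — needs L in the tens of thousands for a
        # multi-sigma classification margin.
        cfg = synth.HostSimConfig(
            n_pops=3, sample_sizes=(n_diploid_per_pop,) * 3, T_div=1.0,
            theta=2500.0, seq_length=4e6, n_chunks=2000, seed=s,
        )
        geno, _, pos, _ = synth.simulate_host_genotypes(cfg)
        rc = synth.ReadSimConfig(
            mean_depth=mean_depth, error_rate=0.01,
            n_clone_groups=n_clone_groups,
            n_tech_replicates=n_tech_replicates, seed=s + 1,
        )
        _, glm, truth = synth.simulate_reads_and_gls(geno, rc, pos)
        dists = glmod.ibs_distance_matrix(glm, seed=s + 2)
        reps = [(a, b) for a, b, r in truth.itertuples(index=False)
                if r == "replicate"]
        clones = [(a, b) for a, b, r in truth.itertuples(index=False)
                  if r == "clone"]
        thr = glmod.clone_threshold(dists, reps)
        clone_below = sum(dists.pair(a, b) < thr for a, b in clones)
        related = set()
        for a, b, _ in truth.itertuples(index=False):
            related |= {(a, b), (b, a)}
        ids = dists.sample_ids
        false_below = 0
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                a, b = ids[i], ids[j]
                if (a, b) in related or a.split("_")[0] == b.split("_")[0]:
                    continue
                if dists.dist[i, j] < thr:
                    false_below += 1
        results.append(
            dict(seed=s, threshold=thr, clone_pairs=len(clones),
                 clone_below=clone_below, false_below=false_below)
        )
    tab = pd.DataFrame(results)
    return dict(
        table=tab,
        all_clones_recovered=bool(
            (tab["clone_below"] == tab["clone_pairs"]).all()
        ),
        total_false_positives=int(tab["false_below"].sum()),
        n_seeds=n_seeds,
    )


def mantel_calibration(
    seed: int = 1, n_null: int = 200, n_reefs: int = 15, n_perm: int = 199
) -> dict:
    """Null rejection rate of the Mantel test on independent random
    distance matrices."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_null):
        a = rng.random((n_reefs, n_reefs))
        b = rng.random((n_reefs, n_reefs))
        a = (a + a.T) / 2
        b = (b + b.T) / 2
        np.fill_diagonal(a, 0)
        np.fill_diagonal(b, 0)
        res = mantel_test(a, b, n_perm=n_perm,
                          seed=int(rng.integers(2**31 - 1)))
        rejections += res.p_value <= 0.05
    return dict(rejection_rate=rejections / n_null, n_null=n_null)


def _symbiont_dataset(seed: int, n_colonies: int, null: bool, **overrides):
    meta = synth.make_study_metadata(n_colonies, seed=seed)
    kwargs = dict(n_colonies=n_colonies, seed=seed + 1)
    if null:
        kwargs.update(
            latitude_effect=0.0,
            shelf_richness_effects={k: 0.0 for k in synth.SHELF_LEVELS},
            latitude_comp_effect=0.0,
            shelf_comp_effect=0.0,
        )
    kwargs.update(overrides)
    cfg = synth.SymbiontSimConfig(**kwargs)
    long_counts = synth.simulate_symbiont_pools(cfg, meta)
    tensor = symmod.plastid_allele_counts(long_counts)
    return cfg, meta, tensor


def rda_null_calibration(
    seed: int = 1, n_null: int = 200, n_colonies: int = 40,
    n_loci: int = 8, n_perm: int = 199,
) -> dict:
    """Type-I error of the symbiont RDA term tests when the generator has
    no latitude or shelf structure."""
    lat_rej = shelf_rej = 0
    for s in _seed_stream(seed, n_null):
        _, meta, tensor = _symbiont_dataset(
            s, n_colonies, null=True, n_loci=n_loci
        )
        res = symmod.symbiont_rda(tensor, meta, n_perm=n_perm, seed=s,
                                  test_axes=False)
        terms = res.terms.set_index("term")
        lat_rej += terms.loc["latitude", "p_value"] <= 0.05
        shelf_rej += terms.loc["shelf", "p_value"] <= 0.05
    return dict(
        latitude_rejection_rate=lat_rej / n_null,
        shelf_rejection_rate=shelf_rej / n_null,
        n_null=n_null,
    )


def rda_power_experiment(
    seed: int = 1, n_runs: int = 100, n_colonies: int = 100,
    n_perm: int = 199, alpha: float = 0.01,
) -> dict:
    """Power of the symbiont RDA at the generator's default effect sizes:
    rejection of the latitude term and the rank of the shelf term among
    the three constraint terms."""
    lat_sig = shelf_first = 0
    for s in _seed_stream(seed, n_runs):
        _, meta, tensor = _symbiont_dataset(s, n_colonies, null=False)
        res = symmod.symbiont_rda(tensor, meta, n_perm=n_perm, seed=s,
                                  test_axes=False)
        terms = res.terms.set_index("term")
        lat_sig += terms.loc["latitude", "p_value"] <= alpha
        shelf_first += (
            terms["variance_fraction"].idxmax() == "shelf"
        )
    return dict(
        latitude_power=lat_sig / n_runs,
        shelf_ranks_first_rate=shelf_first / n_runs,
        n_runs=n_runs,
        alpha=alpha,
    )


def marginal_latitude_slope(
    cfg: "synth.SymbiontSimConfig", n_mc: int = 200_000, seed: int = 0
) -> float:
    """Exact marginal latitude slope of expected allele richness.

    The generator draws K = clip(round(x), 1, A) with x Gaussian around a
    linear predictor; rounding and clipping attenuate the planted
    coefficient.  With x ~ N(mu, s), dE[K]/dmu = sum_{k=2}^{A}
    phi((k - 0.5 - mu)/s)/s, so the marginal slope is latitude_effect times
    that factor averaged over the generator's distribution of pool sizes A
    and intercepts mu (Monte-Carlo average; deterministic given the seed).
    """
    from scipy.stats import norm

    rng = np.random.default_rng(seed)
    A = rng.integers(cfg.alleles_min, cfg.alleles_max + 1, n_mc)
    shelf_eff = rng.choice(list(cfg.shelf_richness_effects.values()), n_mc)
    lat_z = rng.normal(0.0, 1.0, n_mc)
    mu = (
        cfg.base_richness
        + cfg.latitude_effect * lat_z
        + shelf_eff
        + rng.normal(0.0, cfg.locus_sd, n_mc)
        + rng.normal(0.0, cfg.colony_sd, n_mc)
    )
    s = cfg.richness_noise_sd
    kmax = int(cfg.alleles_max)
    k = np.arange(2, kmax + 1)
    dens = norm.pdf((k[None, :] - 0.5 - mu[:, None]) / s) / s
    dens[k[None, :] > A[:, None]] = 0.0
    return float(cfg.latitude_effect * dens.sum(axis=1).mean())


def alpha_model_recovery(
    seed: int = 1, n_runs: int = 100, n_colonies: int = 80
) -> dict:
    """Coverage of the mixed model's latitude CI for the planted slope.

    The recovery target is the generator's marginal slope on the
    allele-count scale (the planted coefficient corrected exactly for
    rounding/clipping; see :func:`marginal_latitude_slope`).
    """
    cfg0 = synth.SymbiontSimConfig()
    true_beta = marginal_latitude_slope(cfg0)
    covered = 0
    betas = []
    fails = 0
    for s in _seed_stream(seed, n_runs):
        cfg, meta, tensor = _symbiont_dataset(s, n_colonies, null=False)
        try:
            res = symmod.alpha_diversity_model(tensor, meta)
        except Exception:
            fails += 1
            continue
        fe = res.fixed_effects
        row = fe.loc[[i for i in fe.index if "latitude" in i][0]]
        lo = row["estimate"] - 1.96 * row["se"]
        hi = row["estimate"] + 1.96 * row["se"]
        covered += lo <= true_beta <= hi
        betas.append(row["estimate"])
    n_ok = n_runs - fails
    return dict(
        coverage=covered / max(n_ok, 1),
        mean_beta=float(np.mean(betas)) if betas else np.nan,
        true_beta=true_beta,
        planted_coefficient=cfg0.latitude_effect,
        n_runs=n_ok,
        n_failures=fails,
    )
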