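"""Cluster diversity, pairwise FST, and demographic model comparison.

Per host cluster: folded SFS by EM from the genotype likelihoods, pi and
Watterson's theta.  Per cluster pair: weighted Hudson/Bhatia FST genome-wide
and in 50-kb windows (10-kb step).  For the most diverged pair the four
two-population histories (strict isolation, symmetric/asymmetric migration,
secondary contact) are fit to the folded joint SFS, ranked by composite
likelihood, and the best model's parameters are converted to physical units
with a block bootstrap.  Writes under results/demography/.
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from holopop import io as hio
from holopop import sfs as sfsmod
from holopop.demography import (
    DemographicModelSpec, UnitConversionConfig, bootstrap_ci,
    compare_models, convert_units, fit_model,
)
from holopop.experiments import light_optimizer
from holopop.sfs import FoldedSFS, fold_sfs

STUDY = Path("results/study")
OUT = Path("results/demography")
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    geno = np.load(STUDY / "genotypes.npy")
    positions = np.load(STUDY / "positions.npy")
    pops = np.load(STUDY / "pops.npy")
    glm = hio.read_beagle_gl(STUDY / "host.beagle")
    glm.depth = np.load(STUDY / "depth.npy")
    glm.minor_count = np.load(STUDY / "minor_count.npy")
    # original (non-clone, non-replicate) columns only
    orig = [i for i, s in enumerate(glm.sample_ids) if "_" not in s]
    n_pops = int(pops.max()) + 1

    # --- per-cluster diversity from GL-based SFS ---
    rows = []
    for p in range(n_pops):
        members = [i for i in orig if pops[int(glm.sample_ids[i][3:])] == p]
        est = sfsmod.estimate_folded_sfs(glm, individuals=members)
        hio.write_sfs_text(est, OUT / f"sfs_cluster{p}.txt")
        d = sfsmod.diversity_from_sfs(est)
        rows.append(dict(cluster=p, pi=d.pi, theta_w=d.theta_w,
                         segregating=d.segregating))
        print(f"cluster {p}: pi={d.pi:.4f} thetaW={d.theta_w:.4f} "
              f"(per variable site)")
    pd.DataFrame(rows).to_csv(OUT / "diversity.tsv", sep="\t", index=False)

    # --- pairwise FST from genotype allele counts ---
    fst_rows = []
    for a in range(n_pops):
        for b in range(a + 1, n_pops):
            ia = np.flatnonzero(pops == a)
            ib = np.flatnonzero(pops == b)
            res = sfsmod.fst_from_counts(
                geno[:, ia].sum(1), 2 * ia.size,
                geno[:, ib].sum(1), 2 * ib.size,
                positions=positions,
            )
            res.windows.to_csv(OUT / f"fst_windows_{a}{b}.tsv", sep="\t",
                               index=False)
            fst_rows.append(dict(pair=f"{a}-{b}", fst=res.fst_weighted,
                                 n_windows=len(res.windows)))
            print(f"FST cluster {a} vs {b}: {res.fst_weighted:.3f}")
    pd.DataFrame(fst_rows).to_csv(OUT / "fst.tsv", sep="\t", index=False)

    # --- demographic models on the most diverged pair (0 vs 2) ---
    a, b = 0, n_pops - 1
    ia = np.flatnonzero(pops == a)
    ib = np.flatnonzero(pops == b)
    joint = np.zeros((2 * ia.size + 1, 2 * ib.size + 1))
    np.add.at(joint, (geno[:, ia].sum(1), geno[:, ib].sum(1)), 1.0)
    folded, mask = fold_sfs(joint)
    obs = FoldedSFS(folded, (2 * ia.size, 2 * ib.size), mask=mask)

    fits = {}
    for model in ("div", "im_sym", "im_asym", "sc"):
        fits[model] = fit_model(
            obs, DemographicModelSpec(model),
            config=light_optimizer(seed=SEED, model=model),
        )
        print(f"{model}: logL {fits[model].loglik:.1f} "
              f"params {{{', '.join(f'{k}={v:.3g}' for k, v in fits[model].params.items())}}}")
    ranking = compare_models(list(fits.values()))
    ranking.to_csv(OUT / "model_ranking.tsv", sep="\t", index=False)

    best = fits[ranking.loc[0, "model"]]
    conv_cfg = UnitConversionConfig(L=float(joint.sum()))
    converted = convert_units(best, conv_cfg)
    print("converted:", {k: round(v, 1) for k, v in converted.items()})

    site_table = pd.DataFrame(
        dict(position=positions, count1=geno[:, ia].sum(1),
             count2=geno[:, ib].sum(1))
    )
    # fold the joint counts per site onto the joint minor allele
    flip = site_table["count1"] + site_table["count2"] > ia.size + ib.size
    site_table.loc[flip, "count1"] = 2 * ia.size - site_table.loc[flip, "count1"]
    site_table.loc[flip, "count2"] = 2 * ib.size - site_table.loc[flip, "count2"]
    from holopop.demography import EnginePrecision, OptimizerConfig

    boot_cfg = OptimizerConfig(
        rounds=((1, 0.5, 60),), seed=SEED,
        engine=EnginePrecision(pts=40, n_ref=6, y_min=1e-5, dt0=0.0125),
    )
    boot = bootstrap_ci(
        site_table, best.spec, (2 * ia.size, 2 * ib.size), conv_cfg,
        n_boot=20, seed=SEED, start=best.params, config=boot_cfg,
    )
    out = dict(
        best_model=best.spec.model, params=best.params, converted=converted,
        bootstrap_quantiles=boot["quantiles"],
        bootstrap_n_success=boot["n_success"],
    )
    (OUT / "demography.json").write_text(json.dumps(out, indent=2, default=float))
    print(f"bootstrap: {boot['n_success']} successful refits")


if __name__ == "__main__":
    main()
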