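"""Generate the synthetic study: three diverged host clusters with clones
and technical replicates at ~5x coverage, plus pooled symbiont plastid
counts structured by latitude and shelf position (independent of host
cluster).

Writes the Beagle-GL matrix, the clone/replicate truth table, colony
metadata and the symbiont allele-count table under results/study/.
"""

import sys
from pathlib import Path

import numpy as np

from holopop import io as hio
from holopop import synth

OUT = Path("results/study")
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    host_cfg = synth.HostSimConfig(
        n_pops=3, sample_sizes=(14, 14, 14), nu=(1.0, 1.0, 0.6),
        T_div=1.0, M=0.5 * (1 - np.eye(3)), theta=2500.0,
        seq_length=5e6, n_chunks=200, seed=SEED,
    )
    geno, true_sfs, positions, pops = synth.simulate_host_genotypes(host_cfg)
    print(f"simulated {geno.shape[0]} SNPs for {geno.shape[1]} colonies")

    read_cfg = synth.ReadSimConfig(
        mean_depth=5.0, error_rate=0.01, n_clone_groups=3,
        n_tech_replicates=4, seed=SEED + 1,
    )
    pileup, glm, truth = synth.simulate_reads_and_gls(geno, read_cfg, positions)
    hio.write_beagle_gl(glm, OUT / "host.beagle")
    truth.to_csv(OUT / "clone_truth.tsv", sep="\t", index=False)
    np.save(OUT / "genotypes.npy", geno)
    np.save(OUT / "positions.npy", positions)
    np.save(OUT / "pops.npy", pops)
    np.save(OUT / "depth.npy", glm.depth)
    np.save(OUT / "minor_count.npy", glm.minor_count)
    print(f"wrote GLs for {glm.n_individuals} libraries "
          f"({len(truth)} planted clone/replicate pairs)")

    meta = synth.make_study_metadata(n_colonies=120, seed=SEED + 2)
    sym_cfg = synth.SymbiontSimConfig(n_colonies=120, seed=SEED + 3)
    pools = synth.simulate_symbiont_pools(sym_cfg, meta)
    meta.to_csv(OUT / "metadata.tsv", sep="\t", index=False)
    pools.to_csv(OUT / "plastid_counts.tsv", sep="\t", index=False)
    print(f"wrote pooled plastid counts: {pools['sample'].nunique()} colonies, "
          f"{pools['locus'].nunique()} loci")


if __name__ == "__main__":
    main()
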