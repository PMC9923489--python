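"""Filter the genotype-likelihood matrix and prune clonal ramets.

Applies the discovery-stage site/individual filters (3+ reads in >= 40% of
individuals; top 65% of individuals by covered positions), derives the
clone threshold from the technical-replicate 1-IBS distances (upper 95%
confidence limit of the mean) and collapses clone groups to single
representatives.  Writes the filter report, the distance summary and the
pruned sample list under results/host/.
"""

import sys
from pathlib import Path

import pandas as pd

from holopop import gl as glmod
from holopop import io as hio

STUDY = Path("results/study")
OUT = Path("results/host")
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    import numpy as np

    glm = hio.read_beagle_gl(STUDY / "host.beagle")
    # depth and minor-allele read counts travel beside the Beagle file
    glm.depth = np.load(STUDY / "depth.npy")
    glm.minor_count = np.load(STUDY / "minor_count.npy")
    truth = pd.read_csv(STUDY / "clone_truth.tsv", sep="\t")

    # clone and replicate detection runs on the full library set: the
    # replicate pairs that anchor the threshold must all be present
    dists = glmod.ibs_distance_matrix(glm, seed=SEED)
    rep_pairs = [
        (a, b) for a, b, rel in truth.itertuples(index=False)
        if rel == "replicate"
    ]
    thr = glmod.clone_threshold(dists, rep_pairs)
    clones = glmod.prune_clones(
        dists, thr, coverage=glm.coverage_per_individual(),
        replicate_pairs=rep_pairs,
    )
    print(f"clone threshold {thr:.4f}: {len(clones.groups)} clone groups, "
          f"{len(clones.removed)} libraries removed, {len(clones.kept)} kept")

    pruned = glm.subset(
        individuals=[glm.sample_ids.index(s) for s in clones.kept]
    )
    filtered, report = glmod.filter_dataset(pruned, stage="discovery")
    report.to_frame().to_csv(OUT / "filter_report.tsv", sep="\t", index=False)
    print(f"discovery filter: {report.sites_in} -> {report.sites_out} sites, "
          f"{report.individuals_in} -> {report.individuals_out} individuals")
    pd.DataFrame(dict(sample=filtered.sample_ids)).to_csv(
        OUT / "kept_samples.tsv", sep="\t", index=False
    )
    rows = [dict(group=i, member=m)
            for i, g in enumerate(clones.groups) for m in g]
    pd.DataFrame(rows).to_csv(OUT / "clone_groups.tsv", sep="\t", index=False)
    pd.DataFrame(
        dict(pair=[f"{a}|{b}" for a, b in rep_pairs],
             dist=[dists.pair(a, b) for a, b in rep_pairs])
    ).to_csv(OUT / "replicate_distances.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
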