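"""Host spatial structure: isolation by distance and partial RDA.

Builds reef geodesic distances (Vincenty/WGS84), tests isolation by
distance with a Mantel test (1000 permutations) between reef-mean genetic
distance and geographic distance, and partitions individual allele
frequencies by latitude and shelf position with a partial RDA conditioned
on the leading genetic PCs.  Writes under results/spatial/.
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from holopop import gl as glmod
from holopop import io as hio
from holopop import structure as structmod
from holopop.spatial import (
    RDADesign, geodesic_distances, mantel_test, partial_rda,
)

STUDY = Path("results/study")
OUT = Path("results/spatial")
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    meta = pd.read_csv(STUDY / "metadata.tsv", sep="\t")
    glm = hio.read_beagle_gl(STUDY / "host.beagle")
    glm.depth = np.load(STUDY / "depth.npy")
    glm.minor_count = np.load(STUDY / "minor_count.npy")
    orig = [i for i, s in enumerate(glm.sample_ids) if "_" not in s]
    glm = glm.subset(individuals=orig)
    # attach each host library to a colony row of the metadata (synthetic
    # study: cyclic assignment keeps reefs balanced across clusters)
    meta_host = meta.iloc[[i % len(meta) for i in range(glm.n_individuals)]]

    reefs = meta.drop_duplicates("reef").sort_values("reef")
    geo = geodesic_distances(reefs[["reef", "latitude", "longitude"]])
    geo.to_frame().to_csv(OUT / "reef_distances_km.tsv", sep="\t")

    # reef-level mean genetic distance (1 - IBS) between host libraries
    dists = glmod.ibs_distance_matrix(glm, seed=SEED)
    reef_of = meta_host["reef"].to_numpy()
    labels = geo.labels
    gmat = np.zeros((len(labels), len(labels)))
    for i, ra in enumerate(labels):
        for j in range(i + 1, len(labels)):
            sel_a = np.flatnonzero(reef_of == ra)
            sel_b = np.flatnonzero(reef_of == labels[j])
            if sel_a.size and sel_b.size:
                gmat[i, j] = gmat[j, i] = np.nanmean(
                    dists.dist[np.ix_(sel_a, sel_b)]
                )
    keep = gmat.sum(0) > 0
    mant = mantel_test(gmat[np.ix_(keep, keep)],
                       geo.dist_km[np.ix_(keep, keep)],
                       n_perm=1000, seed=SEED)
    print(f"Mantel IBD: R = {mant.r:.3f}, p = {mant.p_value:.4f}")

    # partial RDA of individual allele frequencies | genetic PCs
    pca = structmod.gl_pca(glm, n_latent=2)
    Y = pca.indiv_allele_freq.T  # individuals x sites
    design = RDADesign(
        Y=Y,
        constraints=pd.DataFrame(
            dict(latitude=meta_host["latitude"].to_numpy(),
                 shelf=meta_host["shelf"].to_numpy())
        ),
        conditioning=pd.DataFrame(
            dict(PC1=pca.scores[:, 0], PC2=pca.scores[:, 1])
        ),
        references={"shelf": "inshore"},
    )
    rda = partial_rda(design, n_perm=999, seed=SEED)
    rda.terms.to_csv(OUT / "host_rda_terms.tsv", sep="\t", index=False)
    rda.axes.to_csv(OUT / "host_rda_axes.tsv", sep="\t", index=False)
    for _, row in rda.terms.iterrows():
        print(f"  {row['term']}: {100 * row['variance_fraction']:.2f}% of "
              f"variance, F = {row['F']:.2f}, p = {row['p_value']:.3f}")
    (OUT / "spatial.json").write_text(json.dumps(
        dict(mantel_r=mant.r, mantel_p=mant.p_value,
             rda_model_f=rda.model_f, rda_model_p=rda.model_p,
             constrained_fraction=rda.constrained_fraction),
        indent=2,
    ))


if __name__ == "__main__":
    main()
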