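"""Host population structure: genotype-likelihood PCA and admixture.

Runs the PCAngsd-style covariance/individual-allele-frequency estimation
and the GL-aware admixture EM for K = 2..4 on the filtered, clone-pruned
matrix, then assigns individuals to clusters at q >= 0.85.  Writes PC
scores, Q matrices per K and the assignment table under results/host/.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from holopop import gl as glmod
from holopop import io as hio
from holopop import structure as structmod

STUDY = Path("results/study")
OUT = Path("results/host")
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    glm = hio.read_beagle_gl(STUDY / "host.beagle")
    glm.depth = np.load(STUDY / "depth.npy")
    glm.minor_count = np.load(STUDY / "minor_count.npy")
    kept = pd.read_csv(OUT / "kept_samples.tsv", sep="\t")["sample"].tolist()
    glm, _ = glmod.filter_dataset(glm, stage="discovery")
    glm = glm.subset(
        individuals=[glm.sample_ids.index(s) for s in kept
                     if s in glm.sample_ids]
    )

    pca = structmod.gl_pca(glm, n_latent=2)
    scores = pd.DataFrame(
        pca.scores[:, :4], columns=[f"PC{i+1}" for i in range(4)]
    )
    scores.insert(0, "sample", pca.sample_ids)
    scores.to_csv(OUT / "pc_scores.tsv", sep="\t", index=False)
    print("PCA: first four axes explain "
          + ", ".join(f"{v:.1f}%" for v in pca.pct_variance[:4]))

    rows = []
    for K in (2, 3, 4):
        adm = structmod.admixture_em(glm, K=K, seed=SEED, n_starts=3)
        labels = structmod.assign_clusters(adm, q_min=0.85)
        q = pd.DataFrame(adm.Q, columns=[f"q{k+1}" for k in range(K)])
        q.insert(0, "sample", adm.sample_ids)
        q["label"] = labels
        q.to_csv(OUT / f"admixture_K{K}.tsv", sep="\t", index=False)
        rows.append(dict(K=K, loglik=adm.loglik,
                         n_admixed=sum(l == "admixed" for l in labels)))
        print(f"K={K}: logL {adm.loglik:.1f}, "
              f"{rows[-1]['n_admixed']} admixed at q<0.85")
    pd.DataFrame(rows).to_csv(OUT / "admixture_fit.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
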