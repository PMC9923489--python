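"""Symbiont community analyses: plastid allele tensor, alpha-diversity
mixed model, and compositional partial RDA.

Builds the analysis-ready plastid allele tensor (allele/colony completeness
filters), fits the linear mixed model for the number of alleles per locus
(scaled read counts + latitude + shelf + host cluster, random intercepts
for locus and colony) and the partial RDA of allele composition conditioned
on per-locus read counts.  Writes under results/symbiont/.
"""

import json
import sys
from pathlib import Path

import pandas as pd

from holopop import symbiont as symmod

STUDY = Path("results/study")
OUT = Path("results/symbiont")
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    meta = pd.read_csv(STUDY / "metadata.tsv", sep="\t")
    pools = pd.read_csv(STUDY / "plastid_counts.tsv", sep="\t")

    tensor = symmod.plastid_allele_counts(pools)
    rep = tensor.filter_report
    print(f"tensor: {len(tensor.samples)} colonies x {len(tensor.loci)} loci "
          f"({rep['colonies_removed']} colonies dropped by completeness)")
    na = tensor.n_alleles
    print(f"alleles per locus: median {na.stack().median():.0f}, "
          f"max {int(na.stack().max())}")
    tensor.long.to_csv(OUT / "allele_tensor.tsv", sep="\t", index=False)

    lmm = symmod.alpha_diversity_model(tensor, meta)
    lmm.fixed_effects.to_csv(OUT / "alpha_model_effects.tsv", sep="\t")
    lmm.term_tests.to_csv(OUT / "alpha_model_tests.tsv", sep="\t", index=False)
    print("alpha-diversity mixed model fixed effects:")
    print(lmm.fixed_effects.round(4).to_string())

    rda = symmod.symbiont_rda(tensor, meta, n_perm=999, seed=SEED)
    rda.terms.to_csv(OUT / "rda_terms.tsv", sep="\t", index=False)
    rda.axes.to_csv(OUT / "rda_axes.tsv", sep="\t", index=False)
    print("symbiont composition partial RDA:")
    for _, row in rda.terms.iterrows():
        print(f"  {row['term']}: {100 * row['variance_fraction']:.1f}% "
              f"F = {row['F']:.2f}, p = {row['p_value']:.3f}")
    (OUT / "symbiont.json").write_text(json.dumps(
        dict(n_colonies=len(tensor.samples),
             rda_terms={r["term"]: dict(variance_fraction=r["variance_fraction"],
                                        F=r["F"], p=r["p_value"])
                        for _, r in rda.terms.iterrows()}),
        indent=2,
    ))


if __name__ == "__main__":
    main()
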