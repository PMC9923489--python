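"""Method-validation experiments at reduced scale.

Runs the simulation experiments that back the pipeline's claims — SFS-EM
fidelity, FST internal consistency, demographic-model nesting and parameter
recovery, clone detection, Mantel/RDA calibration and power, and
alpha-diversity slope recovery — and writes a single JSON summary under
results/validation/.  Full-scale versions of the same experiments run in
the test suite and scripts/acceptance.py; sizes here are trimmed for a
quick interactive pass.
"""

import json
import sys
from pathlib import Path

from holopop import experiments as E

OUT = Path("results/validation")
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    out = {}
    out["sfs_em"] = E.sfs_em_fidelity(seed=SEED, n_sites=20_000)
    print("SFS-EM total-variation distance:", round(out["sfs_em"]["tv_distance"], 4))
    out["fst"] = E.fst_window_consistency(seed=SEED)
    print("FST vs direct computation:", out["fst"]["abs_error_vs_direct"])
    out["nesting"] = E.model_nesting_error(n=12)
    print("model nesting max relative error:",
          max(out["nesting"]["im_vs_div_max_rel"],
              out["nesting"]["sc_vs_im_max_rel"]))
    rec = E.demographic_recovery(seed=SEED, n_seeds=3)
    out["demography"] = {k: v for k, v in rec.items() if k != "table"}
    print("demographic recovery (3 seeds):", out["demography"])
    clones = E.clone_detection_experiment(seed=SEED, n_seeds=5)
    out["clones"] = {k: v for k, v in clones.items() if k != "table"}
    print("clone detection:", out["clones"])
    out["mantel"] = E.mantel_calibration(seed=SEED, n_null=100)
    print("Mantel null rejection:", out["mantel"]["rejection_rate"])
    out["rda_null"] = E.rda_null_calibration(seed=SEED, n_null=100)
    print("RDA null rejections:", out["rda_null"])
    out["rda_power"] = E.rda_power_experiment(seed=SEED, n_runs=30)
    print("RDA power:", out["rda_power"])
    out["alpha"] = E.alpha_model_recovery(seed=SEED, n_runs=30)
    print("alpha-model recovery:", out["alpha"])
    (OUT / "validation.json").write_text(
        json.dumps(out, indent=2, default=float)
    )


if __name__ == "__main__":
    main()
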