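"""File formats, configuration and the end-to-end pipeline driver.

Formats: Beagle genotype-likelihood text (the ANGSD-ecosystem interchange
format), VCF with GL/PL FORMAT fields (via cyvcf2), a dadi-style SFS text
serialization, TSV tables and JSON reports.  The pipeline driver runs the
synthetic study end to end (simulate, filter, clone-prune, structure, SFS
and FST, spatial and symbiont models) and writes per-stage artifacts with
provenance (config hash, seed, package version).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .gl import GLMatrix
from .sfs import FoldedSFS

__all__ = [
    "write_beagle_gl",
    "read_beagle_gl",
    "read_vcf_gl",
    "write_sfs_text",
    "read_sfs_text",
    "PipelineConfig",
    "run_pipeline",
]


def write_beagle_gl(gl: GLMatrix, path) -> None:
    """Write a GLMatrix as Beagle-GL text: marker, allele1, allele2, then
    three likelihood columns per individual (linear scale, normalized to
    sum 1 per entry)."""
    lik = gl.linear()
    norm = lik / lik.sum(axis=2, keepdims=True)
    with open(path, "w") as fh:
        header = ["marker", "allele1", "allele2"]
        for s in gl.sample_ids:
            header += [s, s, s]
        fh.write("\t".join(header) + "\n")
        for i in range(gl.n_sites):
            row = [f"site_{gl.positions[i]}", "0", "1"]
            row += [f"{v:.17g}" for v in norm[i].ravel()]
            fh.write("\t".join(row) + "\n")


def read_beagle_gl(path) -> GLMatrix:
    """Parse Beagle-GL text into a GLMatrix (log10, per-entry max 0).

    Entries whose three likelihoods are equal are flagged missing (zero
    reads produce flat likelihoods).  Malformed rows raise with the line
    number.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 6 or (len(header) - 3) % 3 != 0:
            raise ValueError("malformed Beagle header: need 3 + 3k columns")
        sample_ids = header[3::3]
        n_ind = len(sample_ids)
        rows, positions = [], []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3 + 3 * n_ind:
                raise ValueError(
                    f"line {lineno}: expected {3 + 3 * n_ind} fields, "
                    f"got {len(parts)}"
                )
            try:
                vals = np.array(parts[3:], dtype=float)
            except ValueError as err:
                raise ValueError(f"line {lineno}: {err}") from None
            rows.append(vals.reshape(n_ind, 3))
            marker = parts[0]
            positions.append(
                int(marker.rsplit("_", 1)[-1])
                if "_" in marker
                else lineno - 2
            )
    lik = np.array(rows)
    if lik.size == 0:
        raise ValueError("empty Beagle file")
    with np.errstate(divide="ignore"):
        gl10 = np.log10(np.maximum(lik, 1e-300))
    gl10 -= gl10.max(axis=2, keepdims=True)
    flat = np.isclose(lik.max(axis=2), lik.min(axis=2))
    gl10[flat] = 0.0
    return GLMatrix(
        gl=gl10, mask=flat, positions=np.array(positions),
        sample_ids=list(sample_ids),
    )


def read_vcf_gl(path) -> tuple[GLMatrix, int]:
    """Read genotype likelihoods from a VCF with PL or GL FORMAT fields.

    PL values are phred-scaled (-10 log10), converted exactly; multiallelic
    records are skipped and counted.  Returns (GLMatrix, n_multiallelic).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    rows, positions, depth_rows = [], [], []
    n_multi = 0
    has_any = False
    def fmt(var, key):
        try:
            return var.format(key)
        except KeyError:
            return None

    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        pl = fmt(var, "PL")
        if pl is not None:
            gl10 = -np.asarray(pl, dtype=float) / 10.0
            has_any = True
        else:
            glf = fmt(var, "GL")
            if glf is None:
                continue
            gl10 = np.asarray(glf, dtype=float)
            has_any = True
        rows.append(gl10[:, :3])
        positions.append(var.POS - 1)  # to 0-based internal coordinates
        dp = fmt(var, "DP")
        depth_rows.append(
            np.asarray(dp, dtype=float).ravel() if dp is not None else None
        )
    if not has_any:
        raise ValueError("VCF contains neither PL nor GL FORMAT fields")
    gl10 = np.array(rows)
    gl10 = gl10 - gl10.max(axis=2, keepdims=True)
    flat = np.isclose(gl10.max(axis=2), gl10.min(axis=2))
    depth = None
    if all(d is not None for d in depth_rows):
        depth = np.array(depth_rows)
    return (
        GLMatrix(
            gl=gl10, mask=flat, positions=np.array(positions),
            sample_ids=sample_ids, depth=depth,
        ),
        n_multi,
    )


def write_sfs_text(sfs: FoldedSFS, path) -> None:
    """dadi-style serialization: a shape/folding line, the flattened
    entries, and a mask line (1 = masked)."""
    with open(path, "w") as fh:
        dims = " ".join(str(s + 1) for s in sfs.n)
        fh.write(f"{dims} {'folded' if sfs.folded else 'unfolded'}\n")
        fh.write(" ".join(f"{v:.17g}" for v in sfs.data.ravel()) + "\n")
        fh.write(" ".join("1" if m else "0" for m in sfs.mask.ravel()) + "\n")


def read_sfs_text(path) -> FoldedSFS:
    with open(path) as fh:
        head = fh.readline().split()
        folded = head[-1] == "folded"
        shape = tuple(int(x) for x in head[:-1])
        data = np.array(fh.readline().split(), dtype=float).reshape(shape)
        mask = (
            np.array(fh.readline().split(), dtype=int)
            .astype(bool)
            .reshape(shape)
        )
    return FoldedSFS(
        data, tuple(s - 1 for s in shape), mask=mask, folded=folded
    )


@dataclass
class PipelineConfig:
    """End-to-end synthetic-study pipeline settings."""

    out_dir: str = "results/pipeline"
    seed: int = 1
    # simulation scale
    n_pops: int = 3
    samples_per_pop: int = 12
    theta: float = 1500.0
    seq_length: float = 2e6
    T_div: float = 1.0
    migration: float = 0.5
    mean_depth: float = 5.0
    error_rate: float = 0.01
    n_clone_groups: int = 3
    n_tech_replicates: int = 4
    # filters
    maf_min: float = 0.05
    q_min: float = 0.85
    window: int = 50_000
    step: int = 10_000
    # symbiont
    n_colonies: int = 90
    n_perm: int = 199
    # stage toggles
    stages: tuple = (
        "simulate", "filter", "clones", "structure", "sfs", "fst",
        "spatial", "symbiont",
    )

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _provenance(cfg: PipelineConfig) -> dict:
    from . import __version__

    return dict(config_hash=cfg.config_hash(), seed=cfg.seed,
                version=__version__)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the enabled stages on synthetic data and write artifacts.

    Returns a report dict mapping stage names to key outputs; every stage
    writes its tables under ``cfg.out_dir`` and a markdown summary is
    emitted at the end.  Reruns with the same config and seed reproduce
    numerically identical outputs.
    """
    from . import gl as glmod
    from . import sfs as sfsmod
    from . import structure as structmod
    from . import symbiont as symmod
    from . import synth
    from .spatial import RDADesign, geodesic_distances, mantel_test, partial_rda

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = _provenance(cfg)
    (out / "config.json").write_text(
        json.dumps({**asdict(cfg), **prov}, indent=2, default=str)
    )
    report: dict = {"provenance": prov}
    stages = set(cfg.stages)

    if "simulate" not in stages:
        raise ValueError("pipeline requires the 'simulate' stage as input source")
    m = np.full((cfg.n_pops, cfg.n_pops), cfg.migration, dtype=float)
    np.fill_diagonal(m, 0.0)
    host_cfg = synth.HostSimConfig(
        n_pops=cfg.n_pops,
        sample_sizes=tuple([cfg.samples_per_pop] * cfg.n_pops),
        nu=tuple([1.0] * cfg.n_pops),
        T_div=cfg.T_div, M=m, theta=cfg.theta,
        seq_length=cfg.seq_length, seed=cfg.seed,
    )
    geno, true_sfs, positions, pops = synth.simulate_host_genotypes(host_cfg)
    read_cfg = synth.ReadSimConfig(
        mean_depth=cfg.mean_depth, error_rate=cfg.error_rate,
        n_clone_groups=cfg.n_clone_groups,
        n_tech_replicates=cfg.n_tech_replicates, seed=cfg.seed + 1,
    )
    pileup, glm, truth = synth.simulate_reads_and_gls(geno, read_cfg, positions)
    truth.to_csv(out / "clone_truth.tsv", sep="\t", index=False)
    report["simulate"] = dict(n_sites=int(glm.n_sites),
                              n_individuals=int(glm.n_individuals))

    # clone detection precedes the individual cut so every replicate pair
    # anchoring the threshold is still present
    kept_ids = list(glm.sample_ids)
    if "clones" in stages:
        dists = glmod.ibs_distance_matrix(glm, seed=cfg.seed + 2)
        rep_pairs = [
            (a, b)
            for a, b, rel in truth.itertuples(index=False)
            if rel == "replicate" and a in glm.sample_ids and b in glm.sample_ids
        ]
        if len(rep_pairs) >= 2:
            thr = glmod.clone_threshold(dists, rep_pairs)
        else:
            thr = 0.17
        clone_report = glmod.prune_clones(
            dists, thr, coverage=glm.coverage_per_individual(),
            replicate_pairs=rep_pairs,
        )
        kept_ids = [s for s in glm.sample_ids if s in set(clone_report.kept)]
        glm = glm.subset(
            individuals=[glm.sample_ids.index(s) for s in kept_ids]
        )
        pd.DataFrame(
            dict(member=sum(clone_report.groups, [])) if clone_report.groups
            else dict(member=[])
        ).to_csv(out / "clone_groups.tsv", sep="\t", index=False)
        report["clones"] = dict(
            threshold=thr, n_groups=len(clone_report.groups),
            removed=clone_report.removed,
        )
    else:
        report["clones"] = dict(
            skipped=True,
            warning="clone stage disabled: downstream sample set is unpruned",
        )

    if "filter" in stages:
        glm, filt_report = glmod.filter_dataset(glm, "discovery")
        filt_report.to_frame().to_csv(
            out / "filter_report.tsv", sep="\t", index=False
        )
        report["filter"] = filt_report.__dict__

    if "structure" in stages:
        pca = structmod.gl_pca(glm, maf_min=cfg.maf_min,
                               n_latent=cfg.n_pops - 1)
        adm = structmod.admixture_em(
            glm, K=cfg.n_pops, maf_min=cfg.maf_min, seed=cfg.seed + 3,
            n_starts=2, max_iter=300,
        )
        labels = structmod.assign_clusters(adm, q_min=cfg.q_min)
        pd.DataFrame(
            dict(sample=glm.sample_ids, label=labels,
                 **{f"q{k+1}": adm.Q[:, k] for k in range(adm.K)})
        ).to_csv(out / "admixture.tsv", sep="\t", index=False)
        np.savetxt(out / "covariance.tsv", pca.cov, delimiter="\t")
        report["structure"] = dict(
            loglik=adm.loglik,
            n_admixed=int(sum(1 for l in labels if l == "admixed")),
        )

    def base_col(sid: str) -> int:
        return int(sid.split("_")[0][3:])

    pop_of = {sid: int(pops[base_col(sid)]) for sid in glm.sample_ids}
    if "sfs" in stages:
        div_rows = []
        for p in range(cfg.n_pops):
            members = [
                i for i, s in enumerate(glm.sample_ids) if pop_of[s] == p
            ]
            if len(members) < 2:
                continue
            est = sfsmod.estimate_folded_sfs(glm, individuals=members)
            write_sfs_text(est, out / f"sfs_pop{p}.txt")
            stats = sfsmod.diversity_from_sfs(est)
            div_rows.append(
                dict(pop=p, pi=stats.pi, theta_w=stats.theta_w,
                     segregating=stats.segregating)
            )
        pd.DataFrame(div_rows).to_csv(
            out / "diversity.tsv", sep="\t", index=False
        )
        report["sfs"] = dict(n_pops=len(div_rows))

    if "fst" in stages:
        rows = []
        for p in range(cfg.n_pops):
            for q in range(p + 1, cfg.n_pops):
                # allele counts from the true genotypes of the underlying
                # (distinct) colonies represented by the kept libraries
                cols_p = sorted({base_col(s) for s in glm.sample_ids
                                 if pop_of[s] == p})
                cols_q = sorted({base_col(s) for s in glm.sample_ids
                                 if pop_of[s] == q})
                ac1 = geno[:, cols_p].sum(axis=1)
                ac2 = geno[:, cols_q].sum(axis=1)
                mem_p, mem_q = cols_p, cols_q
                res = sfsmod.fst_from_counts(
                    ac1, 2 * len(mem_p), ac2, 2 * len(mem_q),
                    positions=glm.positions, window=cfg.window, step=cfg.step,
                )
                res.windows.to_csv(
                    out / f"fst_windows_{p}_{q}.tsv", sep="\t", index=False
                )
                rows.append(dict(pop_a=p, pop_b=q, fst=res.fst_weighted))
        fst_tab = pd.DataFrame(rows)
        fst_tab.to_csv(out / "fst.tsv", sep="\t", index=False)
        report["fst"] = fst_tab.to_dict("records")

    meta = synth.make_study_metadata(cfg.n_colonies, seed=cfg.seed + 4)
    if "spatial" in stages:
        reefs = meta.drop_duplicates("reef")[["reef", "latitude", "longitude"]]
        geo = geodesic_distances(reefs)
        geo.to_frame().to_csv(out / "reef_distances_km.tsv", sep="\t")
        report["spatial"] = dict(n_reefs=len(reefs))

    if "symbiont" in stages:
        sym_cfg = synth.SymbiontSimConfig(
            n_colonies=cfg.n_colonies, seed=cfg.seed + 5
        )
        long_counts = synth.simulate_symbiont_pools(sym_cfg, meta)
        tensor = symmod.plastid_allele_counts(long_counts)
        long_counts.to_csv(out / "plastid_counts.tsv", sep="\t", index=False)
        lmm = symmod.alpha_diversity_model(tensor, meta)
        lmm.fixed_effects.to_csv(out / "alpha_model.tsv", sep="\t")
        rda = symmod.symbiont_rda(
            tensor, meta, n_perm=cfg.n_perm, seed=cfg.seed + 6,
            test_axes=False,
        )
        rda.terms.to_csv(out / "symbiont_rda_terms.tsv", sep="\t", index=False)
        report["symbiont"] = dict(
            n_colonies=len(tensor.samples),
            shelf_fraction=float(
                rda.terms.set_index("term").loc["shelf", "variance_fraction"]
            ),
        )

    lines = ["# Pipeline summary", "", f"Config hash: {prov['config_hash']}",
             f"Seed: {cfg.seed}", ""]
    for stage, info in report.items():
        lines.append(f"## {stage}")
        lines.append("```json")
        lines.append(json.dumps(info, indent=2, default=str))
        lines.append("```")
    (out / "summary.md").write_text("\n".join(lines))
    return report

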