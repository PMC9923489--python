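"""Pooled symbiont community analysis from colony-level shotgun reads.

A coral colony's shotgun library co-captures reads from its algal
endosymbionts (Cladocopium).  Treating each colony as a pooled sample (as
in pool-seq), symbiont variation is summarized two ways: an ITS2 screen
verifying the symbiont genus (reference hits with a minimum read count),
and allele counts at a fixed panel of plastid loci (SNPs and indels),
yielding per-colony community measures — the number of alleles per locus
(alpha diversity) and the allele-count composition (beta diversity).

Alpha diversity is modelled with a linear mixed model (number of alleles ~
scaled read counts + latitude + shelf position + host cluster, random
intercepts for locus and colony); composition with a partial RDA
conditioned on per-locus read counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .spatial import OrdinationResult, RDADesign, partial_rda

__all__ = [
    "ITS2HitTable",
    "PlastidAlleleTensor",
    "AlleleFilter",
    "MixedModelResult",
    "classify_its2",
    "its2_hits_from_alignments",
    "plastid_counts_from_alignments",
    "plastid_allele_counts",
    "alpha_diversity_model",
    "symbiont_rda",
]


@dataclass
class ITS2HitTable:
    """Colony x reference mapped-read counts (MAPQ-filtered upstream)."""

    counts: pd.DataFrame  # index colony, columns reference ids
    genus_of: dict  # reference id -> genus
    mapq_min: int = 20

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("hit counts must be non-negative")


def classify_its2(hits: ITS2HitTable, min_reads: int = 3) -> pd.DataFrame:
    """Call the symbiont genus per colony from ITS2 reference hits.

    A reference is present iff it attracted >= min_reads mapped reads; the
    genus call is the set of genera of present references (colonies with no
    present reference are 'unclassified').
    """
    rows = []
    for colony, row in hits.counts.iterrows():
        present = [ref for ref, c in row.items() if c >= min_reads]
        genera = sorted({hits.genus_of.get(ref, "unknown") for ref in present})
        rows.append(
            dict(
                colony=colony,
                present_references=",".join(map(str, present)),
                n_present=len(present),
                genus="unclassified" if not genera else "+".join(genera),
            )
        )
    return pd.DataFrame(rows)


def its2_hits_from_alignments(
    paths: dict, genus_of: dict, mapq_min: int = 20
) -> ITS2HitTable:
    """Build the ITS2 hit table from per-colony SAM/BAM alignments.

    ``paths`` maps colony id -> alignment file of that colony's reads
    against the ITS2 reference set; reads with MAPQ < mapq_min or
    unmapped are ignored.
    """
    import pysam

    rows = {}
    refs = set()
    for colony, path in paths.items():
        counts: dict = {}
        with pysam.AlignmentFile(str(path), check_sq=False) as af:
            for read in af.fetch(until_eof=True):
                if read.is_unmapped or read.mapping_quality < mapq_min:
                    continue
                counts[read.reference_name] = counts.get(read.reference_name, 0) + 1
        rows[colony] = counts
        refs |= set(counts)
    table = pd.DataFrame(
        [[rows[c].get(r, 0) for r in sorted(refs)] for c in rows],
        index=list(rows), columns=sorted(refs),
    )
    return ITS2HitTable(counts=table, genus_of=genus_of, mapq_min=mapq_min)


def plastid_counts_from_alignments(
    paths: dict, loci: pd.DataFrame, base_quality_min: int = 30,
    mapq_min: int = 20,
) -> pd.DataFrame:
    """Raw per-colony allele counts at SNP loci from plastid alignments.

    ``loci`` is BED-like with columns (contig, position, locus) giving
    0-based SNP positions on the plastid reference.  Counts the bases
    (quality >= base_quality_min) observed at each locus per colony and
    returns the long table consumed by :func:`plastid_allele_counts`.
    Indel loci are keyed by exact inserted/deleted sequence when given a
    pre-tabulated count table instead; the alignment path covers SNPs.
    """
    import pysam

    required = {"contig", "position", "locus"}
    if not required.issubset(loci.columns):
        raise KeyError(f"locus table must have columns {sorted(required)}")
    wanted: dict = {}
    for _, loc in loci.iterrows():
        wanted.setdefault(loc["contig"], {})[int(loc["position"])] = loc["locus"]

    rows = []
    for colony, path in paths.items():
        counts: dict = {}
        with pysam.AlignmentFile(str(path), check_sq=False) as af:
            lengths = dict(zip(af.references, af.lengths))
            for contig, sites in wanted.items():
                if contig in lengths:
                    over = [p for p in sites if p >= lengths[contig]]
                    if over:
                        raise ValueError(
                            f"locus {sites[over[0]]} at {contig}:{over[0]} "
                            f"outside reference bounds ({lengths[contig]} bp)"
                        )
            for read in af.fetch(until_eof=True):
                if read.is_unmapped or read.mapping_quality < mapq_min:
                    continue
                sites = wanted.get(read.reference_name)
                if not sites:
                    continue
                seq = read.query_sequence
                quals = read.query_qualities
                for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                    if rpos in sites:
                        if quals is not None and quals[qpos] < base_quality_min:
                            continue
                        key = (sites[rpos], seq[qpos])
                        counts[key] = counts.get(key, 0) + 1
        for (locus, base), c in sorted(counts.items()):
            rows.append((colony, locus, base, c))
    return pd.DataFrame(rows, columns=["sample", "locus", "allele", "count"])


@dataclass
class AlleleFilter:
    """Allele- and colony-level completeness filters for the plastid panel."""

    min_count: int = 2
    min_freq: float = 0.01
    min_depth: int = 20


@dataclass
class PlastidAlleleTensor:
    """Per-colony, per-locus allele counts for the plastid panel.

    ``long`` has columns (sample, locus, allele, count); the analysis-ready
    tensor is complete: every retained colony has depth at every locus.
    """

    long: pd.DataFrame
    loci: list[str]
    samples: list[str]
    filter_report: dict = field(default_factory=dict)

    @property
    def n_alleles(self) -> pd.DataFrame:
        """N_A per colony x locus (alpha diversity response)."""
        na = (
            self.long.groupby(["sample", "locus"])["allele"]
            .nunique()
            .unstack(fill_value=0)
        )
        return na.reindex(index=self.samples, columns=self.loci, fill_value=0)

    @property
    def depth(self) -> pd.DataFrame:
        d = (
            self.long.groupby(["sample", "locus"])["count"]
            .sum()
            .unstack(fill_value=0)
        )
        return d.reindex(index=self.samples, columns=self.loci, fill_value=0)

    def count_matrix(self) -> pd.DataFrame:
        """Colony x (locus, allele) wide count matrix for ordination."""
        wide = (
            self.long.assign(
                col=self.long["locus"].astype(str)
                + ":"
                + self.long["allele"].astype(str)
            )
            .pivot_table(
                index="sample", columns="col", values="count",
                aggfunc="sum", fill_value=0,
            )
        )
        return wide.reindex(index=self.samples, fill_value=0)


def plastid_allele_counts(
    long_counts: pd.DataFrame,
    loci: list[str] | None = None,
    filters: AlleleFilter | None = None,
) -> PlastidAlleleTensor:
    """Build the analysis-ready allele tensor from raw per-colony counts.

    Within each colony-locus, alleles below ``min_count`` reads or below
    ``min_freq`` of the local depth are dropped (pool-seq noise floor);
    colonies are then retained only if their post-filter depth is >=
    ``min_depth`` at every locus, so the final tensor has no missing
    cells.  A filter report records what was removed at each step.
    """
    filters = filters or AlleleFilter()
    required = {"sample", "locus", "allele", "count"}
    if not required.issubset(long_counts.columns):
        raise KeyError(f"count table must have columns {sorted(required)}")
    df = long_counts.copy()
    if (df["count"] < 0).any():
        raise ValueError("allele counts must be non-negative")
    if loci is None:
        loci = sorted(df["locus"].unique())
    else:
        unknown = set(df["locus"]) - set(loci)
        df = df[df["locus"].isin(loci)]
        if unknown:
            pass  # extraneous loci silently restricted to the panel

    n_alleles_in = len(df)
    depth = df.groupby(["sample", "locus"])["count"].transform("sum")
    keep = (df["count"] >= filters.min_count) & (
        df["count"] >= filters.min_freq * depth
    )
    df = df[keep]
    n_alleles_dropped = n_alleles_in - len(df)

    post_depth = (
        df.groupby(["sample", "locus"])["count"].sum().unstack(fill_value=0)
    )
    post_depth = post_depth.reindex(columns=loci, fill_value=0)
    complete = post_depth.ge(filters.min_depth).all(axis=1)
    kept_samples = sorted(post_depth.index[complete])
    dropped_samples = sorted(post_depth.index[~complete])
    df = df[df["sample"].isin(kept_samples)]

    report = dict(
        alleles_in=n_alleles_in,
        alleles_removed=n_alleles_dropped,
        colonies_in=int(complete.size),
        colonies_removed=len(dropped_samples),
        colonies_removed_ids=dropped_samples,
        min_count=filters.min_count,
        min_freq=filters.min_freq,
        min_depth=filters.min_depth,
    )
    return PlastidAlleleTensor(
        long=df.reset_index(drop=True), loci=list(loci),
        samples=kept_samples, filter_report=report,
    )


@dataclass
class MixedModelResult:
    fixed_effects: pd.DataFrame
    random_variances: dict
    loglik: float
    converged: bool
    model: object
    term_tests: pd.DataFrame


def alpha_diversity_model(
    tensor: PlastidAlleleTensor,
    metadata: pd.DataFrame,
    family: str = "gaussian",
    shelf_reference: str = "inshore",
    cluster_reference: str | None = None,
) -> MixedModelResult:
    """Mixed model for the number of alleles per colony-locus.

    N_A ~ scaled(log-ish counts) + scaled(latitude) + shelf + host cluster,
    random intercepts for locus and colony (crossed, fit as variance
    components).  All continuous covariates are standardized.  Fixed
    effects are tested by Wald tests; multi-level factors get a joint Wald
    chi-square converted to an F statistic with the residual-based
    denominator df (an approximation, reported as such).
    """
    meta = metadata.set_index("sample")
    for col in ("latitude", "shelf", "host_cluster"):
        if col not in meta.columns:
            raise KeyError(f"metadata missing required column: {col!r}")
    na = tensor.n_alleles.stack().rename("NA_").reset_index()
    depth = tensor.depth.stack().rename("counts").reset_index()
    df = na.merge(depth, on=["sample", "locus"])
    df = df.join(meta[["latitude", "shelf", "host_cluster"]], on="sample")
    df["counts_z"] = (df["counts"] - df["counts"].mean()) / df["counts"].std()
    df["latitude_z"] = (df["latitude"] - df["latitude"].mean()) / df[
        "latitude"
    ].std()
    shelf_levels = [shelf_reference] + sorted(
        set(df["shelf"]) - {shelf_reference}
    )
    df["shelf"] = pd.Categorical(df["shelf"], categories=shelf_levels)
    clusters = sorted(df["host_cluster"].unique())
    if cluster_reference:
        clusters = [cluster_reference] + [
            c for c in clusters if c != cluster_reference
        ]
    df["host_cluster"] = pd.Categorical(df["host_cluster"], categories=clusters)

    fixed = "NA_ ~ counts_z + latitude_z + C(shelf) + C(host_cluster)"
    if family == "gaussian":
        df["group"] = 1
        vc = {"locus": "0 + C(locus)", "colony": "0 + C(sample)"}
        model = smf.mixedlm(fixed, df, groups="group", vc_formula=vc)
        with np.errstate(all="ignore"):
            res = model.fit(reml=True, method="lbfgs")
        fe = pd.DataFrame(
            dict(estimate=res.fe_params, se=res.bse_fe[: len(res.fe_params)],
                 p_value=res.pvalues[: len(res.fe_params)])
        )
        rand = {k: float(v) for k, v in res.vcs_to_dict().items()} if hasattr(
            res, "vcs_to_dict"
        ) else dict(zip(vc.keys(), np.atleast_1d(res.vcomp)))
        converged = bool(res.converged)
        llf = float(res.llf)
    elif family == "poisson":
        model = sm.PoissonBayesMixedGLM.from_formula(
            fixed, {"locus": "0 + C(locus)", "colony": "0 + C(sample)"}, df
        )
        res = model.fit_map()
        k = len(res.fe_mean) if hasattr(res, "fe_mean") else model.k_fep
        fe = pd.DataFrame(
            dict(
                estimate=res.params[:k], se=res.fe_sd if hasattr(res, "fe_sd")
                else np.sqrt(np.diag(res.cov_params())[:k]),
            )
        )
        fe.index = model.exog_names
        fe["p_value"] = np.nan
        rand = {}
        converged = True
        llf = float(getattr(res, "logposterior", np.nan) or np.nan)
    else:
        raise ValueError(f"unknown family: {family!r}")

    # joint Wald tests per term (F with residual-df denominator approx)
    names = list(fe.index)
    term_rows = []
    df_resid = len(df) - len(names)
    params = fe["estimate"].to_numpy()
    if family == "gaussian":
        cov = res.cov_params().iloc[: len(names), : len(names)].to_numpy()
        for term, matcher in [
            ("counts", "counts_z"), ("latitude", "latitude_z"),
            ("shelf", "C(shelf)"), ("host_cluster", "C(host_cluster)"),
        ]:
            idx = [i for i, nm in enumerate(names) if matcher in nm]
            if not idx:
                continue
            b = params[idx]
            vsub = cov[np.ix_(idx, idx)]
            wald = float(b @ np.linalg.solve(vsub, b))
            f_stat = wald / len(idx)
            from scipy import stats as _st

            p = float(_st.f.sf(f_stat, len(idx), df_resid))
            term_rows.append(
                dict(term=term, df_num=len(idx), df_den=df_resid,
                     F=f_stat, p_value=p)
            )
    term_tests = pd.DataFrame(term_rows)
    return MixedModelResult(
        fixed_effects=fe, random_variances=rand, loglik=llf,
        converged=converged, model=res, term_tests=term_tests,
    )


def symbiont_rda(
    tensor: PlastidAlleleTensor,
    metadata: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
    hellinger: bool = False,
    shelf_reference: str = "inshore",
    test_axes: bool = True,
) -> OrdinationResult:
    """Partial RDA of symbiont allele composition.

    Response: the colony x allele count matrix (optionally
    Hellinger-transformed); constraints: latitude (scaled), shelf position
    (inshore reference) and host cluster; conditioning: per-locus read
    counts, to absorb sequencing-effort differences.
    """
    meta = metadata.set_index("sample").loc[tensor.samples]
    Y = tensor.count_matrix().to_numpy(float)
    if hellinger:
        row = Y.sum(axis=1, keepdims=True)
        Y = np.sqrt(Y / np.maximum(row, 1.0))
    constraints = pd.DataFrame(
        {
            "latitude": meta["latitude"].to_numpy(float),
            "shelf": meta["shelf"].astype(str).to_numpy(),
            "host_cluster": meta["host_cluster"].astype(str).to_numpy(),
        }
    )
    depth = tensor.depth.to_numpy(float)
    conditioning = pd.DataFrame(
        depth, columns=[f"counts_{l}" for l in tensor.loci]
    ).reset_index(drop=True)
    design = RDADesign(
        Y=Y, constraints=constraints, conditioning=conditioning,
        references={"shelf": shelf_reference},
    )
    return partial_rda(design, n_perm=n_perm, seed=seed, test_axes=test_axes)
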