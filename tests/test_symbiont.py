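import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from holopop import synth
from holopop.symbiont import (
    AlleleFilter,
    ITS2HitTable,
    alpha_diversity_model,
    classify_its2,
    its2_hits_from_alignments,
    plastid_allele_counts,
    plastid_counts_from_alignments,
    symbiont_rda,
)


@pytest.fixture(scope="module")
def sym_dataset():
    meta = synth.make_study_metadata(50, seed=21)
    cfg = synth.SymbiontSimConfig(n_colonies=50, seed=22)
    pools = synth.simulate_symbiont_pools(cfg, meta)
    tensor = plastid_allele_counts(pools)
    return meta, tensor


class TestIts2:
    def _hits(self, rows, refs):
        return ITS2HitTable(
            counts=pd.DataFrame(rows, columns=refs,
                                index=[f"col{i}" for i in range(len(rows))]),
            genus_of={r: "Cladocopium" for r in refs},
        )

    def test_three_read_threshold(self):
        hits = self._hits([[2, 3]], ["C40c", "C72k"])
        out = classify_its2(hits)
        assert out.loc[0, "present_references"] == "C72k"
        assert out.loc[0, "genus"] == "Cladocopium"

    def test_zero_hits_unclassified(self):
        hits = self._hits([[0, 0]], ["C40c", "C72k"])
        out = classify_its2(hits)
        assert out.loc[0, "genus"] == "unclassified"

    def test_counting_oracle_5_3_1(self):
        hits = self._hits([[5, 3, 1]], ["a", "b", "c"])
        out = classify_its2(hits)
        assert out.loc[0, "present_references"] == "a,b"
        assert out.loc[0, "n_present"] == 2


class TestPlastidCounts:
    def test_counts_preserved_exactly(self):
        long = pd.DataFrame(
            dict(sample=["c1"] * 3, locus=["l0"] * 3,
                 allele=["A", "T", "ins:AT"], count=[10, 5, 2])
        )
        t = plastid_allele_counts(
            long, filters=AlleleFilter(min_count=2, min_freq=0.0, min_depth=1)
        )
        na = t.n_alleles
        assert int(na.loc["c1", "l0"]) == 3
        assert int(t.depth.loc["c1", "l0"]) == 17

    def test_rare_alleles_filtered(self):
        long = pd.DataFrame(
            dict(sample=["c1"] * 3, locus=["l0"] * 3,
                 allele=["A", "T", "G"], count=[100, 5, 1])
        )
        t = plastid_allele_counts(
            long, filters=AlleleFilter(min_count=2, min_freq=0.01, min_depth=1)
        )
        assert int(t.n_alleles.loc["c1", "l0"]) == 2

    def test_incomplete_colonies_dropped(self):
        long = pd.DataFrame(
            dict(sample=["c1", "c1", "c2"], locus=["l0", "l1", "l0"],
                 allele=["A", "A", "A"], count=[50, 50, 50])
        )
        t = plastid_allele_counts(long, loci=["l0", "l1"],
                                  filters=AlleleFilter(min_depth=20))
        assert t.samples == ["c1"]
        assert t.filter_report["colonies_removed"] == 1

    def test_tensor_complete(self, sym_dataset):
        _, tensor = sym_dataset
        depth = tensor.depth
        assert (depth >= AlleleFilter().min_depth).all().all()

    def test_richness_monotone_under_read_subsampling(self):
        rng = np.random.default_rng(3)
        counts = np.array([40, 25, 12, 6, 3])
        alleles = list("ACGTN")
        na_by_depth = []
        for frac in (1.0, 0.5, 0.2, 0.05):
            sub = rng.binomial(counts, frac)
            na_by_depth.append((sub > 0).sum())
        assert all(
            a >= b for a, b in zip(na_by_depth, na_by_depth[1:])
        ) or na_by_depth[0] >= na_by_depth[-1]


class TestAlphaModel:
    def test_constant_richness_gives_zero_slopes(self):
        meta = synth.make_study_metadata(30, seed=31)
        cfg = synth.SymbiontSimConfig(n_colonies=30, alleles_min=1,
                                      alleles_max=1, seed=32)
        pools = synth.simulate_symbiont_pools(cfg, meta)
        tensor = plastid_allele_counts(
            pools, filters=AlleleFilter(min_depth=10)
        )
        res = alpha_diversity_model(tensor, meta)
        slopes = res.fixed_effects.drop(index="Intercept", errors="ignore")
        assert np.allclose(slopes["estimate"], 0.0, atol=1e-6)

    def test_matches_lme4_reml(self, sym_dataset, tmp_path):
        meta, tensor = sym_dataset
        res = alpha_diversity_model(tensor, meta)
        df = tensor.n_alleles.stack().rename("NA_").reset_index()
        depth = tensor.depth.stack().rename("counts").reset_index()
        df = df.merge(depth).join(
            meta.set_index("sample")[["latitude", "shelf", "host_cluster"]],
            on="sample",
        )
        df["counts_z"] = (df["counts"] - df["counts"].mean()) / df["counts"].std()
        df["latitude_z"] = (
            df["latitude"] - df["latitude"].mean()
        ) / df["latitude"].std()
        df.to_csv(tmp_path / "data.csv", index=False)
        rscript = textwrap.dedent(
            f"""
            suppressMessages(library(lme4))
            d <- read.csv("{tmp_path}/data.csv")
            d$shelf <- relevel(factor(d$shelf), ref="inshore")
            m <- lmer(NA_ ~ counts_z + latitude_z + shelf + host_cluster
                      + (1|locus) + (1|sample), data=d, REML=TRUE)
            fe <- fixef(m)
            for (nm in names(fe)) cat(nm, fe[[nm]], "\\n")
            """
        )
        proc = subprocess.run(["Rscript", "-e", rscript],
                              capture_output=True, text=True)
        if proc.returncode != 0:
            pytest.skip(f"lme4 unavailable: {proc.stderr[:300]}")
        r_fe = {}
        for line in proc.stdout.strip().splitlines():
            parts = line.split()
            if len(parts) >= 2:
                r_fe[parts[0]] = float(parts[1])
        ours = res.fixed_effects["estimate"]
        assert ours["latitude_z"] == pytest.approx(r_fe["latitude_z"],
                                                   abs=1e-4)
        assert ours["counts_z"] == pytest.approx(r_fe["counts_z"], abs=1e-4)
        assert ours["Intercept"] == pytest.approx(r_fe["(Intercept)"],
                                                  abs=1e-3)


class TestSymbiontRda:
    def test_conditioning_on_response_columns_kills_variance(self, sym_dataset):
        meta, tensor = sym_dataset
        from holopop.spatial import RDADesign, partial_rda

        Y = tensor.count_matrix().to_numpy(float)[:, :6]
        meta2 = meta.set_index("sample").loc[tensor.samples]
        design = RDADesign(
            Y=Y,
            constraints=pd.DataFrame(
                dict(latitude=meta2["latitude"].to_numpy())
            ),
            conditioning=pd.DataFrame(
                Y, columns=[f"y{i}" for i in range(Y.shape[1])]
            ),
        )
        res = partial_rda(design, n_perm=9, seed=0, test_axes=False)
        assert res.ss_constrained == pytest.approx(0.0, abs=1e-12)

    def test_runs_and_partitions_three_terms(self, sym_dataset):
        meta, tensor = sym_dataset
        res = symbiont_rda(tensor, meta, n_perm=49, seed=0, test_axes=False)
        assert set(res.terms["term"]) == {"latitude", "shelf", "host_cluster"}
        assert (res.terms["variance_fraction"] >= 0).all()
        assert res.ss_conditioned + res.ss_constrained + res.ss_residual == (
            pytest.approx(res.ss_total, rel=1e-9)
        )


class TestAlignmentIngestion:
    def _write_sam(self, path, ref, length, reads):
        lines = ["@HD\tVN:1.6\tSO:unsorted", f"@SQ\tSN:{ref}\tLN:{length}"]
        for i, (pos, seq, mapq) in enumerate(reads):
            qual = "I" * len(seq)
            lines.append(
                f"r{i}\t0\t{ref}\t{pos + 1}\t{mapq}\t{len(seq)}M\t*\t0\t0"
                f"\t{seq}\t{qual}"
            )
        path.write_text("\n".join(lines) + "\n")

    def test_its2_hits_respect_mapq_filter(self, tmp_path):
        sam = tmp_path / "c1.sam"
        self._write_sam(sam, "C40c", 300,
                        [(10, "ACGTACGT", 60), (20, "ACGTACGT", 60),
                         (30, "ACGTACGT", 5)])
        hits = its2_hits_from_alignments(
            {"c1": sam}, genus_of={"C40c": "Cladocopium"}
        )
        assert int(hits.counts.loc["c1", "C40c"]) == 2

    def test_plastid_snp_counts_from_pileup(self, tmp_path):
        sam = tmp_path / "c1.sam"
        # three reads over position 5: two C, one T
        self._write_sam(sam, "contig1", 100,
                        [(0, "AAAAACAAAA", 60), (2, "AAACAAAA", 60),
                         (5, "TAAAA", 60)])
        loci = pd.DataFrame(
            dict(contig=["contig1"], position=[5], locus=["l0"])
        )
        counts = plastid_counts_from_alignments({"c1": sam}, loci)
        got = counts.set_index("allele")["count"]
        assert int(got["C"]) == 2
        assert int(got["T"]) == 1

    def test_locus_outside_reference_raises(self, tmp_path):
        sam = tmp_path / "c1.sam"
        self._write_sam(sam, "contig1", 50, [(0, "AAAA", 60)])
        loci = pd.DataFrame(
            dict(contig=["contig1"], position=[500], locus=["l0"])
        )
        with pytest.raises(ValueError, match="outside"):
            plastid_counts_from_alignments({"c1": sam}, loci)
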