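import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from holopop.spatial import (
    RDADesign,
    geodesic_distances,
    mantel_test,
    partial_rda,
    vincenty_km,
)


class TestVincenty:
    def test_identical_points_zero(self):
        assert vincenty_km(-18.5, 147.0, -18.5, 147.0) == 0.0

    def test_one_degree_longitude_on_equator(self):
        # WGS84 equatorial arc: 111.319 km within 1 m
        assert vincenty_km(0.0, 0.0, 0.0, 1.0) == pytest.approx(
            111.3195, abs=1e-3
        )

    def test_symmetry(self):
        a = vincenty_km(-18.2, 146.8, -23.4, 151.9)
        b = vincenty_km(-23.4, 151.9, -18.2, 146.8)
        assert a == pytest.approx(b, abs=1e-9)

    def test_out_of_range_coordinates_rejected(self):
        with pytest.raises(ValueError, match="latitude"):
            vincenty_km(95.0, 0.0, 0.0, 0.0)

    def test_matrix_builder(self):
        coords = pd.DataFrame(
            dict(reef=["a", "b", "c"], latitude=[-18.0, -19.0, -20.0],
                 longitude=[146.5, 147.0, 148.5])
        )
        geo = geodesic_distances(coords)
        assert geo.dist_km.shape == (3, 3)
        assert np.allclose(geo.dist_km, geo.dist_km.T)
        assert np.all(np.diag(geo.dist_km) == 0)
        # triangle inequality within geodesic tolerance
        d = geo.dist_km
        assert d[0, 2] <= d[0, 1] + d[1, 2] + 1e-6


class TestMantel:
    def _random_sym(self, n, seed):
        rng = np.random.default_rng(seed)
        m = rng.random((n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        return m

    def test_identical_matrices_give_r_one_min_p(self):
        m = self._random_sym(10, 0)
        res = mantel_test(m, m, n_perm=199, seed=1)
        assert res.r == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 200)

    def test_negated_matrix_gives_minus_one(self):
        m = self._random_sym(10, 2)
        res = mantel_test(-m + 2, m, n_perm=99, seed=1)
        assert res.r == pytest.approx(-1.0)

    def test_constant_matrix_rejected(self):
        m = np.ones((5, 5)) - np.eye(5)
        with pytest.raises(ValueError, match="constant"):
            mantel_test(m * 0, self._random_sym(5, 3))

    def test_too_few_units_rejected(self):
        m = self._random_sym(2, 4)
        with pytest.raises(ValueError, match="at least 3"):
            mantel_test(m, m)

    def test_relabeling_invariance(self):
        a = self._random_sym(8, 5)
        b = self._random_sym(8, 6)
        perm = np.random.default_rng(7).permutation(8)
        r1 = mantel_test(a, b, n_perm=49, seed=0).r
        r2 = mantel_test(a[np.ix_(perm, perm)], b[np.ix_(perm, perm)],
                         n_perm=49, seed=0).r
        assert r1 == pytest.approx(r2, abs=1e-12)


class TestPartialRda:
    def _design(self, n=30, p=15, seed=0, conditioning=None):
        rng = np.random.default_rng(seed)
        Y = rng.normal(size=(n, p))
        cons = pd.DataFrame(
            dict(latitude=rng.normal(size=n),
                 shelf=rng.choice(["inshore", "midshelf", "offshore"], n))
        )
        return Y, cons

    def test_single_predictor_matches_least_squares(self):
        rng = np.random.default_rng(1)
        n, p = 25, 8
        Y = rng.normal(size=(n, p))
        x = rng.normal(size=n)
        design = RDADesign(Y=Y, constraints=pd.DataFrame(dict(x=x)))
        res = partial_rda(design, n_perm=9, seed=0, test_axes=False)
        xc = (x - x.mean()) / x.std()
        Yc = Y - Y.mean(axis=0)
        beta = xc @ Yc / (xc @ xc)
        fitted = np.outer(xc, beta)
        assert res.ss_constrained == pytest.approx(
            float((fitted**2).sum()), abs=1e-10
        )

    def test_constraints_equal_conditioning_give_zero(self):
        rng = np.random.default_rng(2)
        n = 20
        x = rng.normal(size=n)
        Y = rng.normal(size=(n, 6))
        design = RDADesign(
            Y=Y, constraints=pd.DataFrame(dict(x=x)),
            conditioning=pd.DataFrame(dict(z=x)),
        )
        res = partial_rda(design, n_perm=9, seed=0, test_axes=False)
        assert res.ss_constrained == pytest.approx(0.0, abs=1e-18)

    def test_variance_decomposition_is_exact(self):
        rng = np.random.default_rng(3)
        n = 40
        Y = rng.normal(size=(n, 12))
        cons = pd.DataFrame(
            dict(latitude=rng.normal(size=n),
                 shelf=rng.choice(["inshore", "midshelf", "offshore"], n))
        )
        cond = pd.DataFrame(dict(c1=rng.normal(size=n), c2=rng.normal(size=n)))
        res = partial_rda(
            RDADesign(Y=Y, constraints=cons, conditioning=cond),
            n_perm=9, seed=0, test_axes=False,
        )
        assert (
            res.ss_conditioned + res.ss_constrained + res.ss_residual
        ) == pytest.approx(res.ss_total, rel=1e-10)

    def test_aliased_term_raises(self):
        rng = np.random.default_rng(4)
        n = 20
        x = rng.normal(size=n)
        design = RDADesign(
            Y=rng.normal(size=(n, 5)),
            constraints=pd.DataFrame(dict(a=x, b=2 * x)),
            scale_numeric=False,
        )
        with pytest.raises(ValueError, match="aliased|rank"):
            partial_rda(design, n_perm=9)

    def test_null_term_pvalues_calibrated(self):
        rejections = 0
        n_runs = 60
        for s in range(n_runs):
            Y, cons = self._design(seed=100 + s)
            res = partial_rda(RDADesign(Y=Y, constraints=cons),
                              n_perm=99, seed=s, test_axes=False)
            p = res.terms.set_index("term").loc["latitude", "p_value"]
            rejections += p <= 0.05
        # binomial(60, 0.05): 95% interval roughly [0, 7]
        assert rejections <= 7

    def test_matches_vegan_variance_partition(self, tmp_path):
        """Cross-check constrained/conditioned SS against R vegan."""
        rng = np.random.default_rng(11)
        n, p = 24, 6
        Y = rng.normal(size=(n, p))
        lat = rng.normal(size=n)
        cond = rng.normal(size=n)
        np.savetxt(tmp_path / "Y.csv", Y, delimiter=",")
        np.savetxt(tmp_path / "x.csv", np.column_stack([lat, cond]),
                   delimiter=",")
        rscript = textwrap.dedent(
            f"""
            suppressMessages(library(vegan))
            Y <- as.matrix(read.csv("{tmp_path}/Y.csv", header=FALSE))
            X <- read.csv("{tmp_path}/x.csv", header=FALSE)
            lat <- scale(X$V1); z <- X$V2
            m <- rda(Y ~ lat + Condition(z))
            cat(m$pCCA$tot.chi * {n - 1}, m$CCA$tot.chi * {n - 1},
                m$CA$tot.chi * {n - 1}, sep="\\n")
            """
        )
        proc = subprocess.run(
            ["Rscript", "-e", rscript], capture_output=True, text=True,
        )
        if proc.returncode != 0:
            pytest.skip(f"vegan unavailable: {proc.stderr[:200]}")
        cond_ss, constr_ss, resid_ss = map(float, proc.stdout.split())
        design = RDADesign(
            Y=Y, constraints=pd.DataFrame(dict(lat=lat)),
            conditioning=pd.DataFrame(dict(z=cond)),
        )
        res = partial_rda(design, n_perm=9, seed=0, test_axes=False)
        assert res.ss_conditioned == pytest.approx(cond_ss, rel=1e-6)
        assert res.ss_constrained == pytest.approx(constr_ss, rel=1e-6)
        assert res.ss_residual == pytest.approx(resid_ss, rel=1e-6)
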