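import numpy as np
import pandas as pd
import pytest

from holopop.demography import (
    DemographicFit,
    DemographicModelSpec,
    EnginePrecision,
    OptimizerConfig,
    UnitConversionConfig,
    bootstrap_ci,
    compare_models,
    convert_units,
    expected_sfs,
    fit_model,
)
from holopop.sfs import FoldedSFS, fold_sfs


def _quick_engine():
    return EnginePrecision(pts=40, n_ref=8, y_min=1e-6, dt0=0.01)


class TestExpectedSfs:
    def test_migration_zero_reduces_to_strict_isolation(self):
        base = dict(nu1=1.0, nu2=0.5, T=0.6)
        n = (10, 10)
        im = expected_sfs(
            DemographicModelSpec("im_asym"), n,
            params={**base, "m12": 0.0, "m21": 0.0}, engine=_quick_engine(),
        )
        div = expected_sfs(DemographicModelSpec("div"), n, params=base,
                           engine=_quick_engine())
        sel = ~im.mask & (div.data > 1e-12)
        rel = np.abs(im.data[sel] - div.data[sel]) / div.data[sel]
        assert rel.max() < 1e-6

    def test_full_contact_reduces_to_continuous_migration(self):
        base = dict(nu1=1.0, nu2=0.5, T=0.6, m12=1.0, m21=0.3)
        n = (10, 10)
        sc = expected_sfs(
            DemographicModelSpec("sc"), n, params={**base, "f_sc": 1.0},
            engine=_quick_engine(),
        )
        im = expected_sfs(DemographicModelSpec("im_asym"), n, params=base,
                          engine=_quick_engine())
        sel = ~sc.mask & (im.data > 1e-12)
        rel = np.abs(sc.data[sel] - im.data[sel]) / im.data[sel]
        assert rel.max() < 1e-6

    def test_linear_in_theta(self):
        spec = DemographicModelSpec("div")
        params = dict(nu1=1.0, nu2=1.0, T=0.5)
        a = expected_sfs(spec, (8, 8), params=params, theta=1.0,
                         engine=_quick_engine())
        b = expected_sfs(spec, (8, 8), params=params, theta=7.5,
                         engine=_quick_engine())
        np.testing.assert_allclose(b.data, 7.5 * a.data, rtol=1e-12)

    def test_out_of_bounds_parameters_rejected(self):
        with pytest.raises(ValueError, match="outside bounds"):
            expected_sfs(
                DemographicModelSpec("div"), (6, 6),
                params=dict(nu1=-1.0, nu2=1.0, T=0.5),
            )

    def test_matches_coalescent_expectation_for_divergence_model(self):
        """Strict isolation, nu = 1, T = 1: expected spectrum vs the mean
        branch-length spectrum of many coalescent replicates."""
        import msprime

        n = 8
        model = expected_sfs(
            DemographicModelSpec("div"), (n, n),
            params=dict(nu1=1.0, nu2=1.0, T=1.0),
        )
        demog = msprime.Demography()
        demog.add_population(name="p1", initial_size=0.5)
        demog.add_population(name="p2", initial_size=0.5)
        demog.add_population(name="anc", initial_size=0.5)
        demog.add_population_split(time=1.0, derived=["p1", "p2"],
                                   ancestral="anc")
        acc = np.zeros((n + 1, n + 1))
        reps = 30_000
        for ts in msprime.sim_ancestry(
            samples={"p1": n // 2, "p2": n // 2}, demography=demog,
            ploidy=2, num_replicates=reps, random_seed=17,
        ):
            acc += ts.allele_frequency_spectrum(
                sample_sets=[ts.samples(population=0),
                             ts.samples(population=1)],
                mode="branch", polarised=True, span_normalise=False,
            )
        oracle, omask = fold_sfs(acc / reps / 2.0)
        est = model.data
        sel = ~model.mask
        tv = 0.5 * np.abs(
            est[sel] / est[sel].sum() - oracle[sel] / oracle[sel].sum()
        ).sum()
        assert tv < 0.01


class TestFitting:
    def test_noise_free_self_consistency(self):
        """Fitting a model to its own expected spectrum recovers the
        parameters and the analytic Poisson maximum."""
        spec = DemographicModelSpec("div")
        true = dict(nu1=1.2, nu2=0.6, T=0.5)
        engine = _quick_engine()
        obs = expected_sfs(spec, (8, 8), params=true, theta=500.0,
                           engine=engine)
        cfg = OptimizerConfig(
            rounds=((2, 1, 200), (1, 0.25, 250)), seed=0,
            engine=engine, final_engine=engine, xatol=1e-6, fatol=1e-8,
        )
        fit = fit_model(obs, spec, config=cfg, start=dict(nu1=2.0, nu2=0.3,
                                                          T=1.0))
        for k, v in true.items():
            assert fit.params[k] == pytest.approx(v, rel=0.01)
        assert fit.theta_hat == pytest.approx(500.0, rel=0.01)

    def test_compare_models_orders_by_likelihood(self):
        def mkfit(model, ll):
            return DemographicFit(
                spec=DemographicModelSpec(model), params=dict(nu1=1, nu2=1,
                                                              T=1),
                theta_hat=1.0, loglik=ll, converged=True, trace=None,
                n1=8, n2=8, n_sites=100.0,
            )

        tab = compare_models([mkfit("div", -50.0), mkfit("im_sym", -10.0)])
        assert list(tab["model"]) == ["im_sym", "div"]
        assert tab.loc[1, "delta_loglik"] == pytest.approx(40.0)

    def test_equal_likelihood_ties_order_by_name(self):
        def mkfit(model):
            return DemographicFit(
                spec=DemographicModelSpec(model),
                params=dict(nu1=1, nu2=1, T=1),
                theta_hat=1.0, loglik=-5.0, converged=True, trace=None,
                n1=8, n2=8, n_sites=100.0,
            )

        tab = compare_models([mkfit("sc"), mkfit("div")])
        assert list(tab["model"]) == ["div", "sc"]
        assert tab["indistinguishable_from_best"].all()

    def test_mixed_observations_rejected(self):
        def mkfit(n_sites):
            return DemographicFit(
                spec=DemographicModelSpec("div"),
                params=dict(nu1=1, nu2=1, T=1), theta_hat=1.0, loglik=-5.0,
                converged=True, trace=None, n1=8, n2=8, n_sites=n_sites,
            )

        with pytest.raises(ValueError, match="different observed"):
            compare_models([mkfit(100.0), mkfit(200.0)])


class TestUnitConversion:
    def _fit(self, theta=100.0, params=None):
        params = params or dict(nu1=1.0, nu2=1.0, T=0.0)
        return DemographicFit(
            spec=DemographicModelSpec("div", params=params), params=params,
            theta_hat=theta, loglik=0.0, converged=True, trace=None,
            n1=8, n2=8, n_sites=1.0,
        )

    def test_mu_per_generation_arithmetic(self):
        cfg = UnitConversionConfig()
        assert cfg.mu_per_gen == pytest.approx(9.3e-8)

    def test_n_ref_direct_arithmetic(self):
        conv = convert_units(self._fit(theta=100.0), UnitConversionConfig())
        assert conv["N_ref"] == pytest.approx(
            100.0 / (4 * 9.3e-8 * 296_667), rel=1e-9
        )
        assert conv["N_ref"] == pytest.approx(906.124, abs=0.01)

    def test_zero_divergence_time_gives_zero_years(self):
        conv = convert_units(self._fit(), UnitConversionConfig())
        assert conv["T_div_years"] == 0.0

    def test_migrants_per_generation_formula(self):
        params = dict(nu1=2.0, nu2=0.5, T=1.0, m12=3.0, m21=1.0)
        fit = DemographicFit(
            spec=DemographicModelSpec("im_asym", params=params),
            params=params, theta_hat=50.0, loglik=0.0, converged=True,
            trace=None, n1=8, n2=8, n_sites=1.0,
        )
        conv = convert_units(fit, UnitConversionConfig())
        assert conv["migrants_per_gen_into_1"] == pytest.approx(3.0 * 2.0 / 2)
        assert conv["migrants_per_gen_into_2"] == pytest.approx(1.0 * 0.5 / 2)

    def test_nonpositive_config_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            UnitConversionConfig(mu_per_year=0.0)


class TestBootstrap:
    def test_quantiles_match_order_statistics(self):
        vals = np.arange(1, 101, dtype=float)
        assert np.quantile(vals, 0.025) == pytest.approx(3.475)
        assert np.quantile(vals, 0.975) == pytest.approx(97.525)

    def test_identical_blocks_give_zero_width_intervals(self):
        # one block repeated: every resample is the same dataset
        rng = np.random.default_rng(0)
        n = (8, 8)
        count1 = rng.integers(0, 5, 60)
        count2 = rng.integers(0, 5, 60)
        table = pd.DataFrame(
            dict(position=np.arange(60), count1=count1, count2=count2)
        )
        spec = DemographicModelSpec("div")
        engine = _quick_engine()
        cfg = OptimizerConfig(rounds=((1, 0, 40),), seed=0, engine=engine,
                              final_engine=engine)
        out = bootstrap_ci(
            table, spec, n, UnitConversionConfig(), n_boot=3,
            block_size=10_000_000, seed=1, config=cfg,
            start=dict(nu1=1.0, nu2=1.0, T=0.5),
        )
        assert out["n_success"] == 3
        for lo, hi in out["quantiles"].values():
            assert hi - lo == pytest.approx(0.0, abs=1e-9)
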