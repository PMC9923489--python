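"""Two-population demographic model fitting on folded joint spectra.

Four model families describe the history of a pair of diverged clusters:

* ``div`` — strict isolation: an ancestral population splits T time units
  ago (units of 2 N_ref generations) into populations of relative sizes
  nu1, nu2 with no subsequent gene flow.
* ``im_sym`` / ``im_asym`` — isolation with continuous migration, with one
  symmetric rate m or two directional rates m12 (into population 1) and
  m21, in units of 2 N_ref m.
* ``sc`` — secondary contact: strict isolation for the first part of the
  history, migration only during the final ``T_sc`` time units
  (parameterized internally as a fraction f_sc = T_sc / T so the
  constraint 0 <= T_sc <= T is built in).

Fitting maximizes a Poisson composite likelihood over the unmasked cells of
the folded joint SFS; the scale parameter theta = 4 N_ref mu L is profiled
analytically.  Optimization is a multi-round scheme with perturbed restarts
around the incumbent (replicates and perturbation size per round are
configurable), with the expected-spectrum engine precision increasing in
the final round.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln

from .diffusion import expected_sfs_2d
from .sfs import FoldedSFS, fold_sfs

__all__ = [
    "MODEL_PARAMS",
    "DemographicModelSpec",
    "OptimizerConfig",
    "DemographicFit",
    "UnitConversionConfig",
    "expected_sfs",
    "fit_model",
    "compare_models",
    "convert_units",
    "bootstrap_ci",
]

MODEL_PARAMS = {
    "div": ("nu1", "nu2", "T"),
    "im_sym": ("nu1", "nu2", "T", "m"),
    "im_asym": ("nu1", "nu2", "T", "m12", "m21"),
    "sc": ("nu1", "nu2", "T", "m12", "m21", "f_sc"),
}

_DEFAULT_BOUNDS = {
    "nu1": (1e-2, 100.0),
    "nu2": (1e-2, 100.0),
    "T": (1e-3, 6.0),
    # zero migration is a valid point spec (the strict-isolation limit);
    # fitting tightens the lower bound to keep the log10 search finite
    "m": (0.0, 20.0),
    "m12": (0.0, 20.0),
    "m21": (0.0, 20.0),
    "f_sc": (0.0, 1.0),
}
_FIT_FLOOR = 1e-3


@dataclass
class DemographicModelSpec:
    """A model family plus parameter bounds.

    ``params`` maps parameter names to values when used as a point spec
    (e.g. for generating an expected spectrum); bounds are used in fitting.
    """

    model: str
    params: dict | None = None
    bounds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.model not in MODEL_PARAMS:
            raise ValueError(
                f"unknown model {self.model!r}; choose from {sorted(MODEL_PARAMS)}"
            )
        self.bounds = {**{k: _DEFAULT_BOUNDS[k] for k in MODEL_PARAMS[self.model]},
                       **self.bounds}
        if self.params is not None:
            missing = set(MODEL_PARAMS[self.model]) - set(self.params)
            if missing:
                raise ValueError(f"missing parameters for {self.model}: {missing}")
            for k in ("nu1", "nu2"):
                if self.params.get(k, 1) <= 0:
                    raise ValueError(f"{k} must be positive")
            if self.params.get("T", 0) < 0:
                raise ValueError("T must be >= 0")
            if self.model == "sc" and not 0 <= self.params["f_sc"] <= 1:
                raise ValueError("f_sc must be in [0, 1] (T_sc = f_sc * T <= T)")

    @property
    def param_names(self) -> tuple:
        return MODEL_PARAMS[self.model]

    def to_engine_kwargs(self, params: dict) -> dict:
        """Translate model parameters into diffusion-engine arguments."""
        p = dict(params)
        kw = dict(nu1=p["nu1"], nu2=p["nu2"])
        if self.model == "div":
            kw.update(T=p["T"], m12=0.0, m21=0.0)
        elif self.model == "im_sym":
            kw.update(T=p["T"], m12=p["m"], m21=p["m"])
        elif self.model == "im_asym":
            kw.update(T=p["T"], m12=p["m12"], m21=p["m21"])
        else:  # sc: isolation for T - T_sc, then contact for T_sc
            t_sc = p["f_sc"] * p["T"]
            kw.update(T=t_sc, T_iso=p["T"] - t_sc, m12=p["m12"], m21=p["m21"])
        return kw


@dataclass
class EnginePrecision:
    """Numerical settings for the expected-SFS engine."""

    pts: int = 60
    crwd: float = 8.0
    n_ref: int = 16
    y_min: float = 1e-8
    dt0: float = 0.005


@dataclass
class OptimizerConfig:
    """Multi-round perturbed-restart optimization settings.

    Each round keeps the best point found so far, draws ``replicates``
    starts by perturbing it by up to ``fold`` 2-fold steps per parameter
    (log10-uniform), and polishes each with Nelder-Mead for ``maxiter``
    iterations.  Defaults follow the common four-round workflow for
    SFS-based model fitting; tests and the analysis scripts use lighter
    settings.
    """

    rounds: tuple = ((10, 3, 120), (10, 2, 150), (20, 2, 200), (30, 1, 300))
    seed: int = 0
    engine: EnginePrecision = field(default_factory=EnginePrecision)
    final_engine: EnginePrecision | None = None
    xatol: float = 1e-4
    fatol: float = 1e-4


@dataclass
class DemographicFit:
    spec: DemographicModelSpec
    params: dict
    theta_hat: float
    loglik: float
    converged: bool
    trace: pd.DataFrame
    n1: int
    n2: int
    n_sites: float
    converted: dict | None = None
    bootstrap_quantiles: dict | None = None

    def expected(self, engine: EnginePrecision | None = None) -> np.ndarray:
        e = engine or EnginePrecision()
        m = expected_sfs_2d(
            self.n1, self.n2, pts=e.pts, crwd=e.crwd, n_ref=e.n_ref,
            y_min=e.y_min, dt0=e.dt0, **self.spec.to_engine_kwargs(self.params),
        )
        folded, _ = fold_sfs(m)
        return folded * self.theta_hat


@dataclass
class UnitConversionConfig:
    """Physical-unit conversion constants.

    mu_per_year is per bp per year; L is the number of sites represented by
    the SFS; generation_years converts coalescent times to calendar years.
    """

    mu_per_year: float = 1.86e-8
    generation_years: float = 5.0
    L: float = 296_667.0

    def __post_init__(self) -> None:
        if self.mu_per_year <= 0 or self.generation_years <= 0 or self.L <= 0:
            raise ValueError("all unit-conversion constants must be positive")

    @property
    def mu_per_gen(self) -> float:
        return self.mu_per_year * self.generation_years


def expected_sfs(
    spec: DemographicModelSpec,
    n: tuple,
    params: dict | None = None,
    theta: float = 1.0,
    engine: EnginePrecision | None = None,
    fold: bool = True,
) -> FoldedSFS:
    """Expected (folded) joint SFS under a demographic model at scale theta."""
    p = params if params is not None else spec.params
    if p is None:
        raise ValueError("spec has no parameter values; pass params=")
    for k, v in p.items():
        lo, hi = spec.bounds.get(k, (-np.inf, np.inf))
        if not lo <= v <= hi:
            raise ValueError(f"parameter {k}={v} outside bounds [{lo}, {hi}]")
    e = engine or EnginePrecision()
    raw = expected_sfs_2d(
        n[0], n[1], pts=e.pts, crwd=e.crwd, n_ref=e.n_ref, y_min=e.y_min,
        dt0=e.dt0, **spec.to_engine_kwargs(p),
    ) * theta
    out = FoldedSFS(raw, (n[0], n[1]), folded=False)
    return out.fold() if fold else out


def _poisson_loglik(obs: np.ndarray, model: np.ndarray, mask: np.ndarray):
    """Poisson composite log-likelihood with theta profiled analytically."""
    o = obs[~mask]
    m = np.maximum(model[~mask], 1e-300)
    theta = o.sum() / m.sum()
    lam = m * theta
    ll = float((o * np.log(lam) - lam - gammaln(o + 1.0)).sum())
    return ll, float(theta)


def fit_model(
    obs: FoldedSFS,
    spec: DemographicModelSpec,
    config: OptimizerConfig | None = None,
    start: dict | None = None,
) -> DemographicFit:
    """Maximize the Poisson composite likelihood of a folded joint SFS.

    Optimization is over log10 parameters within bounds, multi-round with
    perturbed restarts; the best round is reported together with the full
    trace.  theta is profiled out analytically at every evaluation.
    """
    if obs.ndim != 2:
        raise ValueError("fit_model requires a 2D joint spectrum")
    cfg = config or OptimizerConfig()
    names = list(spec.param_names)
    lb = np.log10([max(spec.bounds[k][0], _FIT_FLOOR) for k in names])
    ub = np.log10([spec.bounds[k][1] for k in names])
    n1, n2 = obs.n
    data = obs.data
    mask = obs.mask

    def make_negll(engine: EnginePrecision):
        def negll(lp):
            lp = np.clip(lp, lb, ub)
            p = dict(zip(names, 10.0**lp))
            m = expected_sfs_2d(
                n1, n2, pts=engine.pts, crwd=engine.crwd, n_ref=engine.n_ref,
                y_min=engine.y_min, dt0=engine.dt0,
                **spec.to_engine_kwargs(p),
            )
            mf, _ = fold_sfs(m)
            ll, _ = _poisson_loglik(data, mf, mask)
            return -ll
        return negll

    rng = np.random.default_rng(cfg.seed)
    if start is not None:
        incumbent = np.log10([start[k] for k in names])
    else:
        incumbent = (lb + ub) / 2.0
    incumbent = np.clip(incumbent, lb, ub)

    trace_rows = []
    best_val = np.inf
    n_rounds = len(cfg.rounds)
    for rnd, (reps, fold_steps, maxiter) in enumerate(cfg.rounds):
        engine = cfg.engine
        if rnd == n_rounds - 1 and cfg.final_engine is not None:
            engine = cfg.final_engine
        negll = make_negll(engine)
        for rep in range(reps):
            if rnd == 0 and rep == 0:
                x0 = incumbent.copy()
            else:
                pert = rng.uniform(-fold_steps, fold_steps, len(names)) * np.log10(2.0)
                x0 = np.clip(incumbent + pert, lb, ub)
            res = minimize(
                negll, x0, method="Nelder-Mead",
                options=dict(maxiter=maxiter, xatol=cfg.xatol, fatol=cfg.fatol),
            )
            val = float(res.fun)
            trace_rows.append(
                dict(round=rnd + 1, replicate=rep + 1, loglik=-val,
                     **dict(zip(names, 10.0 ** np.clip(res.x, lb, ub))))
            )
            if val < best_val:
                best_val = val
                incumbent = np.clip(res.x, lb, ub)

    if not np.isfinite(best_val):
        raise RuntimeError(
            "all optimization starts failed; trace:\n"
            + pd.DataFrame(trace_rows).to_string()
        )
    best_params = dict(zip(names, 10.0**incumbent))
    final_engine = cfg.final_engine or cfg.engine
    m = expected_sfs_2d(
        n1, n2, pts=final_engine.pts, crwd=final_engine.crwd,
        n_ref=final_engine.n_ref, y_min=final_engine.y_min,
        dt0=final_engine.dt0, **spec.to_engine_kwargs(best_params),
    )
    mf, _ = fold_sfs(m)
    ll, theta_hat = _poisson_loglik(data, mf, mask)
    at_bound = np.any(np.isclose(incumbent, lb) & (np.abs(lb) > 0)) or np.any(
        np.isclose(incumbent, ub)
    )
    return DemographicFit(
        spec=spec, params=best_params, theta_hat=theta_hat, loglik=ll,
        converged=not at_bound, trace=pd.DataFrame(trace_rows),
        n1=n1, n2=n2, n_sites=float(data.sum()),
    )


def compare_models(fits: list, delta_indistinguishable: float = 2.0) -> pd.DataFrame:
    """Rank fits of the same observed spectrum by composite log-likelihood.

    Ties (and near-ties within ``delta_indistinguishable`` log-units, the
    situation where the data cannot separate the histories) are flagged;
    equal likelihoods order deterministically by model name.
    """
    if not fits:
        raise ValueError("no fits to compare")
    key = {(f.n1, f.n2, round(f.n_sites, 6)) for f in fits}
    if len(key) > 1:
        raise ValueError("fits compare different observed spectra")
    rows = [
        dict(model=f.spec.model, loglik=f.loglik, n_params=len(f.params),
             **{f"param_{k}": v for k, v in f.params.items()})
        for f in fits
    ]
    tab = pd.DataFrame(rows).sort_values(
        ["loglik", "model"], ascending=[False, True], kind="mergesort"
    )
    tab["delta_loglik"] = tab["loglik"].iloc[0] - tab["loglik"]
    tab["indistinguishable_from_best"] = tab["delta_loglik"] <= delta_indistinguishable
    return tab.reset_index(drop=True)


def convert_units(fit: DemographicFit, cfg: UnitConversionConfig) -> dict:
    """Convert scaled parameters to physical units.

    N_ref = theta / (4 mu_gen L); N_e,i = nu_i N_ref; divergence time in
    years = T * 2 N_ref * generation_years; migrants per generation into
    population i = M_ji nu_i / 2.
    """
    if fit.theta_hat <= 0:
        raise ValueError("theta_hat must be positive")
    mu_gen = cfg.mu_per_gen
    n_ref = fit.theta_hat / (4.0 * mu_gen * cfg.L)
    p = fit.params
    out = {
        "theta": fit.theta_hat,
        "N_ref": n_ref,
        "N_e1": p["nu1"] * n_ref,
        "N_e2": p["nu2"] * n_ref,
        "T_div_years": p["T"] * 2.0 * n_ref * cfg.generation_years,
    }
    if fit.spec.model == "sc":
        out["T_sc_years"] = p["f_sc"] * p["T"] * 2.0 * n_ref * cfg.generation_years
    m12 = p.get("m12", p.get("m", 0.0))
    m21 = p.get("m21", p.get("m", 0.0))
    # M_ij is scaled migration into pop i; migrants/generation into pop i
    # is M_ij * nu_i / 2 (dadi-style conversion)
    out["migrants_per_gen_into_1"] = m12 * p["nu1"] / 2.0
    out["migrants_per_gen_into_2"] = m21 * p["nu2"] / 2.0
    fit.converted = out
    return out


def bootstrap_ci(
    site_table: pd.DataFrame,
    spec: DemographicModelSpec,
    n: tuple,
    conversion: UnitConversionConfig,
    n_boot: int = 100,
    block_size: int = 50_000,
    scheme: str = "block",
    seed: int = 0,
    config: OptimizerConfig | None = None,
    start: dict | None = None,
) -> dict:
    """Block-bootstrap quantiles (2.5% / 97.5%) of converted parameters.

    ``site_table`` holds one row per variable site with columns
    ``position``, ``count1``, ``count2`` (folded joint minor-allele counts).
    Contiguous ``block_size``-bp blocks (or single sites with
    ``scheme='site'``) are resampled with replacement, the folded joint SFS
    rebuilt and the model refit; refits start from ``start`` (typically the
    empirical fit) with a light perturbation schedule unless ``config``
    overrides.  Failed refits are dropped and disclosed in the output.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rng = np.random.default_rng(seed)
    if scheme == "block":
        block_ids = (site_table["position"] // block_size).to_numpy()
    elif scheme == "site":
        block_ids = np.arange(len(site_table))
    else:
        raise ValueError(f"unknown bootstrap scheme: {scheme!r}")
    blocks = np.unique(block_ids)
    cfg = config or OptimizerConfig(rounds=((3, 1, 100),), seed=seed)

    count1 = site_table["count1"].to_numpy()
    count2 = site_table["count2"].to_numpy()
    estimates = []
    failures = 0
    for b in range(n_boot):
        chosen = rng.choice(blocks, size=blocks.size, replace=True)
        parts = [np.flatnonzero(block_ids == blk) for blk in chosen]
        idx = np.concatenate(parts) if parts else np.array([], dtype=int)
        data = np.zeros((n[0] + 1, n[1] + 1))
        np.add.at(data, (count1[idx], count2[idx]), 1.0)
        folded, mask = fold_sfs(data)
        obs = FoldedSFS(folded, n, mask=mask, folded=True)
        try:
            fit = fit_model(obs, spec, config=cfg, start=start)
            estimates.append(convert_units(fit, conversion))
        except Exception:
            failures += 1
    if not estimates:
        raise RuntimeError("all bootstrap refits failed")
    frame = pd.DataFrame(estimates)
    quants = {
        col: (float(np.quantile(frame[col], 0.025)),
              float(np.quantile(frame[col], 0.975)))
        for col in frame.columns
    }
    return {
        "quantiles": quants,
        "n_success": len(estimates),
        "n_failures": failures,
        "estimates": frame,
    }
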