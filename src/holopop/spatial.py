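"""Geographic distances, isolation-by-distance Mantel tests, and partial
redundancy analysis (RDA).

Distances are Vincenty inverse geodesics on the WGS84 ellipsoid.  The
Mantel test permutes matrix labels jointly and reports a one-sided p-value.
Partial RDA regresses a multivariate response on constraining predictors
after removing conditioning covariates, with permutation inference for the
whole model, each term (marginal, reduced-model residual permutation) and
each constrained axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GeoDistanceMatrix",
    "MantelResult",
    "RDADesign",
    "OrdinationResult",
    "vincenty_km",
    "geodesic_distances",
    "mantel_test",
    "partial_rda",
]

_WGS84_A = 6378137.0
_WGS84_F = 1.0 / 298.257223563


def vincenty_km(
    lat1: float, lon1: float, lat2: float, lon2: float,
    tol: float = 1e-12, max_iter: int = 200,
) -> float:
    """Geodesic distance in km between two WGS84 coordinates.

    Standard Vincenty inverse iteration; for the rare near-antipodal pairs
    where it fails to converge, falls back to the spherical great-circle
    distance on the mean-radius sphere (documented, ~0.5% worst-case error).
    """
    if not (-90 <= lat1 <= 90 and -90 <= lat2 <= 90):
        raise ValueError("latitude out of range [-90, 90]")
    if not (-180 <= lon1 <= 180 and -180 <= lon2 <= 180):
        raise ValueError("longitude out of range [-180, 180]")
    if lat1 == lat2 and lon1 == lon2:
        return 0.0
    a = _WGS84_A
    f = _WGS84_F
    b = (1.0 - f) * a
    u1 = np.arctan((1.0 - f) * np.tan(np.radians(lat1)))
    u2 = np.arctan((1.0 - f) * np.tan(np.radians(lat2)))
    L = np.radians(lon2 - lon1)
    sin_u1, cos_u1 = np.sin(u1), np.cos(u1)
    sin_u2, cos_u2 = np.sin(u2), np.cos(u2)

    lam = L
    for _ in range(max_iter):
        sin_lam, cos_lam = np.sin(lam), np.cos(lam)
        sin_sigma = np.sqrt(
            (cos_u2 * sin_lam) ** 2
            + (cos_u1 * sin_u2 - sin_u1 * cos_u2 * cos_lam) ** 2
        )
        if sin_sigma == 0:
            return 0.0
        cos_sigma = sin_u1 * sin_u2 + cos_u1 * cos_u2 * cos_lam
        sigma = np.arctan2(sin_sigma, cos_sigma)
        sin_alpha = cos_u1 * cos_u2 * sin_lam / sin_sigma
        cos2_alpha = 1.0 - sin_alpha**2
        if cos2_alpha == 0:  # equatorial line
            cos_2sm = 0.0
        else:
            cos_2sm = cos_sigma - 2.0 * sin_u1 * sin_u2 / cos2_alpha
        C = f / 16.0 * cos2_alpha * (4.0 + f * (4.0 - 3.0 * cos2_alpha))
        lam_prev = lam
        lam = L + (1.0 - C) * f * sin_alpha * (
            sigma
            + C * sin_sigma * (cos_2sm + C * cos_sigma * (-1.0 + 2.0 * cos_2sm**2))
        )
        if abs(lam - lam_prev) < tol:
            break
    else:
        # antipodal-safe fallback: spherical law of cosines on mean radius
        r_mean = (2.0 * a + b) / 3.0
        p1, p2 = np.radians(lat1), np.radians(lat2)
        central = np.arccos(
            np.clip(
                np.sin(p1) * np.sin(p2)
                + np.cos(p1) * np.cos(p2) * np.cos(L),
                -1.0, 1.0,
            )
        )
        return float(r_mean * central / 1000.0)

    u_sq = cos2_alpha * (a**2 - b**2) / b**2
    A = 1.0 + u_sq / 16384.0 * (
        4096.0 + u_sq * (-768.0 + u_sq * (320.0 - 175.0 * u_sq))
    )
    B = u_sq / 1024.0 * (256.0 + u_sq * (-128.0 + u_sq * (74.0 - 47.0 * u_sq)))
    delta_sigma = (
        B
        * sin_sigma
        * (
            cos_2sm
            + B
            / 4.0
            * (
                cos_sigma * (-1.0 + 2.0 * cos_2sm**2)
                - B
                / 6.0
                * cos_2sm
                * (-3.0 + 4.0 * sin_sigma**2)
                * (-3.0 + 4.0 * cos_2sm**2)
            )
        )
    )
    return float(b * A * (sigma - delta_sigma) / 1000.0)


@dataclass
class GeoDistanceMatrix:
    dist_km: np.ndarray
    labels: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dist_km, index=self.labels, columns=self.labels)


def geodesic_distances(coords: pd.DataFrame) -> GeoDistanceMatrix:
    """Pairwise geodesic distances (km) from a frame with columns
    'latitude' and 'longitude', indexed (or labelled by a column) 'reef'."""
    labels = (
        coords["reef"].astype(str).tolist()
        if "reef" in coords.columns
        else [str(i) for i in coords.index]
    )
    lat = coords["latitude"].to_numpy(float)
    lon = coords["longitude"].to_numpy(float)
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = vincenty_km(lat[i], lon[i], lat[j], lon[j])
    return GeoDistanceMatrix(dist_km=d, labels=labels)


@dataclass
class MantelResult:
    r: float
    p_value: float
    n_perm: int


def mantel_test(
    gen_d: np.ndarray,
    geo_d: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    alternative: str = "greater",
) -> MantelResult:
    """Mantel correlation between two distance matrices with permutation p.

    r is the Pearson correlation of the off-diagonal upper triangles;
    p = (1 + #{permuted r as extreme}) / (n_perm + 1), one-sided by default
    (isolation by distance predicts positive correlation).
    """
    gen_d = np.asarray(gen_d, float)
    geo_d = np.asarray(geo_d, float)
    n = gen_d.shape[0]
    if gen_d.shape != geo_d.shape or gen_d.shape[0] != gen_d.shape[1]:
        raise ValueError("matrices must be square and of equal shape")
    if n < 3:
        raise ValueError("Mantel test requires at least 3 units")
    iu = np.triu_indices(n, k=1)
    x = geo_d[iu]
    y = gen_d[iu]
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant distance matrix: Mantel r undefined")

    def corr(yv):
        return float(np.corrcoef(x, yv)[0, 1])

    r_obs = corr(y)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = gen_d[np.ix_(perm, perm)][iu]
        rp = corr(yp)
        if alternative == "greater":
            count += rp >= r_obs
        elif alternative == "less":
            count += rp <= r_obs
        else:
            count += abs(rp) >= abs(r_obs)
    return MantelResult(
        r=r_obs, p_value=(1 + count) / (n_perm + 1), n_perm=n_perm
    )


@dataclass
class RDADesign:
    """Response matrix plus constraining and conditioning variables.

    ``constraints`` is a DataFrame whose numeric columns are scaled to mean
    0 / variance 1 and whose categorical (object/category) columns are
    dummy-coded against a reference level (``references`` maps column ->
    reference level; default first level alphabetically).  ``conditioning``
    may be a DataFrame (same treatment, no scaling requirement) or None.
    """

    Y: np.ndarray
    constraints: pd.DataFrame
    conditioning: pd.DataFrame | None = None
    references: dict = field(default_factory=dict)
    scale_numeric: bool = True

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, float)
        if np.isnan(self.Y).any():
            raise ValueError("response matrix contains missing values")
        if len(self.constraints) != self.Y.shape[0]:
            raise ValueError("constraints rows must match response rows")
        if self.conditioning is not None and len(self.conditioning) != self.Y.shape[0]:
            raise ValueError("conditioning rows must match response rows")


def _encode(df: pd.DataFrame, references: dict, scale: bool):
    """Design columns grouped by term; returns (matrix, term slices)."""
    cols = []
    terms = {}
    for name in df.columns:
        col = df[name]
        if col.dtype.kind in "ifu":
            x = col.to_numpy(float)
            if scale:
                sd = x.std()
                if sd == 0:
                    raise ValueError(f"constant numeric term {name!r}")
                x = (x - x.mean()) / sd
            terms[name] = [len(cols)]
            cols.append(x)
        else:
            levels = sorted(col.astype(str).unique())
            ref = str(references.get(name, levels[0]))
            if ref not in levels:
                raise ValueError(f"reference {ref!r} not a level of {name!r}")
            idxs = []
            for lev in levels:
                if lev == ref:
                    continue
                idxs.append(len(cols))
                cols.append((col.astype(str) == lev).to_numpy(float))
            terms[name] = idxs
    if not cols:
        return np.empty((len(df), 0)), terms
    return np.column_stack(cols), terms


@dataclass
class OrdinationResult:
    eigenvalues: np.ndarray
    pct_explainable: np.ndarray
    site_scores: np.ndarray
    biplot: pd.DataFrame
    terms: pd.DataFrame
    axes: pd.DataFrame
    model_f: float
    model_p: float
    ss_total: float
    ss_conditioned: float
    ss_constrained: float
    ss_residual: float

    @property
    def constrained_fraction(self) -> float:
        return self.ss_constrained / self.ss_total


def _qr_basis(X: np.ndarray) -> np.ndarray:
    if X.shape[1] == 0:
        return np.empty((X.shape[0], 0))
    q, r = np.linalg.qr(X)
    keep = np.abs(np.diag(r)) > 1e-9 * max(1.0, np.abs(r).max())
    return q[:, keep]


def partial_rda(
    design: RDADesign, n_perm: int = 999, seed: int = 0, test_axes: bool = True
) -> OrdinationResult:
    """Partial redundancy analysis with permutation tests.

    Stages: (1) residualize response and constraints on the conditioning
    covariates (plus intercept); (2) least-squares fit of the residualized
    response on the constraints; (3) eigen-decompose the fitted values for
    the constrained axes; (4) permutation tests using the
    residuals-of-reduced-model scheme: the whole model permutes residuals
    of the conditioning-only model, each marginal term permutes residuals
    of the model with the term removed.
    """
    Y = design.Y
    n = Y.shape[0]
    X, term_cols = _encode(
        design.constraints, design.references, design.scale_numeric
    )
    if design.conditioning is not None:
        Z, _ = _encode(design.conditioning, {}, scale=False)
    else:
        Z = np.empty((n, 0))
    Z = np.column_stack([np.ones(n), Z])
    Qz = _qr_basis(Z)  # collinear conditioning columns drop out of the basis

    # intra-constraint aliasing is an input error (name the term); columns
    # absorbed by the conditioning covariates are legitimate and simply
    # contribute no constrained variance
    if X.shape[1]:
        x_centered = X - X.mean(axis=0)
        if _qr_basis(x_centered).shape[1] < X.shape[1]:
            for name, idxs in term_cols.items():
                sub = x_centered[:, idxs]
                others = [i for i in range(X.shape[1]) if i not in idxs]
                basis_cols = [np.ones((n, 1))]
                if others:
                    basis_cols.append(x_centered[:, others])
                Qo = _qr_basis(np.column_stack(basis_cols))
                if np.linalg.norm(sub - Qo @ (Qo.T @ sub)) < 1e-8 * max(
                    1.0, np.linalg.norm(sub)
                ):
                    raise ValueError(
                        f"constraint term {name!r} is aliased (rank deficient)"
                    )
            raise ValueError("constraint matrix is rank deficient")

    Yr = Y - Qz @ (Qz.T @ Y)
    Xr = X - Qz @ (Qz.T @ X)
    Qx = _qr_basis(Xr)
    rank_x = Qx.shape[1]

    fitted = Qx @ (Qx.T @ Yr)
    ss_total = float(((Y - Y.mean(axis=0)) ** 2).sum())
    ss_cond_resid = float((Yr**2).sum())
    ss_constrained = float((fitted**2).sum())
    ss_residual = ss_cond_resid - ss_constrained
    ss_conditioned = ss_total - ss_cond_resid

    df_resid = n - Qz.shape[1] - rank_x
    u, svals, vt = np.linalg.svd(fitted, full_matrices=False)
    eig = svals**2
    n_axes = int((eig > 1e-12 * max(eig.max(), 1.0)).sum()) if eig.size else 0
    eig = eig[:n_axes]
    pct = 100.0 * eig / eig.sum() if n_axes else np.array([])
    site_scores = u[:, :n_axes] * svals[:n_axes]

    # biplot arrows: correlations of constraint columns with axis scores
    arrows = {}
    for name, idxs in term_cols.items():
        for k, ci in enumerate(idxs):
            label = name if len(idxs) == 1 else f"{name}[{k}]"
            arrows[label] = [
                float(np.corrcoef(X[:, ci], site_scores[:, ax])[0, 1])
                if site_scores.size
                else np.nan
                for ax in range(n_axes)
            ]
    biplot = pd.DataFrame(arrows, index=[f"RDA{i+1}" for i in range(n_axes)]).T

    rng = np.random.default_rng(seed)

    def _require_orthogonal(Yp):
        # permuted rows are no longer orthogonal to the conditioning space;
        # re-residualize so permuted and observed statistics are comparable
        return Yp - Qz @ (Qz.T @ Yp)

    if rank_x == 0:
        model_f = np.nan
        n_perm = 0
    else:
        model_f = (ss_constrained / rank_x) / (ss_residual / df_resid)
    count = 0
    for _ in range(n_perm):
        Yp = _require_orthogonal(Yr[rng.permutation(n)])
        fit_p = Qx @ (Qx.T @ Yp)
        ssc = float((fit_p**2).sum())
        ssr = float((Yp**2).sum()) - ssc
        fp = (ssc / rank_x) / (ssr / df_resid)
        count += fp >= model_f
    model_p = (1 + count) / (n_perm + 1)

    # marginal term tests, residuals-of-reduced-model permutation
    term_rows = []
    for name, idxs in term_cols.items():
        others = [i for i in range(X.shape[1]) if i not in idxs]
        Q_red = _qr_basis(Xr[:, others]) if others else np.empty((n, 0))
        fit_red = Q_red @ (Q_red.T @ Yr) if Q_red.size else np.zeros_like(Yr)
        ss_red = float((fit_red**2).sum())
        ss_term = ss_constrained - ss_red
        df_term = rank_x - Q_red.shape[1]
        if df_term == 0:  # term fully absorbed by conditioning
            term_rows.append(
                dict(term=name, df=0, ss=0.0, variance_fraction=0.0,
                     F=np.nan, p_value=np.nan)
            )
            continue
        f_term = (ss_term / df_term) / (ss_residual / df_resid)
        resid_red = Yr - fit_red
        count = 0
        for _ in range(n_perm):
            Yp = fit_red + _require_orthogonal(resid_red[rng.permutation(n)])
            full = Qx @ (Qx.T @ Yp)
            red = Q_red @ (Q_red.T @ Yp) if Q_red.size else 0.0
            ssc_f = float((full**2).sum())
            ssc_r = float((red**2).sum()) if np.ndim(red) else 0.0
            ssr_p = float((Yp**2).sum()) - ssc_f
            fp = ((ssc_f - ssc_r) / df_term) / (ssr_p / df_resid)
            count += fp >= f_term
        term_rows.append(
            dict(term=name, df=df_term, ss=ss_term,
                 variance_fraction=ss_term / ss_total, F=f_term,
                 p_value=(1 + count) / (n_perm + 1))
        )
    terms = pd.DataFrame(term_rows)

    # per-axis tests: F_k = eig_k / (SS_resid / df_resid), permuting Yr
    axis_rows = []
    for k in range(n_axes if test_axes else 0):
        f_axis = eig[k] / (ss_residual / df_resid)
        count = 0
        for _ in range(n_perm):
            Yp = _require_orthogonal(Yr[rng.permutation(n)])
            fit_p = Qx @ (Qx.T @ Yp)
            sv = np.linalg.svd(fit_p, compute_uv=False)
            ssr_p = float((Yp**2).sum() - (sv**2).sum())
            fp = (sv[k] ** 2 if k < sv.size else 0.0) / (ssr_p / df_resid)
            count += fp >= f_axis
        axis_rows.append(
            dict(axis=f"RDA{k+1}", eigenvalue=eig[k],
                 pct_explainable=pct[k], F=f_axis,
                 p_value=(1 + count) / (n_perm + 1))
        )
    axes = pd.DataFrame(axis_rows)

    return OrdinationResult(
        eigenvalues=eig, pct_explainable=pct, site_scores=site_scores,
        biplot=biplot, terms=terms, axes=axes, model_f=model_f,
        model_p=model_p, ss_total=ss_total, ss_conditioned=ss_conditioned,
        ss_constrained=ss_constrained, ss_residual=ss_residual,
    )
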