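"""Two-population diffusion solver for expected site-frequency spectra.

Solves the neutral Wright-Fisher diffusion forward in time on a frequency
grid: an ancestral population at the standard neutral equilibrium splits
into two populations of relative sizes nu1, nu2 that may exchange migrants.
Time is in units of 2 N_ref generations, migration rates are M = 2 N_ref m,
and the mutation influx is theta0 = 4 N_ref mu L (computed at theta0 = 1 and
scaled linearly afterwards).

The PDE per population-frequency coordinate x is

    dphi/dt = 1/2 d^2/dx^2 [ x (1 - x) phi / (2 nu) ] - d/dx [ M (y - x) phi ]

discretized in flux form on a non-uniform grid concentrated near the
boundaries, integrated by operator splitting with implicit (backward Euler)
steps in each coordinate, with absorbing boundary terms at fixation/loss and
continuous injection of new mutations at the lowest interior frequency.
Spectra are obtained by integrating binomial sampling kernels against phi.
"""

from __future__ import annotations



import numpy as np
from scipy.special import gammaln

__all__ = ["make_grid", "equilibrium_phi", "split_phi", "integrate_two_pops",
           "sample_sfs_2d", "expected_sfs_2d"]


def make_grid(
    pts: int, crwd: float = 8.0, n_ref: int = 0, y_min: float = 1e-8
) -> np.ndarray:
    """Frequency grid on [0, 1] exponentially concentrated at the ends.

    ``n_ref`` > 0 additionally subdivides the first and last cells
    geometrically down to ``y_min``.  Migration advection against the
    drift-degenerate boundaries creates density layers ~ y^(2 M nu - 1)
    whose exponent can be arbitrarily close to -1; the sampled spectrum is
    insensitive to frequencies far below 1/n, but the layer profile between
    y_min and the first regular grid point must be resolved for the
    low-count spectrum cells to come out right.
    """
    unif = np.linspace(-0.5, 0.5, pts)
    grid = 1.0 / (1.0 + np.exp(-crwd * unif))
    grid = (grid - grid[0]) / (grid[-1] - grid[0])
    if n_ref > 0:
        lo = np.geomspace(y_min, grid[1], n_ref, endpoint=False)
        hi = 1.0 - np.geomspace(y_min, 1.0 - grid[-2], n_ref, endpoint=False)[::-1]
        grid = np.unique(np.concatenate([[0.0], lo, grid[1:-1], hi, [1.0]]))
    return grid


def equilibrium_phi(xx: np.ndarray, theta0: float = 1.0) -> np.ndarray:
    """Standard neutral equilibrium density phi(x) = theta0 / x."""
    phi = np.empty_like(xx)
    phi[1:] = theta0 / xx[1:]
    phi[0] = phi[1]
    return phi


def split_phi(phi1: np.ndarray, xx: np.ndarray) -> np.ndarray:
    """Duplicate a 1D density onto the diagonal of the 2D grid (a split:
    both daughter populations inherit the ancestral frequency)."""
    G = xx.size
    phi = np.zeros((G, G))
    for i in range(G):
        lo = xx[max(i - 1, 0)]
        hi = xx[min(i + 1, G - 1)]
        phi[i, i] = phi1[i] * 2.0 / (hi - lo)
    return phi


def _dfactor(xx: np.ndarray) -> np.ndarray:
    dx = np.diff(xx)
    df = np.empty_like(xx)
    df[1:-1] = 2.0 / (dx[:-1] + dx[1:])
    df[0] = 2.0 / dx[0]
    df[-1] = 2.0 / dx[-1]
    return df


def _tridiag_1d(xx: np.ndarray, nu: float, m_of_x: np.ndarray):
    """Sub/diag/super diagonals of the loss operator A (dphi/dt = -A phi)
    for one coordinate, for a vector of migration drift values M(x) at the
    grid points (one row per value of the other population's frequency).

    m_of_x has shape (rows, G): the advection coefficient M(y_r) - depends
    on x too; here it is evaluated at grid points and averaged to faces.
    """
    G = xx.size
    dx = np.diff(xx)
    df = _dfactor(xx)
    V = xx * (1.0 - xx) / nu
    x_mid = 0.5 * (xx[:-1] + xx[1:])
    V_mid = x_mid * (1.0 - x_mid) / nu
    m_face = 0.5 * (m_of_x[:, :-1] + m_of_x[:, 1:])  # (rows, G-1)

    # Exponential fitting in u = V phi: the face flux F = (M/V) u - u'/2,
    # solved exactly per face for constant flux, gives the two-point form
    #   F = (c_eff/2) (u_j e^{s} - u_{j+1}) / (e^{s} - 1)
    # with s = int_face 2 M / V dx = 2 M nu [logit(x_{j+1}) - logit(x_j)].
    # This resolves the steep boundary layers that migration advection builds
    # against the drift-degenerate boundaries (density ~ y^{2 M nu - 1}),
    # which a central flux cannot represent on a coarse grid.  The two
    # extreme faces (where the logit diverges) use the face-midpoint
    # coefficient; the boundary atoms are handled separately below.
    logit = np.empty(G)
    logit[1:-1] = np.log(xx[1:-1] / (1.0 - xx[1:-1]))
    logit[0], logit[-1] = -np.inf, np.inf
    s = np.empty_like(m_face)
    s[:, 1:-1] = 2.0 * m_face[:, 1:-1] * nu * (logit[2:-1] - logit[1:-2])
    s[:, 0] = 2.0 * m_face[:, 0] / V_mid[0] * dx[0]
    s[:, -1] = 2.0 * m_face[:, -1] / V_mid[-1] * dx[-1]
    with np.errstate(over="ignore"):
        em = np.expm1(-s)
        ep = np.expm1(s)
    small = np.abs(s) < 1e-8
    with np.errstate(invalid="ignore", divide="ignore"):
        coef_j = np.where(small, 0.5 + s / 4.0, -s / (2 * em))
        coef_j1 = np.where(small, 0.5 - s / 4.0, s / (2 * ep))
    coef_j = np.nan_to_num(coef_j, posinf=0.0, neginf=0.0)
    coef_j1 = np.nan_to_num(coef_j1, posinf=0.0, neginf=0.0)
    # F_j = (1/h) [ coef_j u_j - coef_j1 u_{j+1} ]
    alpha = coef_j * V[:-1][None, :] / dx[None, :]
    beta = -coef_j1 * V[1:][None, :] / dx[None, :]
    # boundary atoms: density parked at x=0 / x=1 (V = 0) is carried back
    # into the interior purely advectively when migration pushes inward
    alpha[:, 0] += np.maximum(m_of_x[:, 0], 0.0)
    beta[:, -1] += np.minimum(m_of_x[:, -1], 0.0)

    rows = m_of_x.shape[0]
    sub = np.zeros((rows, G))
    diag = np.zeros((rows, G))
    sup = np.zeros((rows, G))
    diag[:, :-1] += df[:-1] * alpha
    sup[:, :-1] += df[:-1] * beta
    diag[:, 1:] -= df[1:] * beta
    sub[:, 1:] -= df[1:] * alpha
    # No absorbing terms at x=0 / x=1: V vanishes there, so density lost or
    # fixed in this population piles up at the boundary nodes, where it keeps
    # evolving in the other coordinate (and, under migration, can be pulled
    # back into the interior by the advection flux).  Corner mass is masked
    # at sampling time.
    return sub, diag, sup


def _thomas(sub, diag, sup, rhs):
    """Batched tridiagonal solve; all arrays (rows, G)."""
    rows, G = diag.shape
    cp = np.empty((rows, G))
    dp = np.empty((rows, G))
    cp[:, 0] = sup[:, 0] / diag[:, 0]
    dp[:, 0] = rhs[:, 0] / diag[:, 0]
    for k in range(1, G):
        m = diag[:, k] - sub[:, k] * cp[:, k - 1]
        cp[:, k] = sup[:, k] / m
        dp[:, k] = (rhs[:, k] - sub[:, k] * dp[:, k - 1]) / m
    x = np.empty((rows, G))
    x[:, -1] = dp[:, -1]
    for k in range(G - 2, -1, -1):
        x[:, k] = dp[:, k] - cp[:, k] * x[:, k + 1]
    return x


def integrate_two_pops(
    phi: np.ndarray,
    xx: np.ndarray,
    T: float,
    nu1: float,
    nu2: float,
    m12: float = 0.0,
    m21: float = 0.0,
    theta0: float = 1.0,
    dt0: float = 0.005,
    max_steps: int = 250,
) -> np.ndarray:
    """Integrate the 2D density forward for time T (units of 2 N_ref gen).

    The implicit scheme is unconditionally stable, so for long histories the
    step count is capped (the density approaches a quasi-equilibrium and
    coarser late-time steps cost little accuracy).
    """
    if T < 0:
        raise ValueError("integration time must be >= 0")
    if T == 0:
        return phi
    G = xx.size
    steps = min(max(int(np.ceil(T / dt0)), 1), max_steps)
    dt = T / steps

    yy = xx
    # x-direction operator: advection M12 * (y - x), one system per row y
    mx = m12 * (yy[:, None] - xx[None, :])  # (rows=y, G=x)
    sub_x, diag_x, sup_x = _tridiag_1d(xx, nu1, mx)
    my = m21 * (xx[:, None] - yy[None, :])  # (rows=x, G=y)
    sub_y, diag_y, sup_y = _tridiag_1d(yy, nu2, my)

    inv_dt = 1.0 / dt
    # the implicit systems are constant in time: invert them once and apply
    # as batched dense products (G is small, so this is fast and stable)
    inv_x = _batch_inverse(sub_x, diag_x + inv_dt, sup_x)
    inv_y = _batch_inverse(sub_y, diag_y + inv_dt, sup_y)

    # mass rate theta0 / (x1 (x2 - x0)) as in 1D, divided by the boundary
    # node's half-width trapezoid cell dy0 / 2 to convert to a 2D density
    inj10 = theta0 / xx[1] / ((xx[2] - xx[0]) * 0.5 * (yy[1] - yy[0]))
    inj01 = theta0 / yy[1] / ((yy[2] - yy[0]) * 0.5 * (xx[1] - xx[0]))

    for _ in range(steps):
        phi[1, 0] += dt * inj10
        phi[0, 1] += dt * inj01
        # implicit step along x: phi rows indexed by y -> transpose so each
        # system's unknowns run along x for a fixed y
        phi = np.einsum("rij,rj->ri", inv_x, phi.T * inv_dt).T
        phi = np.einsum("rij,rj->ri", inv_y, phi * inv_dt)
    return phi


def _batch_inverse(sub, diag, sup):
    rows, G = diag.shape
    A = np.zeros((rows, G, G))
    idx = np.arange(G)
    A[:, idx, idx] = diag
    A[:, idx[1:], idx[:-1]] = sub[:, 1:]
    A[:, idx[:-1], idx[1:]] = sup[:, :-1]
    return np.linalg.inv(A)


def _binom_weights_xx(n: int, xx: np.ndarray) -> np.ndarray:
    pts = xx.size
    i = np.arange(n + 1)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        logb = (
            gammaln(n + 1)
            - gammaln(i + 1)
            - gammaln(n - i + 1)
            + i * np.log(xx[None, :])
            + (n - i) * np.log(1.0 - xx[None, :])
        )
    B = np.exp(logb)
    B[np.isnan(B)] = 0.0
    B[0, 0] = 1.0
    B[n, -1] = 1.0
    # trapezoid weights for the non-uniform grid
    dx = np.diff(xx)
    w = np.empty(pts)
    w[0] = dx[0] / 2
    w[-1] = dx[-1] / 2
    w[1:-1] = (dx[:-1] + dx[1:]) / 2
    return B * w[None, :]


def sample_sfs_2d(
    phi: np.ndarray, xx: np.ndarray, n1: int, n2: int
) -> np.ndarray:
    """Binomially sample the density into an (n1+1) x (n2+1) spectrum."""
    B1 = _binom_weights_xx(n1, xx)
    B2 = _binom_weights_xx(n2, xx)
    return B1 @ phi @ B2.T


def expected_sfs_2d(
    n1: int,
    n2: int,
    nu1: float,
    nu2: float,
    T: float,
    m12: float = 0.0,
    m21: float = 0.0,
    T_iso: float = 0.0,
    pts: int = 60,
    crwd: float = 8.0,
    n_ref: int = 16,
    y_min: float = 1e-8,
    dt0: float = 0.005,
) -> np.ndarray:
    """Unfolded expected joint SFS at theta0 = 1.

    The ancestral population sits at the standard neutral equilibrium, splits
    T (+ T_iso) time units ago, evolves in strict isolation for ``T_iso``
    units and then with migration (m12, m21) for ``T`` units.  A plain
    isolation-with-migration history is T_iso = 0; a divergence-only history
    additionally has m12 = m21 = 0; a secondary-contact history has
    T_iso > 0 with migration switched on only in the final ``T`` units.
    """
    xx = make_grid(pts, crwd, n_ref=n_ref, y_min=y_min)
    phi1 = equilibrium_phi(xx)
    phi = split_phi(phi1, xx)
    if T_iso > 0:
        phi = integrate_two_pops(phi, xx, T_iso, nu1, nu2, 0.0, 0.0, dt0=dt0)
    phi = integrate_two_pops(phi, xx, T, nu1, nu2, m12, m21, dt0=dt0)
    return sample_sfs_2d(phi, xx, n1, n2)
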