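"""One-dimensional multifractal hydrodynamics: the Gaussian packet solution.

The multifractal hydrodynamic system for the differentiable velocity V_D and
states density rho,

    dV_D/dt + V_D dV_D/dx = -dQ/dx,      Q = -(sigma**2/2) (sqrt rho)_xx / sqrt rho
    drho/dt + d(rho V_D)/dx = 0,

admits, for a free Gaussian packet of initial width alpha moving at V0, the
closed-form solution (s2 = alpha**2 + (sigma/alpha)**2 t**2):

    V_D  = (V0 alpha**2 + (sigma/alpha)**2 x t) / s2
    rho  = pi**(-1/2) s2**(-1/2) exp(-(x - V0 t)**2 / s2)
    V_F  = sigma (x - V0 t) / s2            (the fractal-scale velocity)

The quantum-like potential prefactor sigma**2/2 is the unique one under
which the packet above is an exact solution (it corresponds to the
scale-relativity diffusion coefficient D = sigma/2; the mono-fractal limit
f_alpha = 2 identifies sigma with twice Nottale's D).  This is verified
numerically by :func:`hydro_residuals` and symbolically in the test suite.

Nondimensional form (xi = x/(V0 tau0), eta = t/tau0, mu = sigma tau0/alpha**2,
phi = alpha/(V0 tau0)):

    V = (1 + mu**2 xi eta) / (1 + mu**2 eta**2),
    U = mu (xi - eta) / (1 + mu**2 eta**2),
    U/V = mu (xi - eta) / (1 + mu**2 xi eta)     (homographic in eta).

The U/V ratio being a Moebius map of eta is the synchronization mechanism:
on loci where U/V is constant the two scale resolutions lock together and
the dynamics reduce to the diffusion problem handled by
:mod:`mfrelease.mf_release`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DomainError, FitError, PoleWarning

__all__ = [
    "PacketParams", "NondimParams", "HydroField",
    "velocity_differentiable", "density", "velocity_fractal",
    "nondimensionalize", "velocity_dimensionless", "fractal_velocity_dimensionless",
    "density_dimensionless", "velocity_ratio", "synchronization_locus",
    "check_homographic", "HomographyFit", "specific_potential",
    "evaluate_field", "hydro_residuals",
]

#: quantum-potential prefactor: Q = -QPOT_COEF * sigma**2 * (sqrt rho)'' / sqrt rho
QPOT_COEF = 0.5


@dataclass(frozen=True)
class PacketParams:
    """Gaussian packet: initial velocity v0, width alpha, multifractal degree sigma."""

    v0: float
    alpha: float
    sigma: float

    def __post_init__(self):
        if self.alpha <= 0:
            raise DomainError("alpha must be positive")
        if self.sigma < 0:
            raise DomainError("sigma must be non-negative")

    def width_sq(self, t):
        """s2(t) = alpha**2 + (sigma/alpha)**2 t**2, the squared packet scale."""
        return self.alpha**2 + (self.sigma / self.alpha) ** 2 * np.asarray(t, float) ** 2


@dataclass(frozen=True)
class NondimParams:
    """Dimensionless groups of the packet for a chosen specific time tau0."""

    mu: float
    phi: float
    tau0: float

    def __post_init__(self):
        if self.mu < 0 or self.phi <= 0 or self.tau0 <= 0:
            raise DomainError("require mu >= 0, phi > 0, tau0 > 0")


def _check_t(t):
    t = np.asarray(t, float)
    if np.any(t < 0):
        raise DomainError("t must be non-negative")
    return t


def velocity_differentiable(x, t, params: PacketParams):
    """V_D(x, t): equals v0 at t=0, along x = v0 t, and everywhere if sigma=0."""
    x = np.asarray(x, float)
    t = _check_t(t)
    s2 = params.width_sq(t)
    return (params.v0 * params.alpha**2 + (params.sigma / params.alpha) ** 2 * x * t) / s2


def density(x, t, params: PacketParams):
    """rho(x, t): unit-mass Gaussian centred on x = v0 t, spreading with t."""
    x = np.asarray(x, float)
    t = _check_t(t)
    s2 = params.width_sq(t)
    with np.errstate(under="ignore"):
        return np.pi ** (-0.5) * s2 ** (-0.5) * np.exp(-((x - params.v0 * t) ** 2) / s2)


def velocity_fractal(x, t, params: PacketParams):
    """V_F(x, t): odd in the comoving coordinate, zero at the packet centre."""
    x = np.asarray(x, float)
    t = _check_t(t)
    return params.sigma * (x - params.v0 * t) / params.width_sq(t)


# ---------------------------------------------------------------------------
# nondimensionalization
# ---------------------------------------------------------------------------

def nondimensionalize(params: PacketParams, tau0: float):
    """Return the dimensionless groups and the (x, t) -> (xi, eta) maps."""
    if params.v0 <= 0:
        raise DomainError("nondimensionalization requires v0 > 0")
    if tau0 <= 0:
        raise DomainError("tau0 must be positive")
    nd = NondimParams(mu=params.sigma * tau0 / params.alpha**2,
                      phi=params.alpha / (params.v0 * tau0), tau0=tau0)

    def to_xi_eta(x, t):
        return (np.asarray(x, float) / (params.v0 * tau0),
                np.asarray(t, float) / tau0)

    return nd, to_xi_eta


def velocity_dimensionless(xi, eta, mu):
    """V = (1 + mu^2 xi eta) / (1 + mu^2 eta^2) = V_D/V0 in (xi, eta)."""
    xi, eta = np.asarray(xi, float), np.asarray(eta, float)
    return (1 + mu**2 * xi * eta) / (1 + mu**2 * eta**2)


def fractal_velocity_dimensionless(xi, eta, mu):
    """U = mu (xi - eta) / (1 + mu^2 eta^2) = V_F/V0 in (xi, eta)."""
    xi, eta = np.asarray(xi, float), np.asarray(eta, float)
    return mu * (xi - eta) / (1 + mu**2 * eta**2)


def density_dimensionless(xi, eta, mu, phi):
    """rho_hat = sqrt(pi) alpha rho in (xi, eta)."""
    xi, eta = np.asarray(xi, float), np.asarray(eta, float)
    s2 = 1 + mu**2 * eta**2
    with np.errstate(under="ignore"):
        return s2 ** (-0.5) * np.exp(-((xi - eta) ** 2) / (phi**2 * s2))


def velocity_ratio(xi, eta, mu):
    """U/V = mu (xi - eta) / (1 + mu^2 xi eta), homographic in eta.

    At a pole of the denominator the value is NaN and a :class:`PoleWarning`
    is issued rather than raising.
    """
    xi, eta = np.asarray(xi, float), np.asarray(eta, float)
    den = 1 + mu**2 * xi * eta
    bad = np.isclose(den, 0.0, atol=1e-300)
    if np.any(bad):
        warnings.warn("velocity ratio evaluated at a pole of 1 + mu^2 xi eta",
                      PoleWarning)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = mu * (xi - eta) / den
    return np.where(bad, np.nan, out) if np.any(bad) else out


def synchronization_locus(eta, mu, ratio=-1.0):
    """xi(eta) along which U/V equals ``ratio`` (default the V = -U locus).

    Solving mu (xi - eta) = ratio (1 + mu^2 xi eta) for xi gives
    xi = (ratio + mu eta) / (mu (1 - ratio mu eta)).  Along this locus
    d(U/V)/d eta = 0 identically — the dynamical-simultaneity condition
    under which the hydrodynamic system collapses to a diffusion equation.
    """
    eta = np.asarray(eta, float)
    if mu <= 0:
        raise DomainError("mu must be positive for a synchronization locus")
    den = mu * (1 - ratio * mu * eta)
    if np.any(np.isclose(den, 0.0)):
        raise DomainError("locus passes through a pole at this eta")
    return (ratio + mu * eta) / den


@dataclass
class HomographyFit:
    """Result of fitting (a eta + b)/(c eta + d) to velocity-ratio samples."""

    a: float
    b: float
    c: float
    d: float
    max_residual: float
    degenerate: bool

    def __call__(self, eta):
        eta = np.asarray(eta, float)
        return (self.a * eta + self.b) / (self.c * eta + self.d)


def check_homographic(mu, xi, eta_grid) -> HomographyFit:
    """Certify that U/V is a Moebius function of eta at fixed xi.

    Fits (a eta + b)/(c eta + d) by the total-least-squares nullspace of
    [eta, 1, -r eta, -r] and reports the max residual on the grid; a
    residual at rounding level certifies the homographic property.  A
    constant ratio (e.g. mu = 0) leaves the homography underdetermined and
    is flagged ``degenerate``.
    """
    eta = np.asarray(eta_grid, float)
    if eta.size < 4:
        raise DomainError("need >= 4 eta grid points")
    den = 1 + mu**2 * xi * eta
    if np.any(np.isclose(den, 0.0, atol=1e-12)):
        bad = eta[np.isclose(den, 0.0, atol=1e-12)][0]
        raise DomainError(f"pole of 1 + mu^2 xi eta on the grid at eta = {bad:g}")
    r = velocity_ratio(xi, eta, mu)
    m = np.column_stack([eta, np.ones_like(eta), -r * eta, -r])
    _, s, vt = np.linalg.svd(m)
    coef = vt[-1]
    degenerate = bool(s[-2] < 1e-10 * s[0])
    a, b, c, d = (float(v) for v in coef)
    with np.errstate(divide="ignore", invalid="ignore"):
        fit = (a * eta + b) / (c * eta + d)
    max_res = float(np.max(np.abs(fit - r)))
    return HomographyFit(a, b, c, d, max_res, degenerate)


# ---------------------------------------------------------------------------
# fields, specific potential, residual verification
# ---------------------------------------------------------------------------

@dataclass
class HydroField:
    """Packet fields evaluated on a uniform (t, x) grid (rows = times)."""

    x_grid: np.ndarray
    t_grid: np.ndarray
    v_d: np.ndarray
    v_f: np.ndarray
    rho: np.ndarray
    params: PacketParams


def evaluate_field(params: PacketParams, x_grid, t_grid) -> HydroField:
    x = np.asarray(x_grid, float)
    t = np.asarray(t_grid, float)
    xx, tt = np.meshgrid(x, t)
    return HydroField(x, t,
                      velocity_differentiable(xx, tt, params),
                      velocity_fractal(xx, tt, params),
                      density(xx, tt, params), params)


def specific_potential(rho_on_grid, sigma, dx):
    """Quantum-like specific potential Q = -(sigma^2/2) (sqrt rho)'' / sqrt rho.

    Second-order central differences in the interior, second-order one-sided
    stencils at the edges; spatial axis is the last axis.  A flat density has
    Q identically zero; a Gaussian density of squared width s2 gives the
    closed form Q = (sigma^2/2) (1/s2 - (x - c)^2 / s2^2).
    """
    rho = np.asarray(rho_on_grid, float)
    if np.any(rho <= 0):
        raise DomainError("rho must be strictly positive on the grid")
    if dx <= 0:
        raise DomainError("dx must be positive")
    s = np.sqrt(rho)
    d2 = np.empty_like(s)
    d2[..., 1:-1] = (s[..., :-2] - 2 * s[..., 1:-1] + s[..., 2:]) / dx**2
    # one-sided 4-point second-derivative stencils, O(dx^2)
    d2[..., 0] = (2 * s[..., 0] - 5 * s[..., 1] + 4 * s[..., 2] - s[..., 3]) / dx**2
    d2[..., -1] = (2 * s[..., -1] - 5 * s[..., -2] + 4 * s[..., -3] - s[..., -4]) / dx**2
    return -QPOT_COEF * sigma**2 * d2 / s


def hydro_residuals(field: HydroField, rho_floor: float = 1e-3) -> dict:
    """Finite-difference residual max-norms of the momentum and continuity laws.

    Residuals are evaluated where rho exceeds ``rho_floor`` times its maximum
    (the potential term divides by sqrt(rho) and is meaningless in the far
    tails).  For the analytic packet both norms vanish at second order under
    grid refinement.
    """
    x, t = field.x_grid, field.t_grid
    if len(x) < 5 or len(t) < 5:
        raise DomainError("need >= 5 grid points per axis to differentiate")
    dx = float(x[1] - x[0])
    if not (np.allclose(np.diff(x), dx) and np.allclose(np.diff(t), t[1] - t[0])):
        raise DomainError("grids must be uniform")
    v, rho = field.v_d, field.rho

    mask = rho > rho_floor * rho.max()
    q = specific_potential(np.maximum(rho, 1e-300), field.params.sigma, dx)

    dv_dt = np.gradient(v, t, axis=0, edge_order=2)
    dv_dx = np.gradient(v, x, axis=1, edge_order=2)
    dq_dx = np.gradient(q, x, axis=1, edge_order=2)
    mom = dv_dt + v * dv_dx + dq_dx

    drho_dt = np.gradient(rho, t, axis=0, edge_order=2)
    dflux_dx = np.gradient(rho * v, x, axis=1, edge_order=2)
    cont = drho_dt + dflux_dx

    if not np.any(mask):
        raise FitError("rho below floor everywhere; enlarge the grid")
    return {
        "momentum": float(np.max(np.abs(mom[mask]))),
        "continuity": float(np.max(np.abs(cont[mask]))),
    }
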