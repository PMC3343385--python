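"""One-dimensional electric double layer at a charged planar surface.

Solves the Poisson equation with spatially varying permittivity,

    d/dx [ eps0 eps_r(x) dphi/dx ] = -rho_free(phi, E),

on a graded grid with the charged surface at ``x = 0`` (Neumann condition
``eps0 eps_r(0) phi'(0) = -sigma``) and an electroneutral bulk far away
(``phi -> 0``).  The spatial dependence of the permittivity is handled by
the standard self-consistent iteration: start from the constant bulk value,
solve the nonlinear Poisson problem, recompute ``eps_r(x)`` from the newest
potential and field via the Langevin-Bikerman constitutive relation, and
repeat until the permittivity profile stops changing.

The inner nonlinear solve is a damped Newton iteration on a finite-volume
discretization; the field magnitude entering the steric denominator ``H``
is frozen at the previous outer iterate, which makes the inner Jacobian
tridiagonal and strictly diagonally dominant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import constants as const
from .edl_core import (
    ElectrolyteModel,
    bulk_permittivity,
    free_charge_density,
    relative_permittivity,
)

__all__ = [
    "Grid1D",
    "EDLProfile",
    "ConvergenceError",
    "debye_length",
    "solve_planar",
    "surface_layer_permittivity",
]


class ConvergenceError(RuntimeError):
    """Raised when an iterative solve fails; carries the residual history."""

    def __init__(self, message: str, history=None):
        super().__init__(message)
        self.history = list(history) if history is not None else []


def debye_length(model: ElectrolyteModel, eps_r: float) -> float:
    """Debye screening length sqrt(eps0 eps_r k T / (2 n0 e0^2)) in metres.

    Raises ``ValueError`` for a salt-free model (no screening, the length
    diverges).
    """
    if eps_r < 1.0:
        raise ValueError("eps_r must be >= 1")
    if model.salt_bulk_density == 0.0:
        raise ValueError("no salt: no screening, Debye length is infinite")
    return math.sqrt(
        const.EPS0 * eps_r / (2.0 * model.salt_bulk_density * const.E0**2 * model.beta)
    )


@dataclass(frozen=True)
class Grid1D:
    """Strictly increasing node positions with ``x[0] = 0`` at the surface."""

    x: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        if x.ndim != 1 or x.size < 10:
            raise ValueError("grid needs at least 10 nodes")
        if x[0] != 0.0 or np.any(np.diff(x) <= 0):
            raise ValueError("nodes must start at 0 and increase strictly")
        object.__setattr__(self, "x", x)

    @property
    def length(self) -> float:
        return float(self.x[-1])

    @property
    def first_spacing(self) -> float:
        return float(self.x[1] - self.x[0])

    @classmethod
    def graded(
        cls, length: float, n_nodes: int = 400, first_spacing: float = 0.005e-9
    ) -> "Grid1D":
        """Geometrically graded grid: spacings h0, h0*r, ... summing to ``length``."""
        n = n_nodes - 1
        if first_spacing * n >= length:
            return cls(np.linspace(0.0, length, n_nodes))

        def total(r: float) -> float:
            return first_spacing * (r**n - 1.0) / (r - 1.0) - length

        lo, hi = 1.0 + 1e-12, 2.0
        while total(hi) < 0:
            hi *= 2.0
        from scipy.optimize import brentq

        r = brentq(total, lo, hi, xtol=1e-14)
        h = first_spacing * r ** np.arange(n)
        return cls(np.concatenate(([0.0], np.cumsum(h))))

    @classmethod
    def for_electrolyte(
        cls,
        model: ElectrolyteModel,
        n_debye_lengths: float = 15.0,
        n_nodes: int = 400,
        first_spacing: float = 0.005e-9,
    ) -> "Grid1D":
        lam = debye_length(model, bulk_permittivity(model))
        return cls.graded(n_debye_lengths * lam, n_nodes, first_spacing)


@dataclass
class EDLProfile:
    """Converged double-layer profile on a 1-D grid (all SI units)."""

    grid: Grid1D
    potential: np.ndarray  # V
    field: np.ndarray  # V/m, |dphi/dx|
    permittivity: np.ndarray  # dimensionless
    charge_density: np.ndarray  # C/m^3
    surface_charge: float  # As/m^2
    convergence: dict = field(default_factory=dict)

    def net_charge_per_area(self) -> float:
        """Integral of the space charge, C/m^2 (equals -sigma when converged)."""
        return float(np.trapezoid(self.charge_density, self.grid.x))


def _charge_and_slope(phi, E_frozen, model, steric):
    """rho(phi; E_frozen) and d rho/d phi on the nodes."""
    v = const.E0 * phi * model.beta
    n0 = model.salt_bulk_density
    if not steric:
        rho = -2.0 * const.E0 * n0 * np.sinh(v)
        drho = -2.0 * const.E0**2 * model.beta * n0 * np.cosh(v)
        return rho, drho
    n0w = model.water_bulk_density
    ns = model.lattice_site_density
    u = model.water_dipole_moment * E_frozen * model.beta
    sinhc = np.where(u < 1e-4, 1.0 + u**2 / 6.0, np.sinh(np.minimum(u, 350.0)) / np.maximum(u, 1e-300))
    H = 2.0 * n0 * np.cosh(v) + n0w * sinhc
    rho = -2.0 * const.E0 * ns * n0 * np.sinh(v) / H
    drho = (
        -2.0
        * const.E0**2
        * model.beta
        * ns
        * n0
        * (np.cosh(v) * H - 2.0 * n0 * np.sinh(v) ** 2)
        / H**2
    )
    return rho, drho


def _newton_1d(x, sigma, eps_nodes, E_frozen, model, steric, tol, max_iter):
    """Damped Newton for the finite-volume system; returns (phi, res, iters)."""
    n = x.size
    h = np.diff(x)  # h[i] = x[i+1] - x[i]
    w = np.empty(n)  # control volumes
    w[0] = h[0] / 2.0
    w[1:-1] = (h[:-1] + h[1:]) / 2.0
    w[-1] = h[-1] / 2.0
    eps_face = const.EPS0 * 0.5 * (eps_nodes[:-1] + eps_nodes[1:])
    cond = eps_face / h  # face conductances

    def residual(phi):
        rho, _ = _charge_and_slope(phi, E_frozen, model, steric)
        flux = cond * (phi[1:] - phi[:-1])  # eps0 eps phi' integrated on faces
        F = np.empty(n)
        F[0] = flux[0] + sigma + rho[0] * w[0]
        F[1:-1] = flux[1:] - flux[:-1] + rho[1:-1] * w[1:-1]
        F[-1] = phi[-1]  # Dirichlet phi = 0 in the bulk
        return F

    # residual scale: sigma plus typical flux magnitude
    scale = abs(sigma) + const.EPS0 * np.max(eps_nodes) * 1e4
    phi = np.zeros(n)
    F = residual(phi)
    for it in range(max_iter):
        rnorm = np.max(np.abs(F[:-1])) / scale
        if rnorm < tol:
            return phi, rnorm, it
        _, drho = _charge_and_slope(phi, E_frozen, model, steric)
        main = np.empty(n)
        main[0] = -cond[0] + drho[0] * w[0]
        main[1:-1] = -cond[1:] - cond[:-1] + drho[1:-1] * w[1:-1]
        main[-1] = 1.0
        upper = np.concatenate((cond[:-1], [0.0]))
        upper[-1] = 0.0
        lower = cond.copy()
        lower[-1] = 0.0
        J = sp.diags([lower, main, upper], offsets=[-1, 0, 1], format="csc")
        delta = spla.spsolve(J, -F)
        t = 1.0
        F0 = np.max(np.abs(F[:-1]))
        for _ in range(40):
            trial = phi + t * delta
            Ft = residual(trial)
            if np.max(np.abs(Ft[:-1])) < (1.0 - 1e-4 * t) * F0 or F0 == 0.0:
                phi, F = trial, Ft
                break
            t *= 0.5
        else:
            raise ConvergenceError("Newton line search stalled", [rnorm])
    raise ConvergenceError(
        f"Newton failed to reach tol={tol} in {max_iter} iterations",
        [np.max(np.abs(F[:-1])) / scale],
    )


def solve_planar(
    model: ElectrolyteModel,
    sigma: float,
    grid: Grid1D | None = None,
    *,
    permittivity: Literal["self-consistent", "fixed"] = "self-consistent",
    fixed_eps_r: float | np.ndarray | None = None,
    steric: bool = True,
    outer_tol: float = 1e-6,
    newton_tol: float = 1e-10,
    max_outer: int = 300,
    max_newton: int = 60,
    relax: float = 0.5,
) -> EDLProfile:
    """Solve the planar double layer for surface charge ``sigma`` (As/m^2).

    Parameters
    ----------
    permittivity
        ``"self-consistent"`` iterates eps_r(x) from the constitutive
        relation (the default physical mode); ``"fixed"`` freezes it at
        ``fixed_eps_r`` — a scalar, or an array of node values for a
        prescribed profile such as a step function (bulk value if None).
        Useful for validation against classical Gouy-Chapman theory and
        for planar-limit cross-checks of the curved-geometry solver.
    steric
        If False, the lattice denominator H is replaced by n_s, giving the
        classical point-ion Boltzmann charge density.

    Returns a converged :class:`EDLProfile`.  Raises ``ValueError`` for
    ``|sigma| > 1`` As/m^2 (outside the documented validity range) or an
    inadequate grid, and :class:`ConvergenceError` if iteration fails.
    """
    if abs(sigma) > 1.0:
        raise ValueError("|sigma| must be <= 1 As/m^2")
    eps_b = bulk_permittivity(model)
    lam = debye_length(model, eps_b)
    if grid is None:
        grid = Grid1D.for_electrolyte(model)
    if grid.length < 10.0 * lam - 1e-15:
        raise ValueError(
            f"grid length {grid.length:.3e} m shorter than 10 Debye lengths "
            f"({10 * lam:.3e} m)"
        )
    if grid.first_spacing > 0.01e-9 + 1e-15:
        raise ValueError("node spacing at the surface must be <= 0.01 nm")

    x = grid.x
    if permittivity == "fixed" and fixed_eps_r is not None:
        eps_nodes = np.broadcast_to(np.asarray(fixed_eps_r, dtype=float), x.shape).copy()
    else:
        eps_nodes = np.full(x.size, eps_b)
    E_frozen = np.zeros(x.size)
    phi = np.zeros(x.size)
    newton_total = 0
    eps_update = np.inf
    history = []

    for outer in range(max_outer):
        phi, res, nit = _newton_1d(
            x, sigma, eps_nodes, E_frozen, model, steric, newton_tol, max_newton
        )
        newton_total += nit
        E = np.abs(np.gradient(phi, x))
        # at the surface the Neumann condition gives the field exactly;
        # the one-sided difference would lag the steep near-surface decay
        E[0] = abs(sigma) / (const.EPS0 * eps_nodes[0])
        dphi = np.max(np.abs(E - E_frozen)) / max(np.max(np.abs(E)), 1.0)
        E_frozen = E
        if permittivity == "self-consistent":
            eps_new = np.atleast_1d(relative_permittivity(phi, E, model))
            step = relax * (eps_new - eps_nodes)
            eps_update = np.max(np.abs(step) / eps_nodes)
            eps_nodes = eps_nodes + step
        else:
            eps_update = 0.0
        history.append((eps_update, dphi))
        if eps_update < outer_tol and dphi < max(outer_tol, 1e-9):
            break
    else:
        raise ConvergenceError(
            f"permittivity iteration did not converge in {max_outer} steps",
            history,
        )

    rho = np.atleast_1d(free_charge_density(phi, E_frozen, model)) if steric else (
        _charge_and_slope(phi, E_frozen, model, False)[0]
    )
    return EDLProfile(
        grid=grid,
        potential=phi,
        field=E_frozen,
        permittivity=eps_nodes,
        charge_density=rho,
        surface_charge=sigma,
        convergence={
            "outer_iterations": outer + 1,
            "newton_iterations": newton_total,
            "final_residual": res,
            "final_permittivity_update": eps_update,
        },
    )


def surface_layer_permittivity(profile: EDLProfile, a: float) -> tuple[float, float]:
    """Permittivity at the surface and its mean over the ordered layer [0, a].

    Returns ``(at_surface, layer_average)``.  Both characterize the thin
    layer of strongly oriented water next to the charged face; either may be
    used as the step-function value ``eps_ord`` in the curved-geometry
    solver, so both are reported.
    """
    x = profile.grid.x
    if not 0.0 < a <= x[-1]:
        raise ValueError("layer thickness a must lie within the grid extent")
    at_surface = float(profile.permittivity[0])
    xs = np.linspace(0.0, a, 512)
    layer = np.interp(xs, x, profile.permittivity)
    layer_average = float(np.trapezoid(layer, xs) / a)
    return at_surface, layer_average
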