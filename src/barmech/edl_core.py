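"""Pointwise constitutive relations of the Langevin-Bikerman double layer.

The model treats the electrolyte as a lattice of ``n_s`` sites per unit
volume shared by monovalent anions, cations (bulk density ``n_0`` each) and
water dipoles (bulk density ``n_0w = n_s - 2 n_0``, dipole moment ``p_0``).
Finite molecular size enters through the common lattice, and the
orientational ordering of the water dipoles in the local field makes the
relative permittivity a function of both the electrostatic potential ``phi``
and the field magnitude ``E``:

    rho_free(phi, E) = -2 e0 n_s n_0 sinh(e0 phi beta) / H(phi, E)
    eps_r(phi, E)    = 1 + n_s n_0w p_0 F(p0 E beta) / (eps0 E H(phi, E))
    F(u) = L(u) sinh(u)/u,   L(u) = coth(u) - 1/u
    H(phi, E) = 2 n_0 cosh(e0 phi beta) + n_0w sinh(u)/u,  u = p0 E beta

All functions here are pure, vectorized over numpy arrays, and shared by the
planar and arc solvers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import constants as const

__all__ = [
    "ElectrolyteModel",
    "langevin_L",
    "dipole_factor_F",
    "h_denominator",
    "relative_permittivity",
    "free_charge_density",
    "bulk_permittivity",
]

# Below this argument sinh(u)/u is evaluated by series (pure division is
# fine but the series also covers u = 0 exactly).
SMALL_ARG_SWITCH = 1e-4

# coth(u) - 1/u cancels catastrophically for small u: at u = 1e-4 the naive
# form keeps only ~8 digits.  Below this switch a 3-term odd series is used;
# its truncation error O(u^7/4725) and the closed form's rounding error
# ~ 2 eps/u^2 both stay under 1e-12 relative at the crossover.
LANGEVIN_SWITCH = 2e-2

# Above this argument sinh/cosh overflow in double precision; ratios are
# then evaluated in the log domain.
LARGE_ARG_SWITCH = 350.0


@dataclass(frozen=True)
class ElectrolyteModel:
    """Bulk electrolyte and water-lattice description.

    Parameters
    ----------
    salt_bulk_density
        Bulk number density of each monovalent ion species, 1/m^3.
    water_bulk_density
        Bulk number density of water dipoles, 1/m^3.
    water_dipole_moment
        Dipole moment of a water molecule (or small water cluster), C m.
    temperature
        Absolute temperature, K.

    The lattice-site density ``n_s = n_0w + 2 n_0`` is always derived, never
    set directly, so the lattice bookkeeping cannot become inconsistent.
    """

    salt_bulk_density: float
    water_bulk_density: float
    water_dipole_moment: float
    temperature: float = 298.0
    lattice_site_density: float = field(init=False)
    beta: float = field(init=False)

    def __post_init__(self) -> None:
        if self.salt_bulk_density < 0:
            raise ValueError("salt_bulk_density must be >= 0")
        if self.water_bulk_density <= 0:
            raise ValueError("water_bulk_density must be > 0")
        if self.water_dipole_moment < 0:
            raise ValueError("water_dipole_moment must be >= 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        object.__setattr__(
            self,
            "lattice_site_density",
            self.water_bulk_density + 2.0 * self.salt_bulk_density,
        )
        object.__setattr__(self, "beta", 1.0 / (const.KB * self.temperature))

    @classmethod
    def from_molar(
        cls,
        salt_mol_l: float,
        water_mol_l: float = 55.0,
        dipole_debye: float = 4.79,
        temperature_K: float = 298.0,
    ) -> "ElectrolyteModel":
        """Build a model from user-facing units (mol/l, debye, K)."""
        return cls(
            salt_bulk_density=const.mol_per_l_to_number_density(salt_mol_l),
            water_bulk_density=const.mol_per_l_to_number_density(water_mol_l),
            water_dipole_moment=const.debye_to_Cm(dipole_debye),
            temperature=temperature_K,
        )


def langevin_L(x):
    """Langevin function L(x) = coth(x) - 1/x.

    Mean alignment of a freely rotating dipole in a field of ``x`` thermal
    units.  Odd in ``x``; |L| < 1.  For small |x| an odd Taylor series
    avoids the cancellation between coth and 1/x.
    """
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x) < LANGEVIN_SWITCH
    xs = x[small]
    out[small] = xs / 3.0 - xs**3 / 45.0 + 2.0 * xs**5 / 945.0
    xl = x[~small]
    out[~small] = 1.0 / np.tanh(xl) - 1.0 / xl
    return out if out.ndim else float(out)


def _sinhc(u):
    """sinh(u)/u with a series for small u (may overflow for u > ~709)."""
    u = np.asarray(u, dtype=float)
    out = np.empty_like(u)
    small = np.abs(u) < SMALL_ARG_SWITCH
    us = u[small]
    out[small] = 1.0 + us**2 / 6.0
    ul = u[~small]
    out[~small] = np.sinh(ul) / ul
    return out if out.ndim else float(out)


def _log_sinhc(u):
    """log(sinh(u)/u) for u > 0, stable against overflow."""
    u = np.asarray(u, dtype=float)
    return u + np.log1p(-np.exp(-2.0 * np.minimum(u, 700.0))) - np.log(2.0 * u)


def _log_cosh(v):
    v = np.asarray(v, dtype=float)
    a = np.abs(v)
    return a + np.log1p(np.exp(-2.0 * a)) - np.log(2.0)


def dipole_factor_F(x):
    """Orientational-ordering factor F(x) = L(x) sinh(x)/x.

    Even and positive, F(0) = 0 by the limit of its small-x form x/3;
    strictly increasing for x > 0.  For x above ~350 the product is formed
    in the log domain to avoid overflow of sinh.
    """
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    ax = np.abs(x)
    small = ax < LANGEVIN_SWITCH
    large = ax > LARGE_ARG_SWITCH
    mid = ~small & ~large
    xs = ax[small]
    # F = L(x) sinh(x)/x = x/3 + x^3/30 + x^5/840 + O(x^7)
    out[small] = xs / 3.0 + xs**3 / 30.0 + xs**5 / 840.0
    xm = ax[mid]
    out[mid] = langevin_L(xm) * np.sinh(xm) / xm
    xl = ax[large]
    out[large] = langevin_L(xl) * np.exp(_log_sinhc(xl))
    return out if out.ndim else float(out)


def h_denominator(phi, E, model: ElectrolyteModel):
    """Partition-like denominator H(phi, E) of the lattice statistics, 1/m^3.

    H = 2 n_0 cosh(e0 phi beta) + n_0w sinh(u)/u with u = p0 E beta.
    At phi = 0, E -> 0 it equals the lattice-site density n_s exactly.
    """
    phi = np.asarray(phi, dtype=float)
    E = np.asarray(E, dtype=float)
    u = model.water_dipole_moment * E * model.beta
    v = const.E0 * phi * model.beta
    return 2.0 * model.salt_bulk_density * np.cosh(v) + model.water_bulk_density * _sinhc(u)


def relative_permittivity(phi, E, model: ElectrolyteModel):
    """Field- and potential-dependent relative permittivity eps_r(phi, E).

    eps_r = 1 + n_s n_0w p_0 F(u) / (eps0 E H(phi, E)),  u = p0 E beta.

    The E -> 0 limit is taken analytically (``bulk_permittivity`` gives the
    phi = 0 value); the implementation is continuous there.  Dielectric
    saturation makes eps_r non-increasing in E at fixed phi, and crowding by
    counterions (the cosh term in H) depresses it further at large |phi|.
    """
    phi = np.asarray(phi, dtype=float)
    E = np.asarray(E, dtype=float)
    phi, E = np.broadcast_arrays(phi, E)
    p0 = model.water_dipole_moment
    if p0 == 0.0:
        return np.ones_like(E) if E.ndim else 1.0

    u = p0 * E * model.beta
    v = const.E0 * phi * model.beta
    ns = model.lattice_site_density
    n0 = model.salt_bulk_density
    n0w = model.water_bulk_density
    pref = ns * n0w * p0 / const.EPS0

    out = np.empty_like(E)
    small = u < SMALL_ARG_SWITCH
    large = u > LARGE_ARG_SWITCH
    mid = ~small & ~large

    # u -> 0: F(u)/(E H) -> (p0 beta / 3) / H(phi, 0)
    h0 = 2.0 * n0 * np.cosh(v[small]) + n0w
    out[small] = 1.0 + pref * (p0 * model.beta / 3.0) / h0

    um, vm = u[mid], v[mid]
    Hm = 2.0 * n0 * np.cosh(np.minimum(vm, LARGE_ARG_SWITCH)) + n0w * _sinhc(um)
    out[mid] = 1.0 + pref * dipole_factor_F(um) / (E[mid] * Hm)

    # large u: divide numerator and denominator by sinhc(u)
    ul, vl = u[large], v[large]
    ratio = 2.0 * n0 * np.exp(_log_cosh(vl) - _log_sinhc(ul)) + n0w
    out[large] = 1.0 + pref * langevin_L(ul) / (E[large] * ratio)
    return out if out.ndim else float(out)


def free_charge_density(phi, E, model: ElectrolyteModel):
    """Net ionic charge density rho_free(phi, E) in C/m^3.

    rho_free = -2 e0 n_s n_0 sinh(e0 phi beta) / H(phi, E).

    Odd in phi, opposite in sign to phi, and bounded in magnitude by
    e0 n_s: the shared lattice saturates the counterion density (Bikerman
    steric limit).
    """
    phi = np.asarray(phi, dtype=float)
    E = np.asarray(E, dtype=float)
    phi, E = np.broadcast_arrays(phi, E)
    u = model.water_dipole_moment * E * model.beta
    v = const.E0 * phi * model.beta
    ns = model.lattice_site_density
    n0 = model.salt_bulk_density
    n0w = model.water_bulk_density

    out = np.empty_like(phi)
    big = (np.abs(v) > LARGE_ARG_SWITCH) | (u > LARGE_ARG_SWITCH)
    vb, ub = v[big], u[big]
    # divide through by cosh(v): tanh stays bounded, sinhc/cosh via logs
    rb = np.exp(np.where(ub > 0, _log_sinhc(np.maximum(ub, 1e-300)), 0.0) - _log_cosh(vb))
    rb = np.where(ub == 0.0, np.exp(-_log_cosh(vb)), rb)
    out[big] = -2.0 * const.E0 * ns * n0 * np.tanh(vb) / (2.0 * n0 + n0w * rb)
    vs, us = v[~big], u[~big]
    H = 2.0 * n0 * np.cosh(vs) + n0w * _sinhc(us)
    out[~big] = -2.0 * const.E0 * ns * n0 * np.sinh(vs) / H
    return out if out.ndim else float(out)


def bulk_permittivity(model: ElectrolyteModel) -> float:
    """Zero-field, zero-potential limit of the relative permittivity.

    eps_b = 1 + n_0w p_0^2 beta / (3 eps0).

    In the limit H -> n_s, which cancels the n_s prefactor of the
    permittivity expression, and F(u)/E -> p0 beta / 3.
    """
    return 1.0 + (
        model.water_bulk_density
        * model.water_dipole_moment**2
        * model.beta
        / (3.0 * const.EPS0)
    )
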