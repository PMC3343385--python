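"""Orientation-dependent bending energetics of rod-like membrane inclusions.

A BAR-type protein is modelled as an elastic rod of length ``L0``, flexural
rigidity ``K_p`` and intrinsic (preferred) curvature ``C_p`` lying on a
membrane surface with principal curvatures ``C1, C2``.  At in-plane
orientation ``omega`` (angle between the rod's normal plane and the first
principal direction) the rod senses the normal curvature

    C(omega) = H + D cos(2 omega),
    H = (C1 + C2)/2,  D = |C1 - C2|/2,

and stores the bending energy E_p = (K_p L0 / 2) (C - C_p)^2.  The bilayer
itself is described by a Helfrich energy extended with a deviatoric
(orientational-ordering) term for anisotropic lipids:

    W_b = (k_c/2) Int (2H)^2 dA + k_G Int C1 C2 dA
          - 2 m0 kT Int ln(2 cosh(l^2 D_eff D)) dA,

where ``l^2`` is an explicit coupling area making the cosh argument
dimensionless (the product D_eff * D carries units of 1/m^2).

Rigid rods instead force the membrane tube to adapt: a tube wrapped by
rods at orientation omega has principal curvature C1 = C_p / cos^2(omega).

Energies are in joules throughout; ``kT(T)`` converts to thermal units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from . import constants as const

__all__ = [
    "RodProtein",
    "MembranePatch",
    "MembraneMaterial",
    "ParametricShape",
    "kT",
    "curvature_seen",
    "protein_energy",
    "protein_energy_orient",
    "optimal_orientation",
    "rigid_tube_c1",
    "membrane_energy",
    "equilibrium_tube_radius",
    "packing_scenarios",
]


def kT(temperature: float = 298.0) -> float:
    """Thermal energy in joules at ``temperature`` (K)."""
    return const.KB * temperature


@dataclass(frozen=True)
class RodProtein:
    """Rod-like membrane inclusion (a BAR domain in the applications here).

    ``intrinsic_curvature`` C_p (1/m) is the curvature the rod prefers to
    match; ``flexural_rigidity`` K_p (J m) its stiffness per unit length of
    squared curvature deviation; ``length`` L0 (m); ``orientation`` omega
    (rad), reduced modulo pi because the energy depends on cos(2 omega).
    """

    intrinsic_curvature: float
    flexural_rigidity: float
    length: float
    orientation: float = 0.0

    def __post_init__(self) -> None:
        if self.flexural_rigidity < 0:
            raise ValueError("flexural_rigidity must be >= 0")
        if self.length <= 0:
            raise ValueError("length must be > 0")
        object.__setattr__(self, "orientation", float(self.orientation) % math.pi)


@dataclass(frozen=True)
class MembranePatch:
    """Local membrane shape given by its two principal curvatures (1/m)."""

    c1: float
    c2: float

    @property
    def mean_curvature(self) -> float:
        return 0.5 * (self.c1 + self.c2)

    @property
    def curvature_deviator(self) -> float:
        return 0.5 * abs(self.c1 - self.c2)


@dataclass(frozen=True)
class MembraneMaterial:
    """Bilayer elastic description.

    ``local_bending_constant`` k_c (J), ``gaussian_constant`` k_G (J),
    ``lipid_area_density`` m0 (1/m^2), ``effective_deviator`` D_eff (1/m),
    ``deviator_coupling_area`` l^2 (m^2, multiplies D_eff*D inside the
    cosh), ``temperature`` (K).
    """

    local_bending_constant: float
    gaussian_constant: float = 0.0
    lipid_area_density: float = 1.6e18  # ~0.6 nm^2 per lipid, two leaflets
    effective_deviator: float = 0.0
    deviator_coupling_area: float = 1.0e-18  # 1 nm^2
    temperature: float = 298.0

    def __post_init__(self) -> None:
        if self.local_bending_constant <= 0:
            raise ValueError("local_bending_constant must be > 0")
        if self.lipid_area_density <= 0:
            raise ValueError("lipid_area_density must be > 0")
        if self.deviator_coupling_area <= 0:
            raise ValueError("deviator_coupling_area must be > 0")

    @property
    def kT(self) -> float:
        return const.KB * self.temperature


@dataclass(frozen=True)
class ParametricShape:
    """Cylinder or sphere of given radius (length applies to cylinders)."""

    kind: Literal["cylinder", "sphere"]
    radius: float
    length: float | None = None

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if self.kind == "cylinder" and (self.length is None or self.length <= 0):
            raise ValueError("cylinders need a positive length")
        if self.kind not in ("cylinder", "sphere"):
            raise ValueError(f"unknown shape kind {self.kind!r}")

    @property
    def principal_curvatures(self) -> tuple[float, float]:
        if self.kind == "cylinder":
            return (1.0 / self.radius, 0.0)
        return (1.0 / self.radius, 1.0 / self.radius)

    @property
    def area(self) -> float:
        if self.kind == "cylinder":
            return 2.0 * math.pi * self.radius * self.length
        return 4.0 * math.pi * self.radius**2

    def patch(self) -> MembranePatch:
        c1, c2 = self.principal_curvatures
        return MembranePatch(c1, c2)


def curvature_seen(patch: MembranePatch, omega: float) -> float:
    """Normal curvature sensed by a rod at orientation ``omega``.

    C = H + D cos(2 omega); always within [H - D, H + D].
    """
    return patch.mean_curvature + patch.curvature_deviator * math.cos(2.0 * omega)


def protein_energy(protein: RodProtein, curvature: float) -> float:
    """Bending energy (J) of a flexible rod forced to curvature ``curvature``.

    E_p = (K_p L0 / 2) (C - C_p)^2 — nonnegative, zero iff C = C_p.
    """
    dc = curvature - protein.intrinsic_curvature
    return 0.5 * protein.flexural_rigidity * protein.length * dc * dc


def protein_energy_orient(protein: RodProtein, patch: MembranePatch) -> float:
    """Rod bending energy on ``patch`` at the rod's own orientation.

    E_p = (K_p L0 / 2) (H - C_p + D cos(2 omega))^2, identically equal to
    ``protein_energy(protein, curvature_seen(patch, omega))``.
    """
    return protein_energy(protein, curvature_seen(patch, protein.orientation))


def optimal_orientation(
    protein: RodProtein, patch: MembranePatch
) -> tuple[float, float]:
    """Orientation minimizing the rod energy on ``patch``.

    Returns ``(omega_star, E_min)``.  If C_p lies within the accessible
    band [H - D, H + D] the rod can match its intrinsic curvature exactly:
    cos(2 omega*) = (C_p - H)/D and E_min = 0.  Outside the band the
    minimum sits at the boundary: omega* = 0 for C_p > H + D, omega* = pi/2
    for C_p < H - D.  Of the two symmetric minima +/-omega* the smaller
    non-negative angle is returned; for D = 0 every orientation is
    equivalent and omega* = 0 by convention.
    """
    H = patch.mean_curvature
    D = patch.curvature_deviator
    cp = protein.intrinsic_curvature
    if D == 0.0:
        return 0.0, protein_energy(protein, H)
    if cp >= H + D:
        return 0.0, protein_energy(protein, H + D)
    if cp <= H - D:
        return math.pi / 2.0, protein_energy(protein, H - D)
    omega = 0.5 * math.acos((cp - H) / D)
    return omega, 0.0


def rigid_tube_c1(cp: float, omega: float) -> float:
    """Tube principal curvature forced by a rigid rod at orientation ``omega``.

    Inverts C_p = C1 cos^2(omega): C1 = C_p / cos^2(omega) >= C_p.  At
    omega = pi/4 the deviatoric contribution vanishes and C1 = 2 C_p; at
    omega -> pi/2 the rod lies along the tube axis and no longer
    constrains the tube curvature (ValueError).
    """
    if not 0.0 <= omega < math.pi / 2.0:
        raise ValueError(
            "omega must lie in [0, pi/2): at pi/2 the rod lies along the "
            "tube axis and the curvature is unconstrained"
        )
    # half-angle form: exact at the special orientations 0, pi/4, pi/3
    return cp / (0.5 * (1.0 + math.cos(2.0 * omega)))


def membrane_energy(
    shape: ParametricShape, material: MembraneMaterial
) -> dict[str, float]:
    """Closed-form bilayer energy of a cylinder or sphere, in joules.

    Returns ``{"bending", "gaussian", "deviatoric", "total"}``:

    * cylinder (C1 = 1/R, C2 = 0, H = D = 1/2R):
      bending = pi k_c L / R, gaussian = 0,
      deviatoric = -2 m0 kT ln(2 cosh(l^2 D_eff / 2R)) * 2 pi R L;
    * sphere (C1 = C2 = 1/R, D = 0): bending = 8 pi k_c (R-independent),
      gaussian = 4 pi k_G, deviatoric = -2 m0 kT ln(2) * 4 pi R^2.
    """
    A = shape.area
    p = shape.patch()
    H = p.mean_curvature
    D = p.curvature_deviator
    c1, c2 = shape.principal_curvatures
    bend = 0.5 * material.local_bending_constant * (2.0 * H) ** 2 * A
    gauss = material.gaussian_constant * c1 * c2 * A
    arg = material.deviator_coupling_area * material.effective_deviator * D
    dev = -2.0 * material.lipid_area_density * material.kT * math.log(2.0 * math.cosh(arg)) * A
    return {
        "bending": bend,
        "gaussian": gauss,
        "deviatoric": dev,
        "total": bend + gauss + dev,
    }


def _tube_energy_per_area(
    radius: float,
    material: MembraneMaterial,
    protein: RodProtein,
    coverage: float,
) -> float:
    """Total free energy per unit tube area, J/m^2, at given tube radius."""
    shape = ParametricShape("cylinder", radius, 1.0)
    mem = membrane_energy(shape, material)["total"] / shape.area
    if coverage == 0.0:
        return mem
    _, e_min = optimal_orientation(protein, shape.patch())
    return mem + coverage * e_min


def equilibrium_tube_radius(
    material: MembraneMaterial,
    protein: RodProtein,
    coverage: float,
    *,
    r_min: float = 0.5e-9,
    r_max: float = 1.0e-6,
    n_scan: int = 400,
) -> float:
    """Tube radius minimizing membrane + adsorbed-rod energy per area.

    Scans ``f(R)`` on a logarithmic grid in ``[r_min, r_max]`` and refines
    the bracketed minimum with bounded scalar minimization.  Raises
    :class:`ValueError` if no interior minimum exists in the bracket (for
    example with no proteins and no deviatoric term, where the energy
    decreases monotonically toward the flat limit); the scanned energy
    curve is attached to the exception for diagnosis.
    """
    if coverage < 0:
        raise ValueError("coverage must be >= 0")
    radii = np.geomspace(r_min, r_max, n_scan)
    f = np.array([_tube_energy_per_area(r, material, protein, coverage) for r in radii])
    i = int(np.argmin(f))
    if i == 0 or i == n_scan - 1:
        err = ValueError(
            "no interior energy minimum in the search bracket "
            f"[{r_min:.2e}, {r_max:.2e}] m"
        )
        err.energy_curve = (radii, f)  # type: ignore[attr-defined]
        raise err
    res = minimize_scalar(
        lambda r: _tube_energy_per_area(r, material, protein, coverage),
        bounds=(radii[i - 1], radii[i + 1]),
        method="bounded",
        options={"xatol": 1e-15},
    )
    return float(res.x)


def packing_scenarios(
    protein: RodProtein,
    material: MembraneMaterial,
    interaction_energy_per_contact: float,
    densities: Iterable[float],
) -> pd.DataFrame:
    """Energy comparison of stylized rod arrangements on a membrane tube.

    Three configurations are scored per area density (rods per m^2):

    * ``dispersed`` — isolated rods on the tube matching the rod's own
      curvature (R = 1/C_p), each at its optimal orientation, no contacts;
    * ``ring`` — closed rings of rods at omega = 0 on the R = 1/C_p tube,
      end-to-end contact with one neighbour pair per rod;
    * ``spiral`` — a spiral aggregate at omega = pi/4, which forces the
      tube curvature up to C1 = 2 C_p, with full (end and lateral)
      contacts, two per rod.

    The per-rod energy is the rod's bending energy plus the membrane
    energy of its share of tube area (1/density) plus contacts times
    ``interaction_energy_per_contact`` (J, negative = attractive).  Ties
    are resolved in the order dispersed, ring, spiral.  Returns one row
    per density with the three energies and the minimal configuration.
    """
    cp = protein.intrinsic_curvature
    if cp <= 0:
        raise ValueError("packing scenarios require a positive intrinsic curvature")
    scenarios = {
        "dispersed": {"omega": None, "c1": cp, "contacts": 0},
        "ring": {"omega": 0.0, "c1": rigid_tube_c1(cp, 0.0), "contacts": 1},
        "spiral": {"omega": math.pi / 4.0, "c1": rigid_tube_c1(cp, math.pi / 4.0), "contacts": 2},
    }
    rows = []
    for density in densities:
        if density < 0:
            raise ValueError("densities must be non-negative")
        row: dict[str, float | str] = {"density_per_m2": density}
        area_per_rod = np.inf if density == 0 else 1.0 / density
        for name, sc in scenarios.items():
            shape = ParametricShape("cylinder", 1.0 / sc["c1"], 1.0)
            patch = shape.patch()
            if sc["omega"] is None:
                _, e_rod = optimal_orientation(protein, patch)
            else:
                e_rod = protein_energy(protein, curvature_seen(patch, sc["omega"]))
            mem = membrane_energy(shape, material)["total"] / shape.area
            e_total = (
                e_rod
                + (0.0 if density == 0 else mem * area_per_rod)
                + sc["contacts"] * interaction_energy_per_contact
            )
            row[f"E_{name}_J"] = e_total
        order = ["dispersed", "ring", "spiral"]
        row["minimal"] = min(order, key=lambda n: (row[f"E_{n}_J"], order.index(n)))
        rows.append(row)
    return pd.DataFrame(rows)
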