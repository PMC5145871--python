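"""Closed-form electrostatics of a five-layer membrane-contact stack.

The model idealizes the contact zone between a synaptic vesicle and the
presynaptic membrane as five planar slabs stacked along the membrane
normal Z (bottom to top):

    R3   interstitial fluid          thickness H_L, density rho3
    Rm2  presynaptic membrane        thickness H_m, density rho_m2
    R2   inter-membrane cytosol      thickness D,   density rho2
    Rm1  vesicle membrane            thickness H_m, density rho_m1
    R1   vesicle lumen               thickness H_L, density rho1

Z = 0 sits at the mid-plane of R2 (the symmetry axis of the stack).
Each slab carries a uniform volume charge density (e/nm^3); membranes
are negative (anionic headgroups), aqueous regions carry the
neutralizing potassium.  For a neutral stack the densities satisfy

    rho1*H_L + rho3*H_L + rho2*D + rho_m1*H_m + rho_m2*H_m = 0.

The potential solves the 1-D Poisson equation
``d2(phi)/dZ2 = -rho(Z)/(eps_r*eps0)`` with no field outside the neutral
stack, and is reported with phi(0) = 0.  Because rho is piecewise
constant, phi is piecewise quadratic and the transmembrane voltages have
closed forms:

    dV1 = -(1/eps) * (rho_m1*H_m/2 + rho_m2*H_m + rho2*D + rho3*H_L) * H_m
    dV2 = -(1/eps) * (rho_m2*H_m/2 + rho_m1*H_m + rho2*D + rho1*H_L) * H_m

with eps = eps_r*eps0.  Both equal phi(outer face) - phi(inner face) of
the corresponding membrane; for a mirror-symmetric stack (rho1 = rho3,
rho_m1 = rho_m2 = rho_m) they collapse to

    dV = -(1/(2*eps)) * (rho_m*H_m + rho2*D) * H_m,

which is affine in the inter-membrane distance D at fixed rho2: the
voltage across each bilayer grows as the membranes approach, the driving
force for close-contact electroporation.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .constants import COULOMB_NM, DEFAULT_EPS_R
from .results import ScanResult

__all__ = [
    "LayerStack",
    "PotentialProfile",
    "ClosurePolicy",
    "NoCrossingError",
    "neutrality_residual",
    "potential_at",
    "potential_profile",
    "transmembrane_voltages",
    "stack_at_distance",
    "voltage_vs_distance",
    "critical_distance",
    "composition_to_membrane_charge",
    "DEFAULT_LIPID_CHARGES",
    "NEUTRALITY_TOL",
]

#: Surface-charge residual (e/nm^2) below which a stack counts as neutral.
NEUTRALITY_TOL = 1e-9

#: Nominal headgroup charges (e) of the supported lipid species.
DEFAULT_LIPID_CHARGES: dict[str, float] = {
    "CHOL": 0.0,
    "DOPC": 0.0,
    "POPC": 0.0,
    "POPE": 0.0,
    "POPS": -1.0,
    "PIP2": -5.0,
}


class NoCrossingError(ValueError):
    """|dV(D)| never reaches the requested voltage inside the bracket."""


class ClosurePolicy(str, enum.Enum):
    """How the aqueous charge re-neutralizes the stack when D changes.

    FIXED_RHO2
        rho2 is held fixed; rho1 = rho3 absorb the neutrality residual.
        dV is then exactly affine in D with slope -rho2*H_m/(2*eps_r*eps0).
    FIXED_COUNTER_CHARGE
        The total counterion charge per unit area is held fixed (constant
        ion number, as when two membranes approach in a closed box) and
        spread uniformly over R1, R2 and R3: rho1 = rho2 = rho3 =
        Q / (2*H_L + D).  dV(D) is then a rational function of D.
    """

    FIXED_RHO2 = "fixed_rho2"
    FIXED_COUNTER_CHARGE = "fixed_counter_charge"


@dataclass(frozen=True)
class LayerStack:
    """Parameters of the five-slab electrostatic system.

    Densities in e/nm^3, thicknesses in nm.  ``D`` is the inter-membrane
    distance (thickness of R2); ``H_L`` is shared by R1 and R3.
    """

    rho1: float = 0.0
    rho2: float = 0.0
    rho3: float = 0.0
    rho_m1: float = 0.0
    rho_m2: float = 0.0
    H_L: float = 4.0
    H_m: float = 4.0
    D: float = 3.0
    eps_r: float = DEFAULT_EPS_R

    def __post_init__(self) -> None:
        if self.H_L <= 0 or self.H_m <= 0:
            raise ValueError("layer thicknesses H_L and H_m must be positive")
        if self.D < 0:
            raise ValueError("inter-membrane distance D must be >= 0")
        if self.eps_r <= 0:
            raise ValueError("relative dielectric constant must be positive")

    # -- geometry -----------------------------------------------------
    @property
    def edges(self) -> np.ndarray:
        """Layer boundaries bottom-to-top (6 values, nm, Z=0 at R2 mid-plane)."""
        half = self.D / 2.0
        return np.array(
            [
                -half - self.H_m - self.H_L,
                -half - self.H_m,
                -half,
                half,
                half + self.H_m,
                half + self.H_m + self.H_L,
            ]
        )

    @property
    def densities(self) -> np.ndarray:
        """Charge densities per layer, bottom-to-top [R3, Rm2, R2, Rm1, R1]."""
        return np.array([self.rho3, self.rho_m2, self.rho2, self.rho_m1, self.rho1])

    @property
    def membrane1_faces(self) -> tuple[float, float]:
        """(lower, upper) faces of the vesicle membrane Rm1, nm."""
        return (self.D / 2.0, self.D / 2.0 + self.H_m)

    @property
    def membrane2_faces(self) -> tuple[float, float]:
        """(lower, upper) faces of the presynaptic membrane Rm2, nm."""
        return (-self.D / 2.0 - self.H_m, -self.D / 2.0)

    def is_neutral(self, tol: float = NEUTRALITY_TOL) -> bool:
        return abs(neutrality_residual(self)) < tol


@dataclass(frozen=True)
class PotentialProfile:
    """Electric potential phi(z) on an ordered grid, volts vs nm."""

    z: np.ndarray
    phi: np.ndarray
    reference_z: float = 0.0

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        phi = np.asarray(self.phi, dtype=float)
        if z.ndim != 1 or z.shape != phi.shape:
            raise ValueError("z and phi must be 1-D arrays of equal length")
        if not np.all(np.diff(z) > 0):
            raise ValueError("z grid must be strictly increasing")
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "phi", phi)

    def value(self, at: float | np.ndarray) -> float | np.ndarray:
        """Linearly interpolated potential; errors outside the grid."""
        at_arr = np.asarray(at, dtype=float)
        if np.any(at_arr < self.z[0] - 1e-12) or np.any(at_arr > self.z[-1] + 1e-12):
            raise ValueError("requested position outside the potential grid")
        out = np.interp(at_arr, self.z, self.phi)
        return float(out) if np.isscalar(at) else out


# ---------------------------------------------------------------------
# core operations
# ---------------------------------------------------------------------

def neutrality_residual(stack: LayerStack) -> float:
    """Net charge per unit area of the stack (e/nm^2); 0 for a neutral system."""
    return (
        stack.rho1 * stack.H_L
        + stack.rho3 * stack.H_L
        + stack.rho2 * stack.D
        + stack.rho_m1 * stack.H_m
        + stack.rho_m2 * stack.H_m
    )


def _layer_coefficients(stack: LayerStack) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-layer (phi, dphi/dz) at the lower edge plus curvature coefficient.

    Gauge: dphi/dz = 0 below the stack; phi not yet shifted to the
    reference point.
    """
    coeff = COULOMB_NM / stack.eps_r
    edges = stack.edges
    rho = stack.densities
    h = np.diff(edges)
    slopes = np.empty(6)
    phis = np.empty(6)
    slopes[0] = 0.0
    phis[0] = 0.0
    for k in range(5):
        slopes[k + 1] = slopes[k] - coeff * rho[k] * h[k]
        phis[k + 1] = phis[k] + slopes[k] * h[k] - 0.5 * coeff * rho[k] * h[k] ** 2
    return phis, slopes, rho * coeff


def potential_at(stack: LayerStack, z: float | np.ndarray) -> np.ndarray:
    """Closed-form potential (piecewise quadratic) at arbitrary z, volts.

    phi(0) = 0; no field outside the stack (constant extrapolation below,
    linear continuation above, which is constant too when the stack is
    neutral).
    """
    scalar_in = np.isscalar(z) or (isinstance(z, np.ndarray) and z.ndim == 0)
    z_arr = np.atleast_1d(np.asarray(z, dtype=float))
    edges = stack.edges
    phis, slopes, curv = _layer_coefficients(stack)

    idx = np.clip(np.searchsorted(edges, z_arr, side="right") - 1, 0, 4)
    dz = np.clip(z_arr - edges[idx], 0.0, None)
    out = phis[idx] + slopes[idx] * dz - 0.5 * curv[idx] * dz**2
    below = z_arr < edges[0]
    out[below] = phis[0]
    above = z_arr > edges[-1]
    if np.any(above):
        out[above] = phis[-1] + slopes[-1] * (z_arr[above] - edges[-1])

    # shift so that phi(0) = 0 (Z = 0 always lies in or at the edge of R2)
    k0 = 2
    dz0 = 0.0 - edges[k0]
    phi0 = phis[k0] + slopes[k0] * dz0 - 0.5 * curv[k0] * dz0**2
    out = out - phi0
    return float(out[0]) if scalar_in else out


def potential_profile(stack: LayerStack, n_points: int = 50) -> PotentialProfile:
    """Sample the closed-form potential on ``n_points`` per layer.

    Grid nodes include every layer interface and Z = 0; the profile is
    exact at the nodes (no quadrature involved).
    """
    if n_points < 5:
        raise ValueError("need at least 5 points per layer")
    edges = stack.edges
    pieces = [
        np.linspace(edges[k], edges[k + 1], n_points) for k in range(5) if edges[k + 1] > edges[k]
    ]
    z = np.unique(np.concatenate(pieces + [np.array([0.0])]))
    return PotentialProfile(z=z, phi=potential_at(stack, z), reference_z=0.0)


def transmembrane_voltages(stack: LayerStack) -> tuple[float, float]:
    """Closed-form transmembrane voltages (dV1 vesicle, dV2 presynaptic), volts.

    Sign convention: dV_k = phi(outer face) - phi(inner/R2-side face) of
    membrane k, matching the closed-form algebra above.  Assumes a
    neutral stack; a warning (not an error) is raised otherwise since the
    closed forms then no longer equal the profile read-off.
    """
    residual = neutrality_residual(stack)
    if abs(residual) > NEUTRALITY_TOL:
        warnings.warn(
            f"stack is not neutral (residual {residual:.3g} e/nm^2); "
            "closed-form voltages assume neutrality",
            stacklevel=2,
        )
    coeff = COULOMB_NM / stack.eps_r
    dv1 = -coeff * (
        0.5 * stack.rho_m1 * stack.H_m
        + stack.rho_m2 * stack.H_m
        + stack.rho2 * stack.D
        + stack.rho3 * stack.H_L
    ) * stack.H_m
    dv2 = -coeff * (
        0.5 * stack.rho_m2 * stack.H_m
        + stack.rho_m1 * stack.H_m
        + stack.rho2 * stack.D
        + stack.rho1 * stack.H_L
    ) * stack.H_m
    return (dv1, dv2)


# ---------------------------------------------------------------------
# distance scans and inversion
# ---------------------------------------------------------------------

def stack_at_distance(
    template: LayerStack, D: float, policy: ClosurePolicy = ClosurePolicy.FIXED_COUNTER_CHARGE
) -> LayerStack:
    """Re-neutralized copy of ``template`` at inter-membrane distance ``D``."""
    if D < 0:
        raise ValueError("inter-membrane distance D must be >= 0")
    policy = ClosurePolicy(policy)
    sigma_m = (template.rho_m1 + template.rho_m2) * template.H_m
    if policy is ClosurePolicy.FIXED_RHO2:
        rho_aq = -(template.rho2 * D + sigma_m) / (2.0 * template.H_L)
        return replace(template, D=D, rho1=rho_aq, rho3=rho_aq)
    q_total = (
        template.rho1 * template.H_L
        + template.rho3 * template.H_L
        + template.rho2 * template.D
    )
    rho = q_total / (2.0 * template.H_L + D)
    return replace(template, D=D, rho1=rho, rho2=rho, rho3=rho)


def voltage_vs_distance(
    template: LayerStack,
    d_values: Sequence[float],
    policy: ClosurePolicy = ClosurePolicy.FIXED_COUNTER_CHARGE,
) -> ScanResult:
    """Tabulate (D, dV1, dV2) over a distance grid under a closure policy."""
    d_values = list(d_values)
    if not d_values:
        raise ValueError("d_values must be non-empty")
    if any(d < 0 for d in d_values):
        raise ValueError("all distances must be >= 0")
    policy = ClosurePolicy(policy)
    rows = []
    for d in d_values:
        dv1, dv2 = transmembrane_voltages(stack_at_distance(template, d, policy))
        rows.append({"D_nm": d, "dV1_V": dv1, "dV2_V": dv2})
    import pandas as pd

    return ScanResult(
        table=pd.DataFrame(rows),
        metadata={
            "policy": policy.value,
            "eps_r": template.eps_r,
            "H_m_nm": template.H_m,
            "H_L_nm": template.H_L,
            "units": "D nm; dV V",
        },
    )


def _dv_at(template: LayerStack, D: float, policy: ClosurePolicy) -> float:
    return transmembrane_voltages(stack_at_distance(template, D, policy))[0]


def critical_distance(
    template: LayerStack,
    dv_critical: float,
    policy: ClosurePolicy = ClosurePolicy.FIXED_COUNTER_CHARGE,
    bracket: tuple[float, float] = (0.5, 10.0),
    xtol: float = 1e-9,
) -> float:
    """Distance D at which |dV(D)| equals the critical poration voltage.

    |dV| grows as the membranes approach along the physical branch, so
    the returned root is the one where |dV(D)| crosses ``dv_critical``
    downward with increasing D: pores form for every D at or below it.
    (|dV(D)| can also grow again at large separations under the
    fixed-counter-charge closure — the voltage changes sign where the
    inter-membrane ion charge balances the membrane charge — and such
    upward crossings are not critical distances.)

    Policy (i) is inverted in closed form (dV affine in D); policy (ii)
    by bracketed root finding to ``xtol``.

    Raises :class:`NoCrossingError` when |dV| has no downward crossing
    of ``dv_critical`` inside the bracket.
    """
    if dv_critical <= 0:
        raise ValueError("dv_critical must be positive")
    policy = ClosurePolicy(policy)
    lo, hi = bracket
    if not 0 <= lo < hi:
        raise ValueError("invalid bracket")

    if policy is ClosurePolicy.FIXED_RHO2:
        # dV(D) = a + b*D exactly under this closure
        a = _dv_at(template, 0.0, policy)
        b = _dv_at(template, 1.0, policy) - a
        candidates = []
        if b != 0.0:
            for target in (dv_critical, -dv_critical):
                d = (target - a) / b
                # keep downward crossings of |dV|: d|dV|/dD < 0 there
                if lo - xtol <= d <= hi + xtol and (a + b * d) * b < 0:
                    candidates.append(d)
        if not candidates:
            raise NoCrossingError(
                f"|dV(D)| has no downward crossing of {dv_critical} V for D in {bracket}"
            )
        return max(candidates)

    from scipy.optimize import brentq

    def gap(d: float) -> float:
        return abs(_dv_at(template, d, policy)) - dv_critical

    grid = np.linspace(lo, hi, 1025)
    values = np.array([gap(d) for d in grid])
    roots = []
    for i in range(len(grid) - 1):
        if values[i] == 0.0:
            roots.append((grid[i], values[i + 1] < values[i]))
        elif values[i] * values[i + 1] < 0:
            r = float(brentq(gap, grid[i], grid[i + 1], xtol=xtol))
            roots.append((r, values[i + 1] < values[i]))
    if values[-1] == 0.0:
        roots.append((grid[-1], values[-1] < values[-2]))
    downward = [r for r, down in roots if down]
    if not downward:
        raise NoCrossingError(
            f"|dV(D)| has no downward crossing of {dv_critical} V for D in {bracket}"
        )
    return max(downward)


# ---------------------------------------------------------------------
# composition -> membrane charge
# ---------------------------------------------------------------------

def composition_to_membrane_charge(
    species_fractions: Mapping[str, float],
    species_charges: Mapping[str, float] | None = None,
    area_per_lipid: float = 0.65,
    H_m: float = 4.0,
    leaflets: int = 2,
) -> float:
    """Membrane volume charge density rho_m (e/nm^3) from lipid composition.

    rho_m = leaflets * sum_s fraction_s * charge_s / (area_per_lipid * H_m).

    ``species_fractions`` are mole fractions per leaflet (must sum to 1);
    anionic species default to POPS = -1 e and PIP2 = -5 e, neutral
    species (CHOL, DOPC, POPC, POPE) to 0 e.  ``leaflets`` = 1 models an
    asymmetric membrane charged on one leaflet only.
    """
    if area_per_lipid <= 0:
        raise ValueError("area_per_lipid must be positive")
    if H_m <= 0:
        raise ValueError("H_m must be positive")
    if leaflets < 1:
        raise ValueError("leaflets must be >= 1")
    total = sum(species_fractions.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"species fractions must sum to 1 (got {total})")
    charges = dict(DEFAULT_LIPID_CHARGES)
    if species_charges:
        charges.update({k.upper(): v for k, v in species_charges.items()})
    sigma_leaflet = 0.0
    for species, fraction in species_fractions.items():
        key = species.upper()
        if key not in charges:
            raise ValueError(f"unknown lipid species {species!r}: supply its charge")
        sigma_leaflet += fraction * charges[key]
    return leaflets * sigma_leaflet / (area_per_lipid * H_m)
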