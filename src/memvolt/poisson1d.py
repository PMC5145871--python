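"""Numeric transmembrane voltage from charge-density profiles.

The Tieleman-style route used on MD output: average the particle
charges over the membrane plane into a 1-D profile rho(Z), integrate
the Poisson equation d2(phi)/dZ2 = -rho/(eps_r*eps0) twice along Z
(zero field at the lower box edge, phi = 0 at the symmetry axis), and
read the transmembrane voltage off the potential at the membrane faces.

The double integration treats each bin's density as uniform, which
makes the potential at the bin edges exact for the binned
representation (the trapezoid rule is exact on the piecewise-linear
field); accuracy against the continuum model is then limited only by
how the binning represents the charge distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from .constants import COULOMB_NM
from .layered_model import LayerStack, PotentialProfile
from .synthetic_membrane import PseudoConfiguration

__all__ = [
    "ChargeProfile",
    "MembraneBounds",
    "bin_charge_density",
    "stack_charge_profile",
    "integrate_potential",
    "locate_membranes",
    "measure_voltage",
]


@dataclass(frozen=True)
class ChargeProfile:
    """Binned 1-D charge density rho(Z): N+1 edges (nm), N densities (e/nm^3)."""

    bin_edges: np.ndarray
    rho: np.ndarray
    area: float  # box cross-section X*Y, nm^2
    frame_time: float | None = None  # ns

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        rho = np.asarray(self.rho, dtype=float)
        if edges.ndim != 1 or rho.ndim != 1 or edges.size != rho.size + 1:
            raise ValueError("need N+1 edges for N bin densities")
        if not np.all(np.diff(edges) > 0):
            raise ValueError("bin edges must be strictly increasing")
        if self.area <= 0:
            raise ValueError("area must be positive")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "rho", rho)

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.bin_edges)

    @property
    def total_charge(self) -> float:
        """Net system charge, e (= sum rho_i * dz_i * area)."""
        return float(np.sum(self.rho * self.widths) * self.area)


@dataclass(frozen=True)
class MembraneBounds:
    """Z-extents of the two membrane slabs: (lower_face, upper_face) each.

    ``membrane1`` is the upper slab (vesicle side), ``membrane2`` the
    lower one, matching the closed-form model's numbering.
    """

    membrane1: tuple[float, float]
    membrane2: tuple[float, float]

    def __post_init__(self) -> None:
        for lo, hi in (self.membrane1, self.membrane2):
            if not lo < hi:
                raise ValueError("each membrane needs lower_face < upper_face")
        if not self.membrane2[1] <= self.membrane1[0]:
            raise ValueError("membrane intervals must be disjoint (membrane2 below)")

    @property
    def midplane(self) -> float:
        """Mid-point of the inter-membrane region (the symmetry axis)."""
        return 0.5 * (self.membrane2[1] + self.membrane1[0])


# ---------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------

def bin_charge_density(
    config: PseudoConfiguration, bin_width: float = 0.1
) -> ChargeProfile:
    """Average particle charges over the membrane plane into rho(Z).

    Particles are wrapped once into the primary box image; the bins span
    the full box Z extent, so the binned charge equals the total particle
    charge exactly.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if config.n_particles == 0:
        raise ValueError("configuration has no particles")
    lz = config.box[2]
    z = np.mod(config.positions[:, 2], lz)
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite particle position after wrapping")
    n_bins = max(1, int(round(lz / bin_width)))
    edges = np.linspace(0.0, lz, n_bins + 1)
    q_per_bin, _ = np.histogram(z, bins=edges, weights=config.charges)
    area = config.box[0] * config.box[1]
    rho = q_per_bin / (area * np.diff(edges))
    return ChargeProfile(
        bin_edges=edges, rho=rho, area=area, frame_time=config.frame_time
    )


def stack_charge_profile(
    stack: LayerStack, bin_width: float = 0.1, area: float = 1.0
) -> ChargeProfile:
    """Noise-free binned profile of a LayerStack (bin-averaged densities).

    The stack-frame density (Z = 0 at the R2 mid-plane) is averaged
    exactly over each bin, i.e. the profile an infinitely sampled
    configuration would produce.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    edges_stack = stack.edges
    span = edges_stack[-1] - edges_stack[0]
    n_bins = max(1, int(round(span / bin_width)))
    edges = np.linspace(edges_stack[0], edges_stack[-1], n_bins + 1)
    lo, hi = edges[:-1], edges[1:]
    rho = np.zeros(n_bins)
    densities = stack.densities
    for k in range(5):
        overlap = np.clip(
            np.minimum(hi, edges_stack[k + 1]) - np.maximum(lo, edges_stack[k]),
            0.0,
            None,
        )
        rho += densities[k] * overlap
    rho /= hi - lo
    return ChargeProfile(bin_edges=edges, rho=rho, area=area)


# ---------------------------------------------------------------------
# integration and read-off
# ---------------------------------------------------------------------

def integrate_potential(
    profile: ChargeProfile, eps_r: float, reference_z: float | None = None
) -> PotentialProfile:
    """Double-integrate rho(Z) to phi(Z) at the bin edges.

    Zero field at the lower edge of the profile (no external field; for
    a neutral profile the field also vanishes at the upper edge), then
    phi is shifted so that phi(reference_z) = 0.  ``reference_z``
    defaults to the profile mid-point (the symmetry axis of a stack that
    fills the box symmetrically).
    """
    if eps_r <= 0:
        raise ValueError("eps_r must be positive")
    edges = profile.bin_edges
    if reference_z is None:
        reference_z = 0.5 * (edges[0] + edges[-1])
    if not edges[0] - 1e-12 <= reference_z <= edges[-1] + 1e-12:
        raise ValueError("reference_z outside the profile range")
    coeff = COULOMB_NM / eps_r
    h = profile.widths
    # slope s = dphi/dz: s' = -coeff*rho, s = 0 at the bottom edge
    slopes = np.concatenate([[0.0], -coeff * np.cumsum(profile.rho * h)])
    # phi: exact integral of the piecewise-linear slope
    steps = slopes[:-1] * h - 0.5 * coeff * profile.rho * h**2
    phi = np.concatenate([[0.0], np.cumsum(steps)])
    phi = phi - np.interp(reference_z, edges, phi)
    return PotentialProfile(z=edges, phi=phi, reference_z=float(reference_z))


def locate_membranes(
    source: Union[LayerStack, PseudoConfiguration],
    min_gap: float = 1.0,
) -> MembraneBounds:
    """Find the two membrane slabs' faces.

    Declared geometry (a LayerStack, or a configuration built from one)
    gives the faces exactly — in the stack frame for a LayerStack, in
    box coordinates for a configuration.  Otherwise the faces are
    estimated from the support of the headgroup density: headgroup Z
    positions are clustered wherever consecutive sorted positions are
    closer than ``min_gap``; exactly two clusters are two volumetric
    slabs (faces = cluster extent, which coincides with the density
    half-maximum crossing of a uniform slab to within the sampling
    resolution), exactly four are paired face sheets; anything else is
    an error listing the clusters found.
    """
    if isinstance(source, LayerStack):
        return MembraneBounds(
            membrane1=source.membrane1_faces, membrane2=source.membrane2_faces
        )
    config = source
    if config.stack is not None:
        off = config.box_frame_offset
        m1 = config.stack.membrane1_faces
        m2 = config.stack.membrane2_faces
        return MembraneBounds(
            membrane1=(m1[0] + off, m1[1] + off),
            membrane2=(m2[0] + off, m2[1] + off),
        )

    head_mask = np.char.startswith(config.species.astype(str), "HEAD")
    z = np.sort(np.mod(config.positions[head_mask, 2], config.box[2]))
    if z.size == 0:
        raise ValueError("no headgroup particles to locate membranes from")
    breaks = np.flatnonzero(np.diff(z) > min_gap)
    starts = np.concatenate([[0], breaks + 1])
    stops = np.concatenate([breaks, [z.size - 1]])
    runs = [(float(z[a]), float(z[b])) for a, b in zip(starts, stops)]
    if len(runs) == 2:
        slabs = runs
    elif len(runs) == 4:  # discrete face sheets: pair bottom-up
        slabs = [(runs[0][0], runs[1][1]), (runs[2][0], runs[3][1])]
    else:
        raise ValueError(
            f"expected 2 membrane slabs (2 or 4 headgroup density clusters), "
            f"found {len(runs)}: {runs}"
        )
    return MembraneBounds(membrane1=slabs[1], membrane2=slabs[0])


def measure_voltage(
    potential: PotentialProfile, bounds: MembraneBounds
) -> tuple[float, float]:
    """Transmembrane voltages (dV1, dV2) read off a potential profile.

    dV_k = phi(outer face) - phi(inner face), the inner face being the
    one nearer the inter-membrane mid-plane; linear interpolation between
    grid points.  Same convention as the closed-form model.
    """
    mid = bounds.midplane
    out = []
    for lo, hi in (bounds.membrane1, bounds.membrane2):
        inner, outer = (lo, hi) if abs(lo - mid) < abs(hi - mid) else (hi, lo)
        out.append(potential.value(outer) - potential.value(inner))
    return (out[0], out[1])
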