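"""Shared fixtures and the independent quadrature oracle."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.integrate import cumulative_trapezoid

import memvolt as mv
from memvolt.constants import COULOMB_NM


@pytest.fixture
def pops15_stack() -> mv.LayerStack:
    """Default-geometry 15% POPS stack at D = 4 nm (neutral, symmetric)."""
    return mv.build_stack_params(mv.standard_composition(0.15), D=4.0)


def quadrature_potential(stack: mv.LayerStack, dz: float = 1e-4):
    """Brute-force double trapezoidal integration of the piecewise density.

    Independent of the closed form: samples rho(z) on a dense grid
    (layer interfaces get the mean of the adjacent layers so the
    trapezoid rule integrates the step exactly), integrates to the
    field with zero field below the stack, integrates again to phi and
    shifts phi(0) = 0.  Returns (z, phi).
    """
    edges = stack.edges
    densities = stack.densities
    pieces = []
    for k in range(5):
        if edges[k + 1] > edges[k]:
            n = max(2, int(round((edges[k + 1] - edges[k]) / dz)) + 1)
            pieces.append(np.linspace(edges[k], edges[k + 1], n))
    z = np.unique(np.concatenate(pieces + [np.array([0.0])]))
    rho = np.zeros_like(z)
    for k in range(5):
        inside = (z > edges[k]) & (z < edges[k + 1])
        rho[inside] = densities[k]
    for k in range(1, 5):  # interface nodes: mean of adjacent layers
        at = np.isclose(z, edges[k], rtol=0.0, atol=1e-12)
        rho[at] = 0.5 * (densities[k - 1] + densities[k])
    rho[0] = densities[0]  # integration starts/ends at the outer faces,
    rho[-1] = densities[-1]  # so boundary nodes carry the interior density
    slope = cumulative_trapezoid(-COULOMB_NM / stack.eps_r * rho, z, initial=0.0)
    phi = cumulative_trapezoid(slope, z, initial=0.0)
    phi -= np.interp(0.0, z, phi)
    return z, phi


def quadrature_voltages(stack: mv.LayerStack, dz: float = 1e-4):
    """Transmembrane voltages read off the quadrature potential."""
    z, phi = quadrature_potential(stack, dz)

    def at(x: float) -> float:
        return float(np.interp(x, z, phi))

    f1 = stack.membrane1_faces
    f2 = stack.membrane2_faces
    return (at(f1[1]) - at(f1[0]), at(f2[0]) - at(f2[1]))


def random_neutral_stack(rng: np.random.Generator) -> mv.LayerStack:
    """Arbitrary (generally asymmetric) neutral five-layer stack."""
    h_l = rng.uniform(2.0, 5.0)
    h_m = rng.uniform(2.0, 5.0)
    d = rng.uniform(0.5, 6.0)
    rho_m1 = rng.uniform(-0.4, -0.02)
    rho_m2 = rng.uniform(-0.4, -0.02)
    rho1 = rng.uniform(0.0, 0.15)
    rho2 = rng.uniform(0.0, 0.15)
    rho3 = -(rho1 * h_l + rho2 * d + (rho_m1 + rho_m2) * h_m) / h_l
    return mv.LayerStack(
        rho1=rho1, rho2=rho2, rho3=rho3, rho_m1=rho_m1, rho_m2=rho_m2,
        H_L=h_l, H_m=h_m, D=d, eps_r=rng.uniform(2.0, 10.0),
    )
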