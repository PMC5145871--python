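"""Physical constants in the package's internal unit system {e, nm, V, ns}.

All charge densities are in e/nm^3, lengths in nm, potentials in volts.
The Poisson coupling ``COULOMB_NM`` converts a charge density integrated
twice over nm into volts:  d2(phi)/dz2 = -COULOMB_NM * rho / eps_r.
"""

from scipy import constants as _sc

#: e / epsilon_0, expressed in V*nm (so that rho[e/nm^3] * length^2[nm^2]
#: * COULOMB_NM / eps_r is in volts).  ~18.0951 V*nm from CODATA values.
COULOMB_NM: float = _sc.elementary_charge / _sc.epsilon_0 * 1e9

#: Avogadro constant, 1/mol.
AVOGADRO: float = _sc.Avogadro

#: 1 nm^3 in litres.
NM3_TO_L: float = 1e-24

#: Conversion for lateral tension: bar * nm -> pN/nm.
#: 1 bar = 1e5 N/m^2 = 1e5 * 1e12 pN / 1e18 nm^2 = 0.1 pN/nm^2.
BAR_NM_TO_PN_PER_NM: float = _sc.bar * 1e12 / 1e18

#: Default relative dielectric constant of the slab interior (experimental
#: value for lipid/cytosol stacks used throughout the model).
DEFAULT_EPS_R: float = 3.0
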