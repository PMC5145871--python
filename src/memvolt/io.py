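"""File formats: GRO/PDB coordinates, species-charge tables, profiles, YAML.

Coordinate I/O goes through MDAnalysis; per-particle charges travel in a
companion two-column TSV (species -> charge in e) because GRO carries no
charge field.  Species labels are mapped to short GRO-safe residue/atom
names on write and back on read.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .layered_model import PotentialProfile
from .poisson1d import ChargeProfile
from .synthetic_membrane import PseudoConfiguration, Trajectory

__all__ = [
    "write_gro",
    "read_gro",
    "write_charge_table",
    "read_charge_table",
    "write_trajectory_gro",
    "write_trajectory_pdb",
    "write_profile_tsv",
    "write_potential_tsv",
    "write_yaml",
    "read_yaml",
]

# species label <-> 5-char GRO name
_SPECIES_TO_NAME = {
    "ION": "K",
    "WATER_MARK": "W",
    "HEAD_POPS": "POPS",
    "HEAD_PIP2": "PIP2",
    "HEAD_NEUTRAL": "HEADN",
    "CHARGE_PAD": "PAD",
}
_NAME_TO_SPECIES = {v: k for k, v in _SPECIES_TO_NAME.items()}


def _species_names(species: np.ndarray) -> np.ndarray:
    return np.array([_SPECIES_TO_NAME.get(str(s), str(s)[:5]) for s in species])


def _as_universe(config: PseudoConfiguration):
    import MDAnalysis as mda

    n = config.n_particles
    u = mda.Universe.empty(n, n_residues=n, atom_resindex=np.arange(n), trajectory=True)
    names = _species_names(config.species)
    u.add_TopologyAttr("names", names)
    u.add_TopologyAttr("resnames", names)
    u.add_TopologyAttr("resids", np.arange(1, n + 1))
    u.atoms.positions = config.positions * 10.0  # nm -> A
    u.dimensions = [config.box[0] * 10, config.box[1] * 10, config.box[2] * 10, 90, 90, 90]
    return u


def write_gro(config: PseudoConfiguration, path: str | Path) -> Path:
    """Write a configuration as a GROMACS GRO file (positions in nm)."""
    path = Path(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _as_universe(config).atoms.write(str(path))
    return path


def read_gro(
    path: str | Path, charge_table: str | Path | Mapping[str, float] | None = None
) -> PseudoConfiguration:
    """Read GRO (or PDB) coordinates plus a species->charge table.

    Without a charge table all particles are read with zero charge.
    """
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
    species = np.array([_NAME_TO_SPECIES.get(n, n) for n in u.atoms.names])
    if charge_table is None:
        charge_map: dict[str, float] = {}
    elif isinstance(charge_table, Mapping):
        charge_map = dict(charge_table)
    else:
        charge_map = read_charge_table(charge_table)
    charges = np.array([charge_map.get(s, 0.0) for s in species])
    box = u.dimensions[:3] / 10.0  # A -> nm
    return PseudoConfiguration(
        positions=u.atoms.positions / 10.0,
        charges=charges,
        species=species,
        box=(float(box[0]), float(box[1]), float(box[2])),
    )


def write_charge_table(charges: Mapping[str, float], path: str | Path) -> Path:
    """Two-column TSV: species label, charge in e."""
    path = Path(path)
    pd.DataFrame(
        {"species": list(charges), "charge_e": list(charges.values())}
    ).to_csv(path, sep="\t", index=False)
    return path


def read_charge_table(path: str | Path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["species"].astype(str), df["charge_e"].astype(float)))


def mean_species_charges(config: PseudoConfiguration) -> dict[str, float]:
    """Per-species mean charge of a configuration (for the companion TSV)."""
    out: dict[str, float] = {}
    for s in np.unique(config.species):
        out[str(s)] = float(config.charges[config.species == s].mean())
    return out


def write_trajectory_gro(trajectory: Trajectory, out_dir: str | Path, stem: str = "frame") -> list[Path]:
    """Write each frame as a numbered GRO file; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(trajectory.frames):
        paths.append(write_gro(frame, out_dir / f"{stem}_{i:04d}.gro"))
    return paths


def write_trajectory_pdb(trajectory: Trajectory, path: str | Path) -> Path:
    """Write a trajectory as a single multi-model PDB."""
    import MDAnalysis as mda

    path = Path(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), multiframe=True) as w:
            for frame in trajectory.frames:
                w.write(_as_universe(frame).atoms)
    return path


def write_profile_tsv(profile: ChargeProfile, path: str | Path) -> Path:
    """Charge density profile as TSV with a unit header."""
    path = Path(path)
    centers = 0.5 * (profile.bin_edges[:-1] + profile.bin_edges[1:])
    with open(path, "w") as fh:
        fh.write("# charge density profile: z nm, rho e/nm^3\n")
        fh.write(f"# area_nm2: {profile.area}\n")
        pd.DataFrame({"z_nm": centers, "rho_e_nm3": profile.rho}).to_csv(
            fh, sep="\t", index=False
        )
    return path


def write_potential_tsv(potential: PotentialProfile, path: str | Path) -> Path:
    """Potential profile as TSV with a unit header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# electric potential profile: z nm, phi V\n")
        fh.write(f"# reference_z_nm: {potential.reference_z}\n")
        pd.DataFrame({"z_nm": potential.z, "phi_V": potential.phi}).to_csv(
            fh, sep="\t", index=False
        )
    return path


def write_yaml(data: Mapping, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(dict(data), fh, sort_keys=False)
    return path


def read_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
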