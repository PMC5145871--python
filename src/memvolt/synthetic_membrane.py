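"""Synthetic two-bilayer systems standing in for MD trajectories.

Builds pseudo-particle configurations of the five-layer contact geometry
(two planar bilayers at separation D, anionic headgroup charge set by
the POPS/PIP2 fraction, neutralizing potassium uniformly distributed in
the three aqueous regions) and multi-frame trajectories with planted
cylindrical transmembrane pores whose radius follows a reseal / stable /
dilate schedule.  Everything is deterministic under a fixed seed and
exactly electro-neutral, so each downstream analysis stage (density
binning, voltage integration, pore detection) can be validated against
known ground truth.

Coordinate frame: box coordinates with Z in [0, Lz] and the stack's
symmetry axis at Lz/2; ``box_frame_offset`` converts to the model frame
(Z = 0 at the R2 mid-plane).

The particles are placeholders, not atoms: charged headgroup sites
distributed through each membrane slab (or, optionally, as discrete
face sheets), +1 e potassium ions, zero-charge WATER_MARK occupancy
markers on a jittered lattice (~water number density) used only for
pore detection, and a single CHARGE_PAD particle absorbing the
sub-elementary rounding residual so the net charge is exactly zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np

from .constants import AVOGADRO, NM3_TO_L
from .layered_model import (
    LayerStack,
    composition_to_membrane_charge,
)

__all__ = [
    "PseudoConfiguration",
    "Trajectory",
    "PoreSchedule",
    "SPECIES_ION",
    "SPECIES_WATER",
    "SPECIES_HEAD_POPS",
    "SPECIES_HEAD_PIP2",
    "SPECIES_HEAD_NEUTRAL",
    "SPECIES_CHARGE_PAD",
    "standard_composition",
    "build_stack_params",
    "build_configuration",
    "ion_concentration",
    "build_trajectory",
    "reseal_fast_schedule",
    "reseal_slow_schedule",
    "dilate_schedule",
    "named_schedule",
]

SPECIES_ION = "ION"
SPECIES_WATER = "WATER_MARK"
SPECIES_HEAD_POPS = "HEAD_POPS"
SPECIES_HEAD_PIP2 = "HEAD_PIP2"
SPECIES_HEAD_NEUTRAL = "HEAD_NEUTRAL"
SPECIES_CHARGE_PAD = "CHARGE_PAD"

#: Occupancy-marker number density emulating water at 1 g/cm^3 (~33.4/nm^3).
WATER_NUMBER_DENSITY = 33.4

#: Fine lattice spacing (nm) used to fill planted pore columns with
#: occupancy markers; must be denser than any sensible detection cell.
PORE_FILL_SPACING = 0.1


@dataclass(frozen=True)
class PseudoConfiguration:
    """Particle positions/charges/species in a rectangular box (nm, e)."""

    positions: np.ndarray  # (N, 3)
    charges: np.ndarray  # (N,)
    species: np.ndarray  # (N,) str
    box: tuple[float, float, float]
    stack: LayerStack | None = None  # declared geometry, if built here
    frame_time: float | None = None  # ns

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        q = np.asarray(self.charges, dtype=float)
        sp = np.asarray(self.species)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions must be an (N, 3) array")
        if q.shape != (pos.shape[0],) or sp.shape != (pos.shape[0],):
            raise ValueError("charges/species must match the number of particles")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "charges", q)
        object.__setattr__(self, "species", sp)

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    @property
    def net_charge(self) -> float:
        return float(self.charges.sum())

    @property
    def box_frame_offset(self) -> float:
        """Z of the model frame origin (R2 mid-plane) in box coordinates."""
        return self.box[2] / 2.0

    def wrapped(self) -> "PseudoConfiguration":
        box = np.asarray(self.box, dtype=float)
        return replace(self, positions=np.mod(self.positions, box))

    def select(self, species: str) -> np.ndarray:
        """Positions of all particles of one species, (M, 3)."""
        return self.positions[self.species == species]


@dataclass(frozen=True)
class PoreSchedule:
    """Planted pore radius as a function of time.

    ``radius_fn(t)`` gives the radius in nm for t >= t_open; the radius
    is zero before ``t_open``.  ``center_xy`` fixes the pore axis (box
    coordinates); None centers it in the box.
    """

    t_open: float  # ns
    radius_fn: Callable[[float], float]
    center_xy: tuple[float, float] | None = None
    label: str = "custom"

    def __post_init__(self) -> None:
        if self.t_open < 0:
            raise ValueError("t_open must be >= 0")

    def radius_at(self, t: float) -> float:
        if t < self.t_open:
            return 0.0
        r = float(self.radius_fn(t))
        if r < 0:
            raise ValueError(f"schedule produced a negative radius at t={t}")
        return r


@dataclass(frozen=True)
class Trajectory:
    """Ordered frames plus the planted-pore schedule metadata."""

    frames: tuple[PseudoConfiguration, ...]
    times: np.ndarray  # ns
    schedule: PoreSchedule | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if len(self.frames) != t.shape[0]:
            raise ValueError("times must match the number of frames")
        if t.size and not np.all(np.diff(t) > 0):
            raise ValueError("frame times must be strictly increasing")
        object.__setattr__(self, "times", t)

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)


# ---------------------------------------------------------------------
# composition and stack parameters
# ---------------------------------------------------------------------

def standard_composition(pops_fraction: float = 0.15) -> dict[str, float]:
    """Chol:DOPC:POPE:POPS composition with DOPC absorbing the POPS swing.

    Cholesterol and POPE are fixed at 20% each; DOPC makes up the rest
    (60% minus the POPS share), matching the composition ladder used for
    the distance and composition scans.
    """
    if not 0 <= pops_fraction <= 0.6:
        raise ValueError("pops_fraction must be in [0, 0.6]")
    return {
        "CHOL": 0.20,
        "DOPC": 0.60 - pops_fraction,
        "POPE": 0.20,
        "POPS": pops_fraction,
    }


def build_stack_params(
    composition: Mapping[str, float],
    D: float,
    H_m: float = 4.0,
    H_L: float = 4.0,
    area_per_lipid: float = 0.65,
    eps_r: float = 3.0,
    leaflets: int = 2,
    species_charges: Mapping[str, float] | None = None,
) -> LayerStack:
    """Neutral LayerStack for a lipid composition at separation ``D``.

    The membrane density comes from the composition; the counterion
    charge exactly balances it and is spread uniformly over the three
    aqueous regions (rho1 = rho2 = rho3), the generator's ground state
    for the fixed-counter-charge closure.
    """
    if D < 0:
        raise ValueError("D must be >= 0")
    rho_m = composition_to_membrane_charge(
        composition,
        species_charges=species_charges,
        area_per_lipid=area_per_lipid,
        H_m=H_m,
        leaflets=leaflets,
    )
    rho_aq = -2.0 * rho_m * H_m / (2.0 * H_L + D)
    return LayerStack(
        rho1=rho_aq,
        rho2=rho_aq,
        rho3=rho_aq,
        rho_m1=rho_m,
        rho_m2=rho_m,
        H_L=H_L,
        H_m=H_m,
        D=D,
        eps_r=eps_r,
    )


# ---------------------------------------------------------------------
# particle configurations
# ---------------------------------------------------------------------

def _region_edges(stack: LayerStack) -> dict[str, tuple[float, float]]:
    """Layer z-ranges in box coordinates (bottom of R3 at z = 0)."""
    h_l, h_m, d = stack.H_L, stack.H_m, stack.D
    return {
        "R3": (0.0, h_l),
        "M2": (h_l, h_l + h_m),
        "R2": (h_l + h_m, h_l + h_m + d),
        "M1": (h_l + h_m + d, h_l + 2 * h_m + d),
        "R1": (h_l + 2 * h_m + d, 2 * h_l + 2 * h_m + d),
    }


def _jittered_lattice(
    rng: np.random.Generator,
    box_xy: float,
    z_lo: float,
    z_hi: float,
    density: float,
) -> np.ndarray:
    """Roughly uniform points at a target number density via jittered grid."""
    if z_hi <= z_lo or density <= 0:
        return np.empty((0, 3))
    a = density ** (-1.0 / 3.0)
    nx = max(1, int(round(box_xy / a)))
    nz = max(1, int(round((z_hi - z_lo) / a)))
    ax, az = box_xy / nx, (z_hi - z_lo) / nz
    gx = (np.arange(nx) + 0.5) * ax
    gz = z_lo + (np.arange(nz) + 0.5) * az
    xx, yy, zz = np.meshgrid(gx, gx, gz, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    jitter = rng.uniform(-0.3, 0.3, size=pts.shape) * np.array([ax, ax, az])
    pts = pts + jitter
    pts[:, :2] %= box_xy
    pts[:, 2] = np.clip(pts[:, 2], z_lo + 1e-9, z_hi - 1e-9)
    return pts


def build_configuration(
    stack: LayerStack,
    box_xy: float = 23.0,
    seed: int = 0,
    include_water: bool = False,
    water_density: float = WATER_NUMBER_DENSITY,
    area_per_lipid: float = 0.65,
    headgroup_placement: str = "volumetric",
) -> PseudoConfiguration:
    """Particle realization of a LayerStack in a box_xy x box_xy x Lz box.

    Membrane charge is carried by headgroup pseudo-particles; by default
    they are spread uniformly through each membrane slab so that the
    binned density profile is an unbiased sample of the LayerStack
    (``headgroup_placement='sheets'`` instead puts them on two discrete
    face sheets per membrane, which integrates to the same transmembrane
    voltage in the continuum limit but is first-order biased under
    binning).  Potassium ions (+1 e) are placed uniformly at random in
    R1/R2/R3 with integer counts rounded from the target densities; the
    rounding residual goes to a single CHARGE_PAD particle so the net
    charge is exactly zero.
    """
    if box_xy <= 0:
        raise ValueError("box_xy must be positive")
    if headgroup_placement not in ("volumetric", "sheets"):
        raise ValueError("headgroup_placement must be 'volumetric' or 'sheets'")
    rng = np.random.default_rng(seed)
    area = box_xy * box_xy
    regions = _region_edges(stack)
    lz = regions["R1"][1]

    positions: list[np.ndarray] = []
    charges: list[np.ndarray] = []
    species: list[np.ndarray] = []

    def add(pos: np.ndarray, q: np.ndarray, label: str) -> None:
        if len(pos) == 0:
            return
        positions.append(pos)
        charges.append(np.asarray(q, dtype=float))
        species.append(np.full(len(pos), label))

    # headgroup sites -------------------------------------------------
    n_sites_leaflet = max(1, int(round(area / area_per_lipid)))
    for mem_key, rho_m in (("M1", stack.rho_m1), ("M2", stack.rho_m2)):
        z_lo, z_hi = regions[mem_key]
        total_q = rho_m * stack.H_m * area
        label = SPECIES_HEAD_POPS if total_q < 0 else SPECIES_HEAD_NEUTRAL
        if headgroup_placement == "volumetric":
            n = 2 * n_sites_leaflet
            xy = rng.uniform(0.0, box_xy, size=(n, 2))
            z = rng.uniform(z_lo, z_hi, size=n)
            add(np.column_stack([xy, z]), np.full(n, total_q / n), label)
        else:
            for z_face in (z_lo, z_hi):
                xy = rng.uniform(0.0, box_xy, size=(n_sites_leaflet, 2))
                z = np.full(n_sites_leaflet, z_face)
                add(
                    np.column_stack([xy, z]),
                    np.full(n_sites_leaflet, total_q / 2.0 / n_sites_leaflet),
                    label,
                )

    # neutralizing ions ----------------------------------------------
    for reg_key, rho in (("R1", stack.rho1), ("R2", stack.rho2), ("R3", stack.rho3)):
        z_lo, z_hi = regions[reg_key]
        target = rho * (z_hi - z_lo) * area  # target charge, e
        n_ions = int(round(target))
        if n_ions < 0:
            raise ValueError(
                f"negative target ion count in {reg_key}: generator places "
                "K+ only; net-negative aqueous charge is not supported"
            )
        if n_ions:
            xy = rng.uniform(0.0, box_xy, size=(n_ions, 2))
            z = rng.uniform(z_lo, z_hi, size=n_ions)
            add(np.column_stack([xy, z]), np.ones(n_ions), SPECIES_ION)

    # rounding residual -> one declared compensator at the R2 center --
    net = float(np.concatenate(charges).sum()) if charges else 0.0
    if abs(net) > 1e-12:
        z_lo, z_hi = regions["R2"]
        z_pad = 0.5 * (z_lo + z_hi) if z_hi > z_lo else regions["M1"][0]
        add(
            np.array([[box_xy / 2.0, box_xy / 2.0, z_pad]]),
            np.array([-net]),
            SPECIES_CHARGE_PAD,
        )

    # occupancy markers ----------------------------------------------
    if include_water:
        for reg_key in ("R1", "R2", "R3"):
            z_lo, z_hi = regions[reg_key]
            pts = _jittered_lattice(rng, box_xy, z_lo, z_hi, water_density)
            add(pts, np.zeros(len(pts)), SPECIES_WATER)

    return PseudoConfiguration(
        positions=np.concatenate(positions) if positions else np.empty((0, 3)),
        charges=np.concatenate(charges) if charges else np.empty(0),
        species=np.concatenate(species) if species else np.empty(0, dtype=object),
        box=(box_xy, box_xy, lz),
        stack=stack,
    )


def ion_concentration(config: PseudoConfiguration) -> dict[str, float]:
    """Potassium concentration (mol/L) per aqueous region and overall.

    Requires declared geometry (a configuration built from a LayerStack)
    so that the aqueous volumes are known.
    """
    if config.stack is None:
        raise ValueError("ion_concentration needs a declared-geometry configuration")
    regions = _region_edges(config.stack)
    area = config.box[0] * config.box[1]
    ion_z = config.select(SPECIES_ION)[:, 2]
    out: dict[str, float] = {}
    total_n, total_v = 0, 0.0
    for key in ("R1", "R2", "R3"):
        z_lo, z_hi = regions[key]
        volume = (z_hi - z_lo) * area  # nm^3
        n = int(np.count_nonzero((ion_z >= z_lo) & (ion_z < z_hi)))
        total_n += n
        total_v += volume
        out[key] = n / (AVOGADRO * volume * NM3_TO_L) if volume > 0 else 0.0
    if total_v <= 0:
        raise ValueError("zero aqueous volume")
    out["overall"] = total_n / (AVOGADRO * total_v * NM3_TO_L)
    return out


# ---------------------------------------------------------------------
# pore schedules (reseal / stabilize / dilate regimes)
# ---------------------------------------------------------------------

def reseal_fast_schedule(
    r0: float = 0.75, t_open: float = 2.0, close_after: float = 8.0
) -> PoreSchedule:
    """Low-tension regime: the pore shrinks linearly and reseals quickly."""

    def radius(t: float) -> float:
        return max(0.0, r0 * (1.0 - (t - t_open) / close_after))

    return PoreSchedule(t_open=t_open, radius_fn=radius, label="RESEAL_FAST")


def reseal_slow_schedule(
    r0: float = 0.75, t_open: float = 2.0, window: float = 20.0, final_fraction: float = 0.5
) -> PoreSchedule:
    """Intermediate tension: the pore shrinks but is still open at the window end."""

    def radius(t: float) -> float:
        span = max(window - t_open, 1e-9)
        frac = 1.0 - (1.0 - final_fraction) * min(1.0, (t - t_open) / span)
        return r0 * frac

    return PoreSchedule(t_open=t_open, radius_fn=radius, label="RESEAL_SLOW")


def dilate_schedule(
    r0: float = 0.75, t_open: float = 2.0, growth_rate: float = 0.05
) -> PoreSchedule:
    """High-tension regime: monotone pore growth (fraction per ns)."""

    def radius(t: float) -> float:
        return r0 * (1.0 + growth_rate * (t - t_open))

    return PoreSchedule(t_open=t_open, radius_fn=radius, label="DILATE")


_SCHEDULE_FACTORIES = {
    "RESEAL_FAST": reseal_fast_schedule,
    "RESEAL_SLOW": reseal_slow_schedule,
    "DILATE": dilate_schedule,
}


def named_schedule(name: str, **kwargs) -> PoreSchedule:
    """One of the three template schedules: RESEAL_FAST, RESEAL_SLOW, DILATE."""
    try:
        return _SCHEDULE_FACTORIES[name.upper()](**kwargs)
    except KeyError:
        raise ValueError(
            f"unknown schedule {name!r}; choose from {sorted(_SCHEDULE_FACTORIES)}"
        ) from None


# ---------------------------------------------------------------------
# trajectories with planted pores
# ---------------------------------------------------------------------

def _pore_column(
    box_xy: float,
    center: tuple[float, float],
    radius: float,
    z_lo: float,
    z_hi: float,
    spacing: float = PORE_FILL_SPACING,
) -> np.ndarray:
    """Occupancy markers filling a periodic cylinder through one slab."""
    if radius <= 0 or z_hi <= z_lo:
        return np.empty((0, 3))
    n_r = int(math.ceil(radius / spacing))
    offsets = (np.arange(-n_r, n_r + 1)) * spacing
    ox, oy = np.meshgrid(offsets, offsets, indexing="ij")
    keep = ox**2 + oy**2 <= radius**2
    xy = np.column_stack([(center[0] + ox[keep]), (center[1] + oy[keep])]) % box_xy
    nz = max(2, int(math.ceil((z_hi - z_lo) / spacing)) + 1)
    zs = np.linspace(z_lo + 1e-9, z_hi - 1e-9, nz)
    cols = np.repeat(xy, nz, axis=0)
    z = np.tile(zs, len(xy))
    return np.column_stack([cols, z])


def build_trajectory(
    stack: LayerStack,
    box_xy: float = 8.0,
    n_frames: int = 41,
    dt: float = 0.5,
    schedule: PoreSchedule | None = None,
    seed: int = 0,
    include_water: bool = True,
    water_density: float = WATER_NUMBER_DENSITY,
    leak_ions: int = 0,
) -> Trajectory:
    """Multi-frame trajectory with an optional planted transmembrane pore.

    The base configuration is frozen (pseudo-particles do not diffuse);
    for t >= t_open a cylindrical column of occupancy markers spans each
    membrane slab at the schedule radius, emulating the water channel of
    an open pore.  ``leak_ions`` ions are moved from R2 into R1/R3 on
    the first open frame to emulate charge leakage through the pore.
    """
    if n_frames < 1:
        raise ValueError("need at least one frame")
    if dt <= 0:
        raise ValueError("dt must be positive")
    base = build_configuration(
        stack,
        box_xy=box_xy,
        seed=seed,
        include_water=include_water,
        water_density=water_density,
    )
    regions = _region_edges(stack)
    center = (
        schedule.center_xy
        if schedule is not None and schedule.center_xy is not None
        else (box_xy / 2.0, box_xy / 2.0)
    )

    leaked_charges = base.charges
    leaked_positions = base.positions
    if leak_ions and schedule is not None:
        rng = np.random.default_rng(seed + 1)
        ion_idx = np.flatnonzero(base.species == SPECIES_ION)
        in_r2 = ion_idx[
            (base.positions[ion_idx, 2] >= regions["R2"][0])
            & (base.positions[ion_idx, 2] < regions["R2"][1])
        ]
        move = in_r2[: min(leak_ions, len(in_r2))]
        leaked_positions = base.positions.copy()
        halves = rng.random(len(move)) < 0.5
        for i, idx in enumerate(move):
            lo, hi = regions["R1"] if halves[i] else regions["R3"]
            leaked_positions[idx, 2] = rng.uniform(lo, hi)

    times = np.arange(n_frames) * dt
    frames = []
    for t in times:
        r = schedule.radius_at(t) if schedule is not None else 0.0
        pos, q, sp = base.positions, base.charges, base.species
        if schedule is not None and t >= schedule.t_open:
            pos = leaked_positions
        if r > 0:
            cols = [
                _pore_column(box_xy, center, r, *regions[mem]) for mem in ("M1", "M2")
            ]
            extra = np.concatenate(cols)
            pos = np.concatenate([pos, extra])
            q = np.concatenate([q, np.zeros(len(extra))])
            sp = np.concatenate([sp, np.full(len(extra), SPECIES_WATER)])
        frames.append(
            PseudoConfiguration(
                positions=pos,
                charges=q,
                species=sp,
                box=base.box,
                stack=stack,
                frame_time=float(t),
            )
        )
    return Trajectory(frames=tuple(frames), times=times, schedule=schedule)
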