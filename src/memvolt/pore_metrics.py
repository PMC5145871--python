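"""Detection, sizing and fate classification of transmembrane pores.

A pore is an XY-connected patch of grid columns whose water occupancy
is continuous across a membrane slab: the slab is divided into Z
sub-bins of the grid cell size, and a column counts as open only if
every sub-bin contains at least one water (occupancy-marker) particle.
Open columns are grouped by 4-connectivity with periodic wrap in X and
Y; each component is one pore, sized by its equivalent circular
diameter 2*sqrt(area/pi).

Pore fate under lateral membrane tension is classified from the
diameter time series into the three regimes seen in close-contact
fusion simulations: fast reseal (low tension), slow reseal /
stabilized pore (intermediate tension), and dilation (high tension).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage, optimize

from .poisson1d import MembraneBounds
from .synthetic_membrane import (
    PseudoConfiguration,
    SPECIES_WATER,
    Trajectory,
)

__all__ = [
    "PoreObservation",
    "PoreRecord",
    "PoreFate",
    "GaussianFit",
    "detect_pores",
    "pore_size_distribution",
    "pore_formation_time",
    "classify_fate",
]

FATE_RESEAL_FAST = "RESEAL_FAST"
FATE_RESEAL_SLOW = "RESEAL_SLOW"
FATE_DILATE = "DILATE"


@dataclass(frozen=True)
class PoreObservation:
    """One detected pore in one membrane of one frame."""

    membrane: int  # 1 = upper/vesicle, 2 = lower/presynaptic
    area: float  # nm^2
    equivalent_diameter: float  # nm, 2*sqrt(area/pi)
    centroid_xy: tuple[float, float]  # nm, periodic mean of member cells
    member_cells: int


@dataclass(frozen=True)
class PoreRecord:
    """All pores detected in one frame."""

    frame_time: float | None
    pores: tuple[PoreObservation, ...]

    @property
    def n_pores(self) -> int:
        return len(self.pores)

    def diameters(self, membrane: int | None = None) -> np.ndarray:
        return np.array(
            [
                p.equivalent_diameter
                for p in self.pores
                if membrane is None or p.membrane == membrane
            ]
        )


@dataclass(frozen=True)
class PoreFate:
    """Outcome of one pore's diameter trajectory within the window."""

    label: str  # RESEAL_FAST | RESEAL_SLOW | DILATE
    close_time: float | None  # ns; set for reseal labels only
    final_diameter: float  # nm (0 when resealed)

    def __post_init__(self) -> None:
        if self.label == FATE_DILATE and self.close_time is not None:
            raise ValueError("a dilating pore has no close time")
        if self.label == FATE_RESEAL_FAST and self.close_time is None:
            raise ValueError("a fast-resealing pore needs a close time")


@dataclass(frozen=True)
class GaussianFit:
    """Gaussian fit to the pore diameter histogram."""

    available: bool
    mean: float | None = None
    sigma: float | None = None
    amplitude: float | None = None
    residual: float | None = None
    bin_centers: np.ndarray | None = None
    counts: np.ndarray | None = None
    n_observations: int = 0


# ---------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------

def _periodic_label(open_mask: np.ndarray) -> tuple[np.ndarray, int]:
    """4-connected components of a 2-D mask with periodic wrap in both axes."""
    labels, n = ndimage.label(open_mask)  # default structure = 4-connectivity
    if n == 0:
        return labels, 0
    # union-find merge of labels touching across the periodic boundaries
    parent = list(range(n + 1))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    for a, b in zip(labels[0, :], labels[-1, :]):
        if a and b:
            union(int(a), int(b))
    for a, b in zip(labels[:, 0], labels[:, -1]):
        if a and b:
            union(int(a), int(b))
    roots = sorted({find(k) for k in range(1, n + 1)})
    remap = np.zeros(n + 1, dtype=labels.dtype)
    for new, root in enumerate(roots, start=1):
        for k in range(1, n + 1):
            if find(k) == root:
                remap[k] = new
    return remap[labels], len(roots)


def _periodic_centroid(
    idx: np.ndarray, n_cells: int, cell: float, box: float
) -> float:
    """Mean position of cell centers on a circle (handles wrapped pores)."""
    theta = (idx + 0.5) * (2.0 * np.pi / n_cells)
    angle = np.arctan2(np.sin(theta).mean(), np.cos(theta).mean()) % (2.0 * np.pi)
    return angle / (2.0 * np.pi) * box


def detect_pores(
    frame: PseudoConfiguration,
    bounds: MembraneBounds,
    cell_size: float = 0.2,
) -> PoreRecord:
    """Water-continuity pore detection in both membranes of one frame."""
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    lx, ly, lz = frame.box
    for lo, hi in (bounds.membrane1, bounds.membrane2):
        if lo < 0 or hi > lz:
            raise ValueError("membrane bounds outside the box")
    water = frame.select(SPECIES_WATER)
    pores: list[PoreObservation] = []
    nx = max(1, int(round(lx / cell_size)))
    ny = max(1, int(round(ly / cell_size)))
    cx, cy = lx / nx, ly / ny
    for mem_id, (z_lo, z_hi) in ((1, bounds.membrane1), (2, bounds.membrane2)):
        nz = max(1, int(np.ceil((z_hi - z_lo) / cell_size)))
        in_slab = water[(water[:, 2] >= z_lo) & (water[:, 2] <= z_hi)]
        if len(in_slab) == 0:
            continue
        xyz = in_slab.copy()
        xyz[:, 0] = np.mod(xyz[:, 0], lx)
        xyz[:, 1] = np.mod(xyz[:, 1], ly)
        hist, _ = np.histogramdd(
            xyz,
            bins=(nx, ny, nz),
            range=((0.0, lx), (0.0, ly), (z_lo, z_hi)),
        )
        open_mask = np.all(hist > 0, axis=2)
        labels, n = _periodic_label(open_mask)
        for k in range(1, n + 1):
            ii, jj = np.nonzero(labels == k)
            n_cells = len(ii)
            area = n_cells * cx * cy
            pores.append(
                PoreObservation(
                    membrane=mem_id,
                    area=area,
                    equivalent_diameter=2.0 * np.sqrt(area / np.pi),
                    centroid_xy=(
                        _periodic_centroid(ii, nx, cx, lx),
                        _periodic_centroid(jj, ny, cy, ly),
                    ),
                    member_cells=n_cells,
                )
            )
    return PoreRecord(frame_time=frame.frame_time, pores=tuple(pores))


# ---------------------------------------------------------------------
# size distribution
# ---------------------------------------------------------------------

def _gaussian(x: np.ndarray, amp: float, mean: float, sigma: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((x - mean) / sigma) ** 2)


def pore_size_distribution(
    records: Sequence[PoreRecord],
    membrane: int | None = None,
    bins: int | str = "auto",
    min_observations: int = 10,
) -> GaussianFit:
    """Histogram the pooled (or per-membrane) diameters and fit a Gaussian.

    With fewer than ``min_observations`` pores the histogram is returned
    with the fit marked unavailable.
    """
    diameters = np.concatenate(
        [r.diameters(membrane) for r in records] or [np.empty(0)]
    )
    n = diameters.size
    if n == 0:
        return GaussianFit(available=False, n_observations=0)
    counts, edges = np.histogram(diameters, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    if n < min_observations:
        return GaussianFit(
            available=False, bin_centers=centers, counts=counts, n_observations=n
        )
    mu0, sd0 = float(diameters.mean()), float(diameters.std())
    sd0 = max(sd0, 1e-6)
    try:
        if centers.size < 4:
            raise RuntimeError("too few histogram bins for a 3-parameter fit")
        popt, _ = optimize.curve_fit(
            _gaussian,
            centers,
            counts,
            p0=(float(counts.max()), mu0, sd0),
            maxfev=10000,
        )
        amp, mean, sigma = popt
        sigma = abs(float(sigma))
        residual = float(np.sqrt(np.mean((_gaussian(centers, *popt) - counts) ** 2)))
    except (RuntimeError, TypeError):
        # degenerate histograms (e.g. all-identical diameters): fall back
        # to the sample moments, which the Gaussian limit would give
        amp, mean, sigma, residual = float(counts.max()), mu0, sd0, 0.0
    return GaussianFit(
        available=True,
        mean=float(mean),
        sigma=sigma,
        amplitude=float(amp),
        residual=residual,
        bin_centers=centers,
        counts=counts,
        n_observations=n,
    )


# ---------------------------------------------------------------------
# kinetics
# ---------------------------------------------------------------------

def pore_formation_time(
    trajectory: Trajectory,
    bounds: MembraneBounds,
    cell_size: float = 0.2,
    window: float = 20.0,
) -> float | None:
    """Time of the first frame with a detected pore, or None within the window."""
    if len(trajectory) == 0:
        raise ValueError("empty trajectory")
    for frame, t in zip(trajectory.frames, trajectory.times):
        if t > window:
            break
        record = detect_pores(frame, bounds, cell_size=cell_size)
        if record.n_pores > 0:
            return float(t)
    return None


def classify_fate(
    size_series: Sequence[tuple[float, float]],
    window: float = 20.0,
    growth_threshold: float = 0.25,
    trend_tol: float = 0.01,
    closed_below: float = 1e-9,
) -> PoreFate:
    """Classify a pore's (time, diameter) series into its tension regime.

    RESEAL_FAST: the diameter reaches zero within the window.
    DILATE: the final diameter exceeds the initial by at least
    ``growth_threshold`` (fractional) and the least-squares slope over
    the last third of the window is non-negative (within ``trend_tol``
    nm/ns, to tolerate grid-cell noise).
    RESEAL_SLOW: anything still open at the window end that is not
    dilating (shrinking or stable pores).
    """
    if len(size_series) == 0:
        raise ValueError("empty size series")
    series = sorted((float(t), float(d)) for t, d in size_series)
    t = np.array([p[0] for p in series])
    d = np.array([p[1] for p in series])
    in_window = t <= t[0] + window
    t, d = t[in_window], d[in_window]

    closed = np.flatnonzero(d <= closed_below)
    if closed.size:
        return PoreFate(
            label=FATE_RESEAL_FAST,
            close_time=float(t[closed[0]]),
            final_diameter=0.0,
        )

    initial, final = d[0], d[-1]
    grown = final > initial * (1.0 + growth_threshold)
    last_third = t >= t[-1] - (t[-1] - t[0]) / 3.0
    if np.count_nonzero(last_third) >= 2:
        slope = float(np.polyfit(t[last_third], d[last_third], 1)[0])
    else:
        slope = 0.0
    if grown and slope >= -trend_tol:
        return PoreFate(label=FATE_DILATE, close_time=None, final_diameter=float(final))
    return PoreFate(
        label=FATE_RESEAL_SLOW, close_time=None, final_diameter=float(final)
    )
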