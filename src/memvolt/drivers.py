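"""Tension computation and the distance / composition scan pipelines.

``distance_scan`` mirrors the simulation protocol: step the
inter-membrane distance down from 6 nm in 0.5 nm steps, compute the
transmembrane voltage at each distance, and report which distances
porate (|dV| at or above the critical poration voltage) together with
the critical distance.  In trajectory mode a synthetic trajectory is
built for each porating distance and the pore formation time is
measured by detection; the coupling between voltage and pore opening
time is an explicit stub (a threshold rule), not a kinetic model.

``composition_scan`` maps the POPS ladder to membrane charge and
critical distance; ``membrane_tension`` converts box pressures to the
lateral tension Gamma = L_Z * (P_Z - P_Lat).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import BAR_NM_TO_PN_PER_NM
from .layered_model import (
    ClosurePolicy,
    LayerStack,
    NoCrossingError,
    critical_distance,
    stack_at_distance,
    transmembrane_voltages,
)
from .poisson1d import locate_membranes
from .pore_metrics import pore_formation_time
from .results import ScanResult
from .synthetic_membrane import (
    PoreSchedule,
    build_stack_params,
    build_trajectory,
    reseal_slow_schedule,
)

__all__ = [
    "TensionRecord",
    "membrane_tension",
    "tension_record",
    "pressure_difference_for_tension",
    "distance_scan",
    "composition_scan",
]


@dataclass(frozen=True)
class TensionRecord:
    """Lateral membrane tension derived from box pressures."""

    L_Z: float  # nm
    P_Z: float  # bar
    P_Lat: float  # bar
    gamma: float  # pN/nm


def membrane_tension(L_Z: float, P_Z: float, P_Lat: float) -> float:
    """Lateral tension Gamma = L_Z * (P_Z - P_Lat) in pN/nm.

    ``L_Z`` in nm, pressures in bar; the conversion constant
    (1 bar*nm = 0.1 pN/nm) is derived from SI definitions.
    """
    if L_Z <= 0:
        raise ValueError("L_Z must be positive")
    return L_Z * (P_Z - P_Lat) * BAR_NM_TO_PN_PER_NM


def tension_record(L_Z: float, P_Z: float, P_Lat: float) -> TensionRecord:
    return TensionRecord(
        L_Z=L_Z, P_Z=P_Z, P_Lat=P_Lat, gamma=membrane_tension(L_Z, P_Z, P_Lat)
    )


def pressure_difference_for_tension(gamma: float, L_Z: float) -> float:
    """Invert the tension formula: P_Z - P_Lat (bar) giving ``gamma`` pN/nm."""
    if L_Z <= 0:
        raise ValueError("L_Z must be positive")
    return gamma / (L_Z * BAR_NM_TO_PN_PER_NM)


# ---------------------------------------------------------------------
# scans
# ---------------------------------------------------------------------

def _stub_opening_time(dv_abs: float, dv_critical: float, window: float) -> float:
    """Threshold-rule stand-in for poration kinetics: stronger voltage,
    earlier opening; exactly-critical voltage opens at the window edge."""
    return window * (dv_critical / dv_abs) ** 2


def distance_scan(
    composition: Mapping[str, float],
    dv_critical: float,
    d_start: float = 6.0,
    d_step: float = 0.5,
    d_stop: float = 2.0,
    window: float = 20.0,
    mode: str = "analytic",
    policy: ClosurePolicy = ClosurePolicy.FIXED_COUNTER_CHARGE,
    stack_kwargs: Mapping | None = None,
    trajectory_kwargs: Mapping | None = None,
    seed: int = 0,
) -> ScanResult:
    """Scan the inter-membrane distance downward and locate D_critical.

    Rows: (D, dV, pore_formed, T).  In analytic mode pore_formed is
    |dV(D)| >= dv_critical and T is left empty; in trajectory mode a
    synthetic trajectory (pore planted when the threshold rule fires) is
    analyzed with the pore detector to measure T.  D_critical is the
    largest scanned distance that porates, or "below scan range".
    """
    if d_step <= 0:
        raise ValueError("d_step must be positive")
    if mode not in ("analytic", "trajectory"):
        raise ValueError("mode must be 'analytic' or 'trajectory'")
    if dv_critical < 0:
        raise ValueError("dv_critical must be >= 0")
    policy = ClosurePolicy(policy)
    stack_kwargs = dict(stack_kwargs or {})
    trajectory_kwargs = dict(trajectory_kwargs or {})

    d_values = np.arange(d_start, d_stop - 1e-9, -d_step)
    template = build_stack_params(composition, D=d_start, **stack_kwargs)

    rows = []
    for d in d_values:
        stack = stack_at_distance(template, float(d), policy)
        dv1, _ = transmembrane_voltages(stack)
        formed = abs(dv1) >= dv_critical
        t_form: float | None = None
        if mode == "trajectory" and formed:
            t_open = min(
                _stub_opening_time(abs(dv1), dv_critical, window) if dv_critical > 0 else 0.0,
                window,
            )
            kwargs = dict(trajectory_kwargs)
            sched_r0 = kwargs.pop("r0", 0.75)
            schedule = reseal_slow_schedule(
                r0=sched_r0, t_open=t_open, window=window
            )
            traj = build_trajectory(
                stack, schedule=schedule, seed=seed, **kwargs
            )
            bounds = locate_membranes(traj.frames[0])
            t_form = pore_formation_time(traj, bounds, window=window)
            formed = t_form is not None
        rows.append(
            {
                "D_nm": float(d),
                "dV_V": dv1,
                "pore_formed": bool(formed),
                "T_ns": t_form,
            }
        )

    table = pd.DataFrame(rows)
    formed_d = table.loc[table["pore_formed"], "D_nm"]
    d_critical = float(formed_d.max()) if len(formed_d) else None
    return ScanResult(
        table=table,
        metadata={
            "policy": policy.value,
            "composition": dict(composition),
            "dv_critical_V": dv_critical,
            "window_ns": window,
            "mode": mode,
            "D_critical_nm": d_critical if d_critical is not None else "below scan range",
            "units": "D nm; dV V; T ns",
        },
    )


def composition_scan(
    pops_fractions: Sequence[float],
    dv_critical: float,
    policy: ClosurePolicy = ClosurePolicy.FIXED_COUNTER_CHARGE,
    stack_kwargs: Mapping | None = None,
    bracket: tuple[float, float] = (0.5, 10.0),
) -> ScanResult:
    """Critical distance as a function of the POPS fraction.

    One row per fraction; fractions whose voltage never reaches
    ``dv_critical`` are flagged (``no_crossing``) and excluded from the
    monotonicity report in the metadata.
    """
    from .synthetic_membrane import standard_composition

    if any(not 0 <= f <= 1 for f in pops_fractions):
        raise ValueError("fractions must lie in [0, 1]")
    stack_kwargs = dict(stack_kwargs or {})
    rows = []
    for f in pops_fractions:
        template = build_stack_params(
            standard_composition(f), D=bracket[1], **stack_kwargs
        )
        try:
            d_crit = critical_distance(
                template, dv_critical, policy=policy, bracket=bracket
            )
            rows.append(
                {"pops_fraction": f, "D_critical_nm": d_crit, "no_crossing": False}
            )
        except NoCrossingError:
            rows.append(
                {"pops_fraction": f, "D_critical_nm": np.nan, "no_crossing": True}
            )
    table = pd.DataFrame(rows)
    ok = table.loc[~table["no_crossing"]].sort_values("pops_fraction")
    monotone = bool(np.all(np.diff(ok["D_critical_nm"].to_numpy()) >= -1e-12))
    return ScanResult(
        table=table,
        metadata={
            "policy": ClosurePolicy(policy).value,
            "dv_critical_V": dv_critical,
            "monotone_non_decreasing": monotone,
            "units": "D_critical nm",
        },
    )
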