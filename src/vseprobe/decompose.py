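"""Splitting substate fields into noncovalent and hydrogen-bond contributions.

For an H-bonded nitrile the observed frequency shift Δν = ν − ν₀ mixes two
opposing sensitivities: the Stark tuning rate for the noncovalent part of
the field and a negative coefficient k for the H-bond part,

    Δν = |Δμ̃|·E_non + k·E_HB,      E_non + E_HB = E_i.

This 2×2 linear system is solved per component; H-bond-free components are
never decomposed — their entire field counts as noncovalent.  State-level
totals weight the per-component splits by mole fraction, and the magnitude
of the total H-bond field maps onto a conventional strength scale
(very weak < 15 ≤ weak < 30 ≤ medium < 45 ≤ strong < 60 ≤ very strong,
in MV/cm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .fields import SubstateSolution, VSECalibration

__all__ = [
    "ComponentDecomposition",
    "FieldDecomposition",
    "HBOND_CLASS_EDGES",
    "decompose_field",
    "classify_hbond",
    "decompose_solution",
    "aggregate_totals",
    "consistency_report",
]

#: lower-inclusive magnitude edges of the H-bond strength classes (MV/cm)
HBOND_CLASS_EDGES: tuple[tuple[float, str], ...] = (
    (0.0, "very weak"),
    (15.0, "weak"),
    (30.0, "medium"),
    (45.0, "strong"),
    (60.0, "very strong"),
)


def decompose_field(e_field: float, nu_rt: float, cal: VSECalibration) -> tuple[float, float]:
    """Split a substate field into (noncovalent, H-bond) parts.

    Solves Δν = |Δμ̃|·E_non + k·E_HB together with E_non + E_HB = E; the
    closed form is E_non = (Δν − k·E)/(|Δμ̃| − k), E_HB = E − E_non.
    Exact additivity E_non + E_HB = E holds by construction.
    """
    delta_nu = nu_rt - cal.nu0
    e_non = (delta_nu - cal.k_hbond * e_field) / (cal.tuning_rate - cal.k_hbond)
    return e_non, e_field - e_non


def classify_hbond(e_tot_hb: float) -> str:
    """H-bond strength class from the magnitude of the total H-bond field."""
    mag = abs(e_tot_hb)
    label = HBOND_CLASS_EDGES[0][1]
    for edge, name in HBOND_CLASS_EDGES:
        if mag >= edge:
            label = name
    return label


@dataclass
class ComponentDecomposition:
    """Noncovalent/H-bond split of one H-bonded substate field."""

    role: str
    x: float
    e_field: float
    nu_rt: float
    e_non: float
    e_hb: float
    delta_nu_non: float
    delta_nu_hb: float


@dataclass
class FieldDecomposition:
    """State-level noncovalent/H-bond decomposition and strength class."""

    variant_id: str
    state: str
    components: list[ComponentDecomposition]  # H-bonded components only
    e_tot_non: float
    e_tot_hb: float
    hbond_class: str
    e_sum: float


def aggregate_totals(
    solution: SubstateSolution, decomps: Sequence[ComponentDecomposition]
) -> tuple[float, float]:
    """Mole-fraction-weighted noncovalent and H-bond totals.

    Every H-bonded component of the solution must carry a decomposition;
    H-bond-free components contribute their full field to the noncovalent
    total.  Uses the solver's unrounded mole fractions.
    """
    by_role = {d.role: d for d in decomps}
    e_non_tot = 0.0
    e_hb_tot = 0.0
    for comp in solution.components:
        if comp.hbond:
            if comp.role not in by_role:
                raise ValueError(
                    f"{solution.variant_id}/{solution.state}: missing decomposition for "
                    f"H-bonded component {comp.role}"
                )
            d = by_role[comp.role]
            e_non_tot += comp.x * d.e_non
            e_hb_tot += comp.x * d.e_hb
        else:
            e_non_tot += comp.x * comp.e_field
    return e_non_tot, e_hb_tot


def decompose_solution(solution: SubstateSolution, cal: VSECalibration) -> FieldDecomposition:
    """Decompose every H-bonded component of a substate solution and aggregate."""
    decomps: list[ComponentDecomposition] = []
    for comp in solution.components:
        if not comp.hbond:
            continue
        e_non, e_hb = decompose_field(comp.e_field, comp.nu_rt, cal)
        decomps.append(
            ComponentDecomposition(
                role=comp.role,
                x=comp.x,
                e_field=comp.e_field,
                nu_rt=comp.nu_rt,
                e_non=e_non,
                e_hb=e_hb,
                delta_nu_non=cal.tuning_rate * e_non,
                delta_nu_hb=cal.k_hbond * e_hb,
            )
        )
    e_tot_non, e_tot_hb = aggregate_totals(solution, decomps)
    return FieldDecomposition(
        variant_id=solution.variant_id,
        state=solution.state,
        components=decomps,
        e_tot_non=e_tot_non,
        e_tot_hb=e_tot_hb,
        hbond_class=classify_hbond(e_tot_hb),
        e_sum=solution.e_sum,
    )


def consistency_report(solutions: Iterable[SubstateSolution]) -> tuple[pd.DataFrame, float]:
    """Per-state consistency deviations and their overall RMS.

    Each state contributes 100·|E_F,sum − E_F,tot|/|E_F,tot|; the overall
    figure is the root mean square over all variant/state rows.  States with
    a zero total field are excluded (with a NaN marker in the table).
    """
    rows = []
    devs = []
    for sol in solutions:
        dev = sol.deviation_pct
        rows.append(
            {
                "variant": sol.variant_id,
                "state": sol.state,
                "E_sum": sol.e_sum,
                "E_tot": sol.e_total,
                "deviation_pct": dev,
            }
        )
        if math.isfinite(dev):
            devs.append(dev)
    frame = pd.DataFrame(rows, columns=["variant", "state", "E_sum", "E_tot", "deviation_pct"])
    overall = float(np.sqrt(np.mean(np.square(devs)))) if devs else math.nan
    return frame, overall
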