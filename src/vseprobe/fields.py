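"""Electric fields from nitrile band intensities and frequencies.

Two independent routes convert IR observables into the electric field
projected onto the C≡N bond (MV/cm, signed; negative means pointing from N
to C in the convention used throughout):

* the **intensity route**: the transition dipole moment (TDM) is linear in
  the field, μ = μ₀ + A·E with A < 0, and proportional to the square root of
  the integral intensity.  The dark state Pfr — whose field E_F,tot,Pfr and
  ensemble TDM μ_Pfr are known from electronic-structure calculations —
  serves as an internal standard: μ_PP = μ_Pfr·√(I_PP/I_Pfr) and
  E_PP = E_Pfr·(μ_PP − μ₀)/(μ_Pfr − μ₀), in which A cancels;
* the **frequency route** (H-bond-free nitriles only): the linear Stark
  relation E = (ν − ν₀)/|Δμ̃| with tuning rate |Δμ̃| = 0.268 cm⁻¹/(MV/cm).

Coexisting probe substates resolved as band components carry mole fractions
x_i; applying the internal standard to a component intensity yields the
scaled TDM m_i = √x_i·μ_i rather than μ_i itself, and the substate system is
closed with Σx_i = 1.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import yaml

from .normalize import StateRecord

__all__ = [
    "VSECalibration",
    "VariantAnchors",
    "SubstateComponent",
    "SubstateSolution",
    "InfeasibleSolutionError",
    "load_calibration",
    "tdm_from_intensity",
    "total_field_photoproduct",
    "field_from_frequency",
    "scaled_tdm_components",
    "solve_substates",
    "fit_tdm_field_line",
]


class InfeasibleSolutionError(ValueError):
    """The substate closure produced an unphysical mole fraction or TDM."""


@dataclass(frozen=True)
class VSECalibration:
    """Constants of the linear VSE relations.

    Units: frequencies in cm⁻¹, fields in MV/cm, TDMs in (km·mol)^1/2.
    ``deb_D_reference`` documents the provenance of ``k_hbond`` (the slope of
    the benzonitrile/water relation before rescaling) and is not used
    numerically.
    """

    nu0: float = 2234.5
    tuning_rate: float = 0.268
    k_hbond: float = -0.2
    tdm_slope: float = -0.047  # A in mu = mu0 + A*E
    mu0_oCNF: float = 4.44
    mu0_pCNF: float = 7.04
    deb_D_reference: float = -0.317
    deb_C: float | None = None
    hbond_threshold: float = 2228.0

    def __post_init__(self) -> None:
        if self.tuning_rate <= 0:
            raise ValueError("tuning_rate must be positive")
        if self.k_hbond >= 0:
            raise ValueError("k_hbond must be negative")
        if self.tuning_rate == self.k_hbond:
            raise ValueError("tuning_rate and k_hbond must differ")
        if self.tdm_slope >= 0:
            raise ValueError("tdm_slope (A) must be negative")
        if self.mu0_oCNF <= 0 or self.mu0_pCNF <= 0:
            raise ValueError("zero-field TDMs must be positive")

    def mu0_for(self, label_type: str) -> float:
        try:
            return {"oCNF": self.mu0_oCNF, "pCNF": self.mu0_pCNF}[label_type]
        except KeyError:
            raise ValueError(f"unknown label type {label_type!r}; expected oCNF or pCNF") from None


@dataclass(frozen=True)
class VariantAnchors:
    """Per-variant Pfr internal standard: anchor field, ensemble TDM, RT intensity."""

    variant_id: str
    label_type: str  # oCNF or pCNF
    e_pfr_total: float  # MV/cm
    mu_pfr: float  # (km mol)^1/2
    i_pfr_rt: float  # area units

    def __post_init__(self) -> None:
        if self.label_type not in ("oCNF", "pCNF"):
            raise ValueError(f"label_type must be oCNF or pCNF, got {self.label_type!r}")
        if self.mu_pfr <= 0 or self.i_pfr_rt <= 0:
            raise ValueError("mu_pfr and i_pfr_rt must be positive")


def load_calibration(
    path: str | os.PathLike,
) -> tuple[VSECalibration, dict[str, VariantAnchors], dict]:
    """Read calibration constants, per-variant anchors and solver pins from YAML."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    cal = VSECalibration(**doc.get("calibration", {}))
    anchors = {
        name: VariantAnchors(variant_id=name, **block)
        for name, block in doc.get("variants", {}).items()
    }
    return cal, anchors, doc.get("pins", {}) or {}


# ---------------------------------------------------------------------------
# Intensity and frequency routes

def tdm_from_intensity(i_pp_rt: float, anchors: VariantAnchors) -> float:
    """TDM of a photoproduct population from its RT-normalized intensity.

    μ_PP = μ_Pfr · √(I_PP / I_Pfr): the Pfr ensemble is the internal standard,
    so only the intensity ratio matters, not the absorbance scale.
    """
    if i_pp_rt <= 0:
        raise ValueError(f"intensity must be positive, got {i_pp_rt}")
    return anchors.mu_pfr * math.sqrt(i_pp_rt / anchors.i_pfr_rt)


def total_field_photoproduct(mu_pp: float, anchors: VariantAnchors, cal: VSECalibration) -> float:
    """Total field of a photoproduct from its envelope TDM (A-free ratio form).

    E_PP = E_Pfr · (μ_PP − μ₀) / (μ_Pfr − μ₀).  The slope A cancels between
    the photoproduct and Pfr forms of the linear TDM/field relation, making
    the result independent of how A was calibrated.
    """
    mu0 = cal.mu0_for(anchors.label_type)
    denom = anchors.mu_pfr - mu0
    if abs(denom) < 1e-9:
        raise ZeroDivisionError(
            f"{anchors.variant_id}: Pfr TDM equals the zero-field TDM; internal standard degenerate"
        )
    return anchors.e_pfr_total * (mu_pp - mu0) / denom


def field_from_frequency(nu_rt: float, cal: VSECalibration) -> float:
    """Field of an H-bond-free nitrile from its RT frequency: (ν − ν₀)/|Δμ̃|."""
    return (nu_rt - cal.nu0) / cal.tuning_rate


def scaled_tdm_components(record: StateRecord, anchors: VariantAnchors) -> list[float]:
    """Scaled TDMs m_i = √x_i·μ_i from component intensities (internal standard)."""
    return [tdm_from_intensity(c.intensity_RT, anchors) for c in record.components]


def fit_tdm_field_line(samples: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """Least-squares line μ = μ₀ + A·E through (field, TDM) samples.

    Returns ``(mu0, A)``.  Used to (re)derive the TDM calibration from
    snapshot ensembles or printed substate pairs.
    """
    arr = np.asarray(samples, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need at least two (field, TDM) pairs")
    e, mu = arr[:, 0], arr[:, 1]
    if np.ptp(e) == 0:
        raise ValueError("field values are all identical; line is rank-deficient")
    slope, intercept = np.polyfit(e, mu, 1)
    return float(intercept), float(slope)


# ---------------------------------------------------------------------------
# Substate solver

@dataclass
class SubstateComponent:
    """Solved substate: population weight, TDM and field of one band component."""

    role: str
    x: float
    mu: float
    e_field: float
    scaled_tdm: float
    nu_rt: float
    hbond: bool


@dataclass
class SubstateSolution:
    """Per-state substate populations and fields, with consistency metrics.

    ``e_total`` is the envelope-derived (or, for Pfr, anchor) total field;
    ``e_sum`` is the independent mole-fraction-weighted sum of substate
    fields.  Their relative gap ``deviation_pct`` is the method's internal
    consistency metric.  For underdetermined two-H-bonded-component states,
    ``solution_family`` samples the one-parameter family and ``ambiguous``
    marks near-degenerate optima.
    """

    variant_id: str
    state: str
    components: list[SubstateComponent]
    e_total: float
    e_sum: float
    deviation_pct: float
    ambiguous: bool = False
    pinned: bool = False
    solution_family: list[dict] | None = None

    def component(self, role: str) -> SubstateComponent:
        for c in self.components:
            if c.role == role:
                return c
        raise KeyError(f"no component with role {role!r}")


def _weighted_sum(components: Iterable[SubstateComponent]) -> float:
    return sum(c.x * c.e_field for c in components)


def _deviation_pct(e_sum: float, e_total: float) -> float:
    if e_total == 0:
        return math.nan
    return 100.0 * abs(e_sum - e_total) / abs(e_total)


def _solve_free(comp, m: float, mu0: float, cal: VSECalibration) -> SubstateComponent:
    e1 = field_from_frequency(comp.nu_RT, cal)
    mu1 = mu0 + cal.tdm_slope * e1
    if mu1 <= 0:
        raise InfeasibleSolutionError(f"{comp.role}: calibration gives non-positive TDM {mu1:.3g}")
    x1 = (m / mu1) ** 2
    if not 0.0 < x1 < 1.0 + 1e-12:
        raise InfeasibleSolutionError(
            f"{comp.role}: mole fraction {x1:.4g} outside (0, 1) (m = {m:.4g}, mu = {mu1:.4g})"
        )
    return SubstateComponent(comp.role, min(x1, 1.0), mu1, e1, m, comp.nu_RT, False)


def _family_fields(m2: float, m3: float, x2: float, mu0: float, A: float) -> tuple[float, float, float, float]:
    x3 = 1.0 - x2
    mu2 = m2 / math.sqrt(x2)
    mu3 = m3 / math.sqrt(x3)
    return mu2, mu3, (mu2 - mu0) / A, (mu3 - mu0) / A


def solve_substates(
    record: StateRecord,
    anchors: VariantAnchors,
    cal: VSECalibration,
    e_total: float,
    *,
    pinned_x: dict[str, float] | None = None,
    family_grid: int = 999,
) -> SubstateSolution:
    """Recover mole fractions, TDMs and fields of the substates of one state.

    Three regimes, set by the H-bond flags of the components:

    * one H-bond-free + one H-bonded component — the free component's field
      follows from its frequency, fixing x₁ = (m₁/μ₁)²; closure gives
      x₂ = 1 − x₁, μ₂ = m₂/√x₂ and E₂ = (μ₂ − μ₀)/A;
    * a single component — x = 1; field from frequency if H-bond-free,
      from the TDM otherwise;
    * two H-bonded components — one-parameter family in x₂; the reported
      solution minimizes |E_F,sum − E_F,tot| unless ``pinned_x`` fixes x for
      one role, and the sampled family is attached either way.

    ``e_total`` is the envelope-derived total field used for the consistency
    metric (and, in the underdetermined regime, the selection objective).
    """
    mu0 = cal.mu0_for(anchors.label_type)
    A = cal.tdm_slope
    m = scaled_tdm_components(record, anchors)
    comps = record.components
    free = [i for i, c in enumerate(comps) if not c.hbond]
    bonded = [i for i, c in enumerate(comps) if c.hbond]

    solved: list[SubstateComponent] = []
    ambiguous = False
    pinned = False
    family: list[dict] | None = None

    if len(comps) == 1:
        c, mi = comps[0], m[0]
        if c.hbond:
            e = (mi - mu0) / A
            solved.append(SubstateComponent(c.role, 1.0, mi, e, mi, c.nu_RT, True))
        else:
            e = field_from_frequency(c.nu_RT, cal)
            solved.append(SubstateComponent(c.role, 1.0, mi, e, mi, c.nu_RT, False))
    elif len(bonded) <= 1:
        for i in free:
            solved.append(_solve_free(comps[i], m[i], mu0, cal))
        x_free = sum(c.x for c in solved)
        if bonded:
            i = bonded[0]
            xb = 1.0 - x_free
            if not 0.0 < xb < 1.0:
                raise InfeasibleSolutionError(
                    f"{record.variant_id}/{record.state}: H-bonded mole fraction {xb:.4g} outside (0, 1)"
                )
            mub = m[i] / math.sqrt(xb)
            solved.append(
                SubstateComponent(comps[i].role, xb, mub, (mub - mu0) / A, m[i], comps[i].nu_RT, True)
            )
        elif abs(x_free - 1.0) > 0.25:
            # all-free multi-component states have no closure; x_i are
            # independent estimates and should still roughly sum to one
            raise InfeasibleSolutionError(
                f"{record.variant_id}/{record.state}: free-component mole fractions sum to {x_free:.3g}"
            )
    elif len(free) == 0 and len(bonded) == 2:
        i2, i3 = bonded
        m2, m3 = m[i2], m[i3]
        xs = np.linspace(0.0, 1.0, family_grid + 2)[1:-1]
        family = []
        gaps = np.empty_like(xs)
        for j, x2 in enumerate(xs):
            mu2, mu3, e2, e3 = _family_fields(m2, m3, float(x2), mu0, A)
            e_sum = x2 * e2 + (1 - x2) * e3
            gaps[j] = abs(e_sum - e_total)
            family.append(
                {"x": float(x2), "e_fields": (e2, e3), "e_sum": float(e_sum), "gap": float(gaps[j])}
            )
        pin = None
        if pinned_x:
            for idx in (i2, i3):
                if comps[idx].role in pinned_x:
                    pin = (idx, pinned_x[comps[idx].role])
        if pin is not None:
            idx, xpin = pin
            x2 = xpin if idx == i2 else 1.0 - xpin
            pinned = True
        else:
            jbest = int(np.argmin(gaps))
            x2 = float(xs[jbest])
            # near-degenerate second optimum away from the first → ambiguous
            close = np.flatnonzero(gaps <= gaps[jbest] + 0.01 * max(gaps[jbest], 1e-9))
            if np.any(np.abs(xs[close] - x2) > 0.05):
                ambiguous = True
        mu2, mu3, e2, e3 = _family_fields(m2, m3, x2, mu0, A)
        solved.append(SubstateComponent(comps[i2].role, x2, mu2, e2, m2, comps[i2].nu_RT, True))
        solved.append(SubstateComponent(comps[i3].role, 1.0 - x2, mu3, e3, m3, comps[i3].nu_RT, True))
    else:
        raise InfeasibleSolutionError(
            f"{record.variant_id}/{record.state}: unsupported substate pattern "
            f"({len(free)} free, {len(bonded)} H-bonded components)"
        )

    for c in solved:
        if c.mu <= 0:
            raise InfeasibleSolutionError(f"{c.role}: non-positive TDM {c.mu:.3g}")
    solved.sort(key=lambda c: c.nu_rt)
    e_sum = _weighted_sum(solved)
    return SubstateSolution(
        variant_id=record.variant_id,
        state=record.state,
        components=solved,
        e_total=e_total,
        e_sum=e_sum,
        deviation_pct=_deviation_pct(e_sum, e_total),
        ambiguous=ambiguous,
        pinned=pinned,
        solution_family=family,
    )
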