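"""Temperature normalization of photoproduct bands against the Pfr reference.

Photocycle intermediates are cryo-trapped, so their band intensities and
frequencies are measured at trapping temperatures while the whole analysis is
anchored to the dark state Pfr at room temperature (300 K).  Assuming the
temperature dependence established for Pfr transfers to the photoproducts:

* intensities scale by the Pfr ratio, I(PP, RT) = I(PP, T) · I(Pfr, RT) / I(Pfr, T);
* frequencies keep the conjugate-band difference, ν(PP, RT) = ν(Pfr, RT) − (ν(Pfr, T) − ν(PP, T)).

Conjugate band components are matched across states by ascending-frequency
rank — the identity of the low/high band is tracked through the photocycle,
not re-assigned by proximity.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .bandfit import BandFit

__all__ = [
    "ComponentRecord",
    "StateRecord",
    "ConjugatePairing",
    "PairingError",
    "HBOND_THRESHOLD",
    "normalize_intensity",
    "normalize_frequency",
    "pair_conjugates",
    "flag_hbond",
    "normalize_state",
    "records_to_frame",
    "frame_to_records",
    "read_state_table",
    "write_state_table",
]

#: RT-normalized frequency above which a nitrile is classed as hydrogen bonded.
#: Sits between the observed classes (≤2227.1 vs ≥2229.0 cm⁻¹) and at the
#: benzonitrile 0%-water point; the boundary itself counts as non-H-bonded.
HBOND_THRESHOLD = 2228.0

STATE_TABLE_COLUMNS = ["variant", "state", "T_K", "role", "nu_T", "nu_RT", "I_T", "I_RT", "hbond"]


class PairingError(ValueError):
    """Conjugate band components could not be matched across states."""


@dataclass
class ComponentRecord:
    """One band component of one photocycle state, before/after normalization."""

    role: str  # P1, P2 or P3 in ascending RT frequency
    nu_T: float
    nu_RT: float
    intensity_T: float
    intensity_RT: float
    hbond: bool

    def __post_init__(self) -> None:
        if self.intensity_T <= 0 or self.intensity_RT <= 0:
            raise ValueError(f"component {self.role}: intensities must be positive")


@dataclass
class StateRecord:
    """Normalized envelope and component data for one variant/state."""

    variant_id: str
    state: str
    trap_temperature: float
    envelope_intensity_T: float
    envelope_intensity_RT: float
    components: list[ComponentRecord] = field(default_factory=list)
    single_component: bool = False

    def __post_init__(self) -> None:
        if self.envelope_intensity_T <= 0 or self.envelope_intensity_RT <= 0:
            raise ValueError("envelope intensities must be positive")
        self.components.sort(key=lambda c: c.nu_RT)

    def component_intensity_sum(self) -> float:
        return sum(c.intensity_RT for c in self.components)

    def check_conservation(self, tolerance: float = 0.01) -> None:
        """Assert Σ component intensities ≈ envelope intensity (mole-fraction closure)."""
        gap = abs(self.component_intensity_sum() - self.envelope_intensity_RT)
        if gap > tolerance * self.envelope_intensity_RT:
            raise ValueError(
                f"{self.variant_id}/{self.state}: component intensities sum to "
                f"{self.component_intensity_sum():.4g} vs envelope {self.envelope_intensity_RT:.4g}"
            )


@dataclass
class ConjugatePairing:
    """Rank-based match between Pfr and photoproduct band components."""

    pairs: list[tuple[int, int]]  # (pfr index, photoproduct index), ascending rank
    envelope_only: bool = False  # photoproduct handled at envelope level only


# ---------------------------------------------------------------------------
# Elementary normalization rules

def normalize_intensity(i_pp_T: float, i_pfr_T: float, i_pfr_RT: float) -> float:
    """Scale a trapping-temperature intensity to the RT Pfr reference."""
    if i_pp_T <= 0 or i_pfr_T <= 0 or i_pfr_RT <= 0:
        raise ValueError("intensities must be positive")
    return i_pp_T * (i_pfr_RT / i_pfr_T)


def normalize_frequency(nu_pp_T: float, nu_pfr_T: float, nu_pfr_RT: float) -> float:
    """Translate a frequency to RT, preserving the Pfr-minus-photoproduct gap."""
    return nu_pfr_RT - (nu_pfr_T - nu_pp_T)


def flag_hbond(nu_RT: float, threshold: float = HBOND_THRESHOLD) -> bool:
    """True when the RT-normalized frequency indicates a hydrogen-bonded nitrile."""
    return nu_RT > threshold


def pair_conjugates(pfr_fit: BandFit, pp_fit: BandFit) -> ConjugatePairing:
    """Match Pfr and photoproduct components by ascending-frequency rank.

    When the photoproduct resolves fewer components than Pfr (e.g. a single
    symmetric band), no component-level conjugates exist and the state is
    handled at the envelope level.
    """
    n_pfr, n_pp = len(pfr_fit.components), len(pp_fit.components)
    if n_pp >= n_pfr + 2:
        raise PairingError(
            f"photoproduct resolves {n_pp} components vs {n_pfr} in Pfr; no conjugate assignment"
        )
    if n_pp != n_pfr:
        return ConjugatePairing(pairs=[], envelope_only=True)
    return ConjugatePairing(pairs=[(i, i) for i in range(n_pfr)])


def _envelope_centroid(fit: BandFit) -> float:
    areas = np.array([c.area for c in fit.components])
    centers = np.array([c.center for c in fit.components])
    return float(np.sum(areas * centers) / np.sum(areas))


def normalize_state(
    pp_fit: BandFit,
    pfr_trap_fit: BandFit,
    pfr_rt_fit: BandFit,
    *,
    variant_id: str,
    state: str,
    trap_temperature: float,
    hbond_threshold: float = HBOND_THRESHOLD,
) -> StateRecord:
    """Build a normalized :class:`StateRecord` from band fits.

    ``pfr_trap_fit`` is the Pfr reference measured at the same trapping
    temperature as the photoproduct fit; ``pfr_rt_fit`` is the Pfr reference
    at 300 K.  The intensity scale factor is taken from the Pfr envelopes so
    that the component/envelope closure survives normalization exactly;
    frequencies are normalized per conjugate component.
    """
    if len(pfr_trap_fit.components) != len(pfr_rt_fit.components):
        raise PairingError(
            "Pfr reference fits at trapping and room temperature resolve different component counts"
        )
    i_pfr_T = pfr_trap_fit.total_area
    i_pfr_RT = pfr_rt_fit.total_area
    env_T = pp_fit.total_area
    env_RT = normalize_intensity(env_T, i_pfr_T, i_pfr_RT)

    pairing = pair_conjugates(pfr_trap_fit, pp_fit)
    components: list[ComponentRecord] = []
    if pairing.envelope_only:
        # single unresolved band: normalize its frequency against the Pfr
        # envelope centroid, its intensity against the Pfr envelope
        cen_trap = _envelope_centroid(pfr_trap_fit)
        cen_rt = _envelope_centroid(pfr_rt_fit)
        for comp in pp_fit.components:
            nu_rt = normalize_frequency(comp.center, cen_trap, cen_rt)
            components.append(
                ComponentRecord(
                    role="P1",
                    nu_T=comp.center,
                    nu_RT=nu_rt,
                    intensity_T=comp.area,
                    intensity_RT=normalize_intensity(comp.area, i_pfr_T, i_pfr_RT),
                    hbond=flag_hbond(nu_rt, hbond_threshold),
                )
            )
    else:
        for rank, (i_pfr, i_pp) in enumerate(pairing.pairs):
            pfr_trap_c = pfr_trap_fit.components[i_pfr]
            pfr_rt_c = pfr_rt_fit.components[i_pfr]
            pp_c = pp_fit.components[i_pp]
            nu_rt = normalize_frequency(pp_c.center, pfr_trap_c.center, pfr_rt_c.center)
            components.append(
                ComponentRecord(
                    role=f"P{rank + 1}",
                    nu_T=pp_c.center,
                    nu_RT=nu_rt,
                    intensity_T=pp_c.area,
                    intensity_RT=normalize_intensity(pp_c.area, i_pfr_T, i_pfr_RT),
                    hbond=flag_hbond(nu_rt, hbond_threshold),
                )
            )
    return StateRecord(
        variant_id=variant_id,
        state=state,
        trap_temperature=trap_temperature,
        envelope_intensity_T=env_T,
        envelope_intensity_RT=env_RT,
        components=components,
        single_component=pairing.envelope_only,
    )


# ---------------------------------------------------------------------------
# Tabular I/O (fixed column layout shared with the packaged fixture)

def records_to_frame(records: Iterable[StateRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        rows.append(
            {
                "variant": rec.variant_id,
                "state": rec.state,
                "T_K": rec.trap_temperature,
                "role": "env",
                "nu_T": np.nan,
                "nu_RT": np.nan,
                "I_T": rec.envelope_intensity_T,
                "I_RT": rec.envelope_intensity_RT,
                "hbond": np.nan,
            }
        )
        for c in rec.components:
            rows.append(
                {
                    "variant": rec.variant_id,
                    "state": rec.state,
                    "T_K": rec.trap_temperature,
                    "role": c.role,
                    "nu_T": c.nu_T,
                    "nu_RT": c.nu_RT,
                    "I_T": c.intensity_T,
                    "I_RT": c.intensity_RT,
                    "hbond": c.hbond,
                }
            )
    return pd.DataFrame(rows, columns=STATE_TABLE_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[StateRecord]:
    records: list[StateRecord] = []
    for (variant, state), group in df.groupby(["variant", "state"], sort=False):
        env = group[group["role"] == "env"]
        if len(env) != 1:
            raise ValueError(f"{variant}/{state}: expected exactly one envelope row, got {len(env)}")
        env = env.iloc[0]
        comps = []
        for _, row in group[group["role"] != "env"].iterrows():
            nu_rt = float(row["nu_RT"])
            hbond = row["hbond"]
            if isinstance(hbond, str):
                hbond = hbond.strip().lower() in ("true", "1", "yes")
            elif pd.isna(hbond):
                hbond = flag_hbond(nu_rt)
            comps.append(
                ComponentRecord(
                    role=str(row["role"]),
                    nu_T=float(row["nu_T"]) if pd.notna(row["nu_T"]) else nu_rt,
                    nu_RT=nu_rt,
                    intensity_T=float(row["I_T"]) if pd.notna(row["I_T"]) else float(row["I_RT"]),
                    intensity_RT=float(row["I_RT"]),
                    hbond=bool(hbond),
                )
            )
        records.append(
            StateRecord(
                variant_id=str(variant),
                state=str(state),
                trap_temperature=float(env["T_K"]) if pd.notna(env["T_K"]) else 300.0,
                envelope_intensity_T=float(env["I_T"]) if pd.notna(env["I_T"]) else float(env["I_RT"]),
                envelope_intensity_RT=float(env["I_RT"]),
                components=comps,
                single_component=len(comps) == 1,
            )
        )
    return records


def read_state_table(path: str | os.PathLike) -> list[StateRecord]:
    return frame_to_records(pd.read_csv(path))


def write_state_table(records: Iterable[StateRecord], path: str | os.PathLike) -> None:
    records_to_frame(records).to_csv(path, index=False)
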