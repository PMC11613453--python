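"""Synthetic nitrile spectra with known ground truth, plus the packaged fixture.

The forward model composes the same calibration relations the analysis
inverts: a substate with noncovalent field e_non and H-bond field e_hb has

    ν = ν₀ + |Δμ̃|·e_non + k·e_hb + thermal_shift
    μ = μ₀ + A·(e_non + e_hb)
    area ∝ x · μ² · global_intensity_scale · temperature_factor

and each state's envelope is the sum of Gaussian bands plus a polynomial
baseline and seeded additive Gaussian noise.  Because truths live strictly
in-model, the full pipeline is an exact inverse at zero noise — the basis of
the round-trip tests.  Real spectra differ in band shape, baseline behaviour
and the validity of the linear relations themselves; recovery here bounds
algorithmic error only.
"""

from __future__ import annotations

import importlib.resources
import json
import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .bandfit import GAUSS_AREA_FACTOR, Spectrum, write_spectrum
from .fields import VSECalibration, VariantAnchors, load_calibration
from .normalize import StateRecord, frame_to_records

__all__ = [
    "Substate",
    "GroundTruthState",
    "SimulationConfig",
    "PhotocycleDataset",
    "FixtureBundle",
    "forward_bands",
    "forward_spectrum",
    "generate_photocycle_dataset",
    "load_paper_fixture",
    "fixture_path",
]

ROOM_TEMPERATURE = 300.0


@dataclass
class Substate:
    """Ground-truth probe environment: population, field split, band width."""

    x: float
    e_non: float  # MV/cm
    e_hb: float = 0.0  # MV/cm; 0 for H-bond-free environments
    fwhm: float = 7.0  # cm-1

    def __post_init__(self) -> None:
        if not 0 < self.x <= 1:
            raise ValueError(f"mole fraction must be in (0, 1], got {self.x}")
        if self.fwhm <= 0:
            raise ValueError("fwhm must be positive")


@dataclass
class GroundTruthState:
    """All ground truth for one variant/state at one temperature."""

    variant_id: str
    label_type: str
    state: str
    substates: list[Substate]
    temperature: float = ROOM_TEMPERATURE
    temperature_factor: float = 1.0  # intensity scale relative to RT
    thermal_shift: float = 0.0  # cm-1, rigid frequency offset at this temperature

    def __post_init__(self) -> None:
        total = sum(s.x for s in self.substates)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"substate mole fractions sum to {total}, expected 1")
        if self.temperature_factor <= 0:
            raise ValueError("temperature_factor must be positive")


@dataclass
class SimulationConfig:
    seed: int = 0
    noise_sigma: float = 0.0  # fraction of max absorbance
    baseline: tuple[float, ...] = (0.0,)  # ascending powers of (nu - window center)
    grid_spacing: float = 0.25  # cm-1
    window: tuple[float, float] = (2210.0, 2250.0)
    global_intensity_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.grid_spacing > 0.5:
            raise ValueError("grid spacing must be <= 0.5 cm-1 to resolve nitrile bands")


def forward_bands(
    truth: GroundTruthState, cal: VSECalibration
) -> list[tuple[float, float, float]]:
    """Per-substate (center, TDM, mole fraction) from the calibration relations."""
    mu0 = cal.mu0_for(truth.label_type)
    out = []
    for s in truth.substates:
        nu = cal.nu0 + cal.tuning_rate * s.e_non + cal.k_hbond * s.e_hb + truth.thermal_shift
        mu = mu0 + cal.tdm_slope * (s.e_non + s.e_hb)
        if mu <= 0:
            raise ValueError(
                f"{truth.variant_id}/{truth.state}: field {s.e_non + s.e_hb} MV/cm gives "
                f"non-positive TDM {mu:.3g}"
            )
        out.append((nu, mu, s.x))
    return out


def forward_spectrum(
    truth: GroundTruthState,
    cal: VSECalibration,
    sim: SimulationConfig,
    anchors: VariantAnchors | None = None,
) -> Spectrum:
    """Emit the Gaussian-sum envelope of a ground-truth state.

    Integral band areas are x·μ²·scale·temperature_factor, so intensity
    ratios between states reproduce the TDM relations exactly.  Noise and
    baseline are seeded per (variant, state, temperature) so regenerating the
    same state is bit-identical.
    """
    lo, hi = sim.window
    n = int(round((hi - lo) / sim.grid_spacing)) + 1
    grid = lo + sim.grid_spacing * np.arange(n)
    center = 0.5 * (lo + hi)
    absorbance = np.polynomial.polynomial.polyval(grid - center, sim.baseline)

    for (nu, mu, x), s in zip(forward_bands(truth, cal), truth.substates):
        area = x * mu**2 * sim.global_intensity_scale * truth.temperature_factor
        height = area / (s.fwhm * GAUSS_AREA_FACTOR)
        sigma = s.fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
        absorbance = absorbance + height * np.exp(-0.5 * ((grid - nu) / sigma) ** 2)

    if sim.noise_sigma > 0:
        key = abs(hash((truth.variant_id, truth.state, round(truth.temperature, 3)))) % (2**31)
        rng = np.random.default_rng([sim.seed, key])
        absorbance = absorbance + rng.normal(
            0.0, sim.noise_sigma * float(np.max(np.abs(absorbance))), size=absorbance.shape
        )
    return Spectrum(
        grid,
        absorbance,
        variant_id=truth.variant_id,
        state=truth.state,
        temperature=truth.temperature,
    )


@dataclass
class PhotocycleDataset:
    """Spectra plus the manifest of everything the pipeline should recover."""

    spectra: dict[tuple[str, str, float], Spectrum]  # (variant, state, T) -> trace
    manifest: dict

    def write(self, outdir: str | os.PathLike) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        index = {}
        for (variant, state, temp), spec in self.spectra.items():
            name = f"{variant}_{state.replace('-', '')}_{temp:g}K.csv"
            write_spectrum(spec, outdir / name)
            index[name] = {"variant": variant, "state": state, "temperature": temp}
        manifest = dict(self.manifest)
        manifest["spectra"] = index
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)


def generate_photocycle_dataset(
    truths: Sequence[GroundTruthState],
    cal: VSECalibration,
    sim: SimulationConfig,
) -> PhotocycleDataset:
    """Simulate a full trapping experiment for one variant.

    ``truths`` must contain the Pfr state at room temperature and, for every
    photoproduct trapping temperature, a Pfr entry at that temperature (the
    reference measured before irradiation).  The manifest records all
    ground-truth quantities plus the internal-standard anchors implied by the
    RT Pfr truth, so recovery can be scored stage by stage.
    """
    pfr_by_temp = {
        round(t.temperature, 6): t for t in truths if t.state == "Pfr"
    }
    rt_key = round(ROOM_TEMPERATURE, 6)
    if rt_key not in pfr_by_temp:
        raise ValueError("dataset requires a Pfr ground truth at 300 K")
    for t in truths:
        if t.state != "Pfr" and round(t.temperature, 6) not in pfr_by_temp:
            raise ValueError(
                f"no Pfr reference at trapping temperature {t.temperature} K "
                f"(needed for {t.state})"
            )

    pfr_rt = pfr_by_temp[rt_key]
    bands_rt = forward_bands(pfr_rt, cal)
    i_pfr_rt = sim.global_intensity_scale * sum(x * mu**2 for _, mu, x in bands_rt)
    mu_pfr = math.sqrt(sum(x * mu**2 for _, mu, x in bands_rt))
    e_pfr_total = sum(
        s.x * (s.e_non + s.e_hb) for s in pfr_rt.substates
    )

    spectra: dict[tuple[str, str, float], Spectrum] = {}
    truth_records = []
    for t in truths:
        spectra[(t.variant_id, t.state, t.temperature)] = forward_spectrum(t, cal, sim)
        bands = forward_bands(t, cal)
        truth_records.append(
            {
                "variant": t.variant_id,
                "state": t.state,
                "temperature": t.temperature,
                "temperature_factor": t.temperature_factor,
                "thermal_shift": t.thermal_shift,
                "substates": [
                    {
                        "x": s.x,
                        "e_non": s.e_non,
                        "e_hb": s.e_hb,
                        "e_field": s.e_non + s.e_hb,
                        "fwhm": s.fwhm,
                        "nu": nu,
                        "mu": mu,
                    }
                    for s, (nu, mu, _) in zip(t.substates, bands)
                ],
            }
        )

    manifest = {
        "seed": sim.seed,
        "noise_sigma": sim.noise_sigma,
        "window": list(sim.window),
        "grid_spacing": sim.grid_spacing,
        "global_intensity_scale": sim.global_intensity_scale,
        "anchors": {
            pfr_rt.variant_id: {
                "label_type": pfr_rt.label_type,
                "e_pfr_total": e_pfr_total,
                "mu_pfr": mu_pfr,
                "i_pfr_rt": i_pfr_rt,
            }
        },
        "calibration": {
            "nu0": cal.nu0,
            "tuning_rate": cal.tuning_rate,
            "k_hbond": cal.k_hbond,
            "tdm_slope": cal.tdm_slope,
            "mu0_oCNF": cal.mu0_oCNF,
            "mu0_pCNF": cal.mu0_pCNF,
        },
        "truth": truth_records,
    }
    return PhotocycleDataset(spectra=spectra, manifest=manifest)


# ---------------------------------------------------------------------------
# Packaged fixture (published band-fit table and anchors for the four
# Agp2 cyanophenylalanine variants)

@dataclass
class FixtureBundle:
    records: list[StateRecord]
    anchors: dict[str, VariantAnchors]
    calibration: VSECalibration
    pins: dict
    table: pd.DataFrame  # raw fixture table incl. published TDM column


def fixture_path(name: str) -> Path:
    return Path(importlib.resources.files("vseprobe.data") / name)


def fixture_records_from_tdm(bundle: "FixtureBundle | None" = None) -> list[StateRecord]:
    """Fixture records with intensities reconstructed from the published TDMs.

    The published table prints intensities with fewer significant digits than
    the transition dipole moments derived from them; inverting the internal
    standard, I = I(Pfr, RT)·(μ/μ_Pfr)², recovers the unrounded intensities
    and gives the exact-input path used for regression against the published
    field tables.
    """
    from .normalize import ComponentRecord, StateRecord, flag_hbond

    bundle = bundle or load_paper_fixture()
    records: list[StateRecord] = []
    for (variant, state), group in bundle.table.groupby(["variant", "state"], sort=False):
        anc = bundle.anchors[str(variant)]

        def intensity(mu: float) -> float:
            return anc.i_pfr_rt * (mu / anc.mu_pfr) ** 2

        env = group[group["role"] == "env"].iloc[0]
        comps = []
        for _, row in group[group["role"] != "env"].iterrows():
            nu = float(row["nu_RT"])
            i_rt = intensity(float(row["mu"]))
            comps.append(
                ComponentRecord(
                    role=str(row["role"]),
                    nu_T=nu,
                    nu_RT=nu,
                    intensity_T=i_rt,
                    intensity_RT=i_rt,
                    hbond=str(row["hbond"]).strip().lower() in ("true", "1", "yes"),
                )
            )
        env_i = intensity(float(env["mu"]))
        records.append(
            StateRecord(
                variant_id=str(variant),
                state=str(state),
                trap_temperature=float(env["T_K"]),
                envelope_intensity_T=env_i,
                envelope_intensity_RT=env_i,
                components=comps,
                single_component=len(comps) == 1,
            )
        )
    return records


def load_paper_fixture() -> FixtureBundle:
    """Load the packaged normalized state table, anchors and calibration.

    The table carries the published RT-normalized intensities, frequencies
    and (for cross-checks) transition dipole moments of all four variants in
    all four photocycle states, together with the QM/MM-derived Pfr anchor
    constants.  One known inconsistency in the published component TDM of the
    Y165pCNF Lumi-F band (14.168 vs the envelope's 14.618) is resolved in
    favour of 14.618, the value consistent with the intensity relation.
    """
    table = pd.read_csv(fixture_path("agp2_state_table.csv"))
    records = frame_to_records(table)
    cal, anchors, pins = load_calibration(fixture_path("agp2_calibration.yaml"))
    return FixtureBundle(records=records, anchors=anchors, calibration=cal, pins=pins, table=table)
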