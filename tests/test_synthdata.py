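import json
import math

import numpy as np
import pytest

from vseprobe.bandfit import fit_bands
from vseprobe.decompose import decompose_field
from vseprobe.pipeline import analyze_spectra_dataset
from vseprobe.fields import VariantAnchors
from vseprobe.synthdata import (
    GroundTruthState,
    SimulationConfig,
    Substate,
    fixture_path,
    fixture_records_from_tdm,
    forward_bands,
    forward_spectrum,
    generate_photocycle_dataset,
    load_paper_fixture,
)


class TestForwardModel:
    def test_published_dark_state_band_centers(self, cal):
        """Ground-truth fields taken from the published decomposition reproduce
        the published band centers through the forward frequency model."""
        e1 = (2225.9 - cal.nu0) / cal.tuning_rate  # H-bond-free substate
        e2_non, e2_hb = decompose_field(-81.6778421, 2230.4, cal)
        truth = GroundTruthState(
            "Y165oCNF", "oCNF", "Pfr",
            [Substate(0.2477, e1), Substate(0.7523, e2_non, e2_hb)],
        )
        bands = forward_bands(truth, cal)
        assert bands[0][0] == pytest.approx(2225.9, abs=1e-6)
        assert bands[1][0] == pytest.approx(2230.4, abs=1e-6)

    def test_zero_field_substate_sits_at_nu0(self, cal, noiseless_sim):
        truth = GroundTruthState("V", "oCNF", "Pfr", [Substate(1.0, 0.0, 0.0)])
        spec = forward_spectrum(truth, cal, noiseless_sim)
        assert spec.wavenumbers[np.argmax(spec.absorbance)] == pytest.approx(2234.5, abs=0.1)
        assert forward_bands(truth, cal)[0][0] == 2234.5

    def test_fixed_seed_is_bit_identical(self, cal, two_substate_truth):
        sim = SimulationConfig(seed=42, noise_sigma=0.01)
        a = forward_spectrum(two_substate_truth, cal, sim)
        b = forward_spectrum(two_substate_truth, cal, sim)
        np.testing.assert_array_equal(a.absorbance, b.absorbance)

    def test_unphysical_truth_rejected(self, cal, noiseless_sim):
        # field so strong the linear TDM relation would go negative
        truth = GroundTruthState("V", "oCNF", "Pfr", [Substate(1.0, 20.0, 80.0)])
        with pytest.raises(ValueError, match="non-positive TDM"):
            forward_spectrum(truth, cal, noiseless_sim)


PFR_SUBSTATES = [Substate(0.24, -35.82), Substate(0.76, -25.10, -13.64)]


def build_photocycle(noise=0.0, seed=0):
    """Photocycle patterned on the F192pCNF band layout: an H-bond-free band
    near 2225 cm-1 and an H-bonded band near 2230.5 cm-1 in every state."""
    states = {
        "Lumi-F": ([Substate(0.38, -34.33), Substate(0.62, -17.63, -5.12)], 140.0, 1.25, 1.5),
        "Meta-F": ([Substate(0.40, -35.07), Substate(0.60, -25.69, -15.92)], 240.0, 1.1, 0.8),
    }
    truths = [GroundTruthState("SYN1", "pCNF", "Pfr", PFR_SUBSTATES)]
    for temp, factor, shift in {(140.0, 1.25, 1.5), (240.0, 1.1, 0.8)}:
        truths.append(
            GroundTruthState("SYN1", "pCNF", "Pfr", PFR_SUBSTATES, temperature=temp,
                             temperature_factor=factor, thermal_shift=shift)
        )
    for state, (subs, temp, factor, shift) in states.items():
        truths.append(
            GroundTruthState("SYN1", "pCNF", state, subs, temperature=temp,
                             temperature_factor=factor, thermal_shift=shift)
        )
    sim = SimulationConfig(seed=seed, noise_sigma=noise, grid_spacing=0.1)
    return generate_photocycle_dataset(truths, load_paper_fixture().calibration, sim)


class TestPhotocycleDataset:
    def test_missing_trap_reference_rejected(self, cal, noiseless_sim):
        truths = [
            GroundTruthState("V", "oCNF", "Pfr", [Substate(1.0, -30.0)]),
            GroundTruthState("V", "oCNF", "Lumi-F", [Substate(1.0, -35.0)], temperature=140.0),
        ]
        with pytest.raises(ValueError, match="no Pfr reference"):
            generate_photocycle_dataset(truths, cal, noiseless_sim)

    def test_zero_noise_end_to_end_recovery(self, cal):
        """Full pipeline (fit -> normalize -> solve) inverts the forward model."""
        dataset = build_photocycle(noise=0.0)
        anchors = {
            name: VariantAnchors(variant_id=name, **block)
            for name, block in dataset.manifest["anchors"].items()
        }
        result = analyze_spectra_dataset(dataset.spectra, anchors, cal)
        truth_by_state = {t["state"]: t for t in dataset.manifest["truth"]
                          if t["temperature"] != 300.0 or t["state"] == "Pfr"}
        for state in ("Pfr", "Lumi-F", "Meta-F"):
            sol = result.state("SYN1", state).solution
            subs = truth_by_state[state]["substates"]
            assert len(sol.components) == len(subs)
            for comp, sub in zip(sol.components, subs):
                assert comp.x == pytest.approx(sub["x"], abs=1e-6)
                assert comp.e_field == pytest.approx(sub["e_field"], abs=1e-6)

    def test_noisy_recovery_of_mole_fractions(self, cal):
        """Monte-Carlo: at 1% noise the median recovered x1 stays within 0.03."""
        errors = []
        for seed in range(10):
            dataset = build_photocycle(noise=0.01, seed=seed)
            anchors = {
                name: VariantAnchors(variant_id=name, **block)
                for name, block in dataset.manifest["anchors"].items()
            }
            result = analyze_spectra_dataset(dataset.spectra, anchors, cal)
            sol = result.state("SYN1", "Lumi-F").solution
            errors.append(abs(sol.components[0].x - 0.38))
        assert float(np.median(errors)) < 0.03

    def test_noise_scaling_of_area_recovery(self, cal):
        """Area recovery error scales at most linearly with the noise level.

        Least-squares errors are asymptotically proportional to the noise; the
        regression envelope asserts no superlinear amplification (basin jumps,
        degeneracy blow-ups) across a 20x noise ladder at fixed seeds.
        """
        truth = GroundTruthState("SYN1", "pCNF", "Pfr", PFR_SUBSTATES)
        true_areas = [x * mu**2 for _, mu, x in forward_bands(truth, cal)]

        def area_error(noise):
            errs = []
            for seed in range(1, 7):
                sim = SimulationConfig(seed=seed, noise_sigma=noise, grid_spacing=0.1)
                fit = fit_bands(forward_spectrum(truth, cal, sim), 2)
                errs.append(
                    sum(abs(c.area - a) / a for c, a in zip(fit.components, true_areas))
                )
            return float(np.median(errs))

        noises = np.array([0.001, 0.005, 0.02])
        medians = np.array([area_error(n) for n in noises])
        assert np.all(np.diff(medians) > 0)  # more noise, more error
        exponent = np.polyfit(np.log(noises), np.log(medians), 1)[0]
        assert exponent < 1.15


class TestPaperFixture:
    def test_fixture_values_match_published_table_verbatim(self):
        """Spot-check that fixture cells carry the printed strings exactly."""
        text = fixture_path("agp2_state_table.csv").read_text()
        for row in (
            "Y165oCNF,Pfr,300,P1,2225.9,2225.9,1.11,1.11,2.960,False",
            "F192pCNF,Pr,300,P2,2229.0,2229.0,1.528,1.528,8.864,True",
            "Y165pCNF,Pr,300,P3,2241.6,2241.6,1.686,1.686,7.640,True",
        ):
            assert row in text

    def test_anchor_constants(self, fixture_bundle):
        anc = fixture_bundle.anchors
        assert anc["F192pCNF"].e_pfr_total == -28.76
        assert anc["Y165oCNF"].mu_pfr == 7.767
        assert anc["Y165pCNF"].i_pfr_rt == 2.642
        assert fixture_bundle.calibration.tuning_rate == 0.268

    def test_component_envelope_closure(self, fixture_bundle):
        for record in fixture_bundle.records:
            record.check_conservation(tolerance=0.01)

    def test_sixteen_states_four_variants(self, fixture_bundle):
        assert len(fixture_bundle.records) == 16
        assert len({r.variant_id for r in fixture_bundle.records}) == 4

    def test_tdm_route_intensities_match_internal_standard(self, fixture_bundle):
        """Reconstructed unrounded intensities agree with the printed ones to ~1%."""
        by_key = {(r.variant_id, r.state): r for r in fixture_records_from_tdm(fixture_bundle)}
        for record in fixture_bundle.records:
            recon = by_key[(record.variant_id, record.state)]
            assert recon.envelope_intensity_RT == pytest.approx(
                record.envelope_intensity_RT, rel=0.01
            )
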