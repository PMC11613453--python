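import numpy as np
import pytest

from vseprobe.bandfit import FitConfig
from vseprobe.fields import VSECalibration, VariantAnchors
from vseprobe.synthdata import GroundTruthState, SimulationConfig, Substate, load_paper_fixture


@pytest.fixture(scope="session")
def fixture_bundle():
    return load_paper_fixture()


@pytest.fixture(scope="session")
def cal():
    return VSECalibration()


@pytest.fixture(scope="session")
def y165o_anchors():
    return VariantAnchors("Y165oCNF", "oCNF", e_pfr_total=-53.41, mu_pfr=7.767, i_pfr_rt=7.64)


@pytest.fixture
def two_substate_truth():
    """In-model two-substate dark state: one H-bond-free, one H-bonded band."""
    return GroundTruthState(
        "SYN1",
        "oCNF",
        "Pfr",
        [Substate(x=0.3, e_non=-32.0, e_hb=0.0), Substate(x=0.7, e_non=-45.0, e_hb=-37.0)],
    )


@pytest.fixture
def noiseless_sim():
    return SimulationConfig(seed=7, noise_sigma=0.0, grid_spacing=0.1)


@pytest.fixture
def fit_config():
    return FitConfig()


@pytest.fixture
def y165o_pfr_solution(cal):
    """Substate solution of the Y165oCNF dark state from published scaled TDMs."""
    from vseprobe.fields import solve_substates
    from vseprobe.normalize import ComponentRecord, StateRecord

    anchors = VariantAnchors("Y165oCNF", "oCNF", -53.41, 7.767, 7.64)
    comps = []
    for role, nu, m, hb in (("P1", 2225.9, 2.960, False), ("P2", 2230.4, 7.181, True)):
        i_rt = anchors.i_pfr_rt * (m / anchors.mu_pfr) ** 2
        comps.append(ComponentRecord(role, nu, nu, i_rt, i_rt, hb))
    env = sum(c.intensity_RT for c in comps)
    record = StateRecord("Y165oCNF", "Pfr", 300.0, env, env, comps)
    return solve_substates(record, anchors, cal, e_total=-53.41)
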