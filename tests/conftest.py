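import numpy as np
import pytest

import mnrm


@pytest.fixture(scope="session")
def wx() -> mnrm.WorkedExample:
    """The built-in three-item QOL + ERS worked example."""
    return mnrm.worked_example()


@pytest.fixture(scope="session")
def wx_order(wx):
    """Grid node indices in the worked example's printed column order."""
    return [wx.node_index(q, e) for e, q in wx.expected["grid_order"]]


@pytest.fixture(scope="session")
def recovery_study() -> mnrm.StyleStudy:
    """Synthetic trait + ERS study at recovery scale (N=2000, 20 items)."""
    design = mnrm.SimulationDesign(
        n_persons=2000,
        n_items=20,
        seed=7,
        R=np.array([[1.0, -0.18], [-0.18, 1.0]]),
    )
    return mnrm.make_style_study(design)


@pytest.fixture(scope="session")
def recovery_fit(recovery_study):
    """EM fit of the recovery study (shared across tests: ~25 s)."""
    model, summary = mnrm.fit_em(
        recovery_study.responses, recovery_study.scoring, tol=1e-4, max_iter=300
    )
    return model, summary


@pytest.fixture(scope="session")
def small_study() -> mnrm.StyleStudy:
    """Small synthetic study for fast estimation tests."""
    design = mnrm.SimulationDesign(
        n_persons=400,
        n_items=6,
        seed=42,
        R=np.array([[1.0, -0.2], [-0.2, 1.0]]),
    )
    return mnrm.make_style_study(design)
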