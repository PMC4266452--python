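import numpy as np
import pytest

import silicoqt as sq
from silicoqt.channel_pharm import Channel, ChannelAffinity, Source
from silicoqt.pacing import SolverSettings, pace_to_steady_state

# Scaled-down pacing defaults for the test suite: solver tolerances stay at
# the pipeline values (1e-6 / 1e-8); the pace budget is reduced so the whole
# suite runs on one CPU in minutes.  The steady-state criterion (1e-4
# relative) is comfortably converged for the control cells (see the fidelity
# test, which checks the resulting pace against a 1 µs reference).
TEST_TOL = 1e-4
TEST_MAX_PACES = 60


@pytest.fixture(scope="session")
def control_steady():
    """Per-model control steady state at 1 Hz (session-cached)."""
    out = {}
    for name in sq.MODEL_NAMES:
        spec, state = sq.instantiate(name)
        res = pace_to_steady_state(
            spec, state, solver=SolverSettings(),
            convergence_tol=TEST_TOL, max_paces=TEST_MAX_PACES,
        )
        assert res.converged, f"{name} control did not converge in tests' pace budget"
        out[name] = (spec, res)
    return out


def pure_ikr_compound(pic50: float, compound_id: str = "synthblocker") -> list:
    """A synthetic selective hERG blocker with a full Quattro panel
    (all non-hERG channels floored at pIC50 = 0)."""
    affs = [ChannelAffinity(compound_id, Channel.IKr, Source.Q, pic50)]
    for ch in (Channel.IKs, Channel.INa, Channel.ICaL, Channel.Ito):
        affs.append(ChannelAffinity(compound_id, ch, Source.Q, 0.0))
    return affs


@pytest.fixture(scope="session")
def pic50_panel():
    return sq.load_pic50_table()
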