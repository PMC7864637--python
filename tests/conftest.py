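import numpy as np
import pytest

import photonflc as pf


@pytest.fixture(scope="session")
def meta():
    return pf.InstrumentMeta()


@pytest.fixture(scope="session")
def two_state_streams():
    """Small two-state switching ensemble with ground truth (shared)."""
    comp = pf.two_state_component(k_u_to_q=2e4, k_q_to_u=1e4)
    cfg = pf.SimulationConfig(
        components=[comp], n_molecules=6, trace_duration_s=1.0, seed=42
    )
    streams, truth = pf.simulate_ensemble(cfg)
    return streams, truth, comp


def make_stream(macrotimes, microtimes=None, meta=None, molecule_id="m0"):
    macrotimes = np.asarray(macrotimes, dtype=float)
    if microtimes is None:
        microtimes = np.full(macrotimes.size, 1.0)
    return pf.PhotonStream(
        molecule_id=molecule_id,
        macrotimes=macrotimes,
        microtimes=np.asarray(microtimes, dtype=float),
        meta=meta or pf.InstrumentMeta(),
    )
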