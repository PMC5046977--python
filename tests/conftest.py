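import numpy as np
import pandas as pd
import pytest

import epitoc as e


@pytest.fixture
def tiny_beta():
    """2x2 beta matrix used for round-trip and scoring checks."""
    return e.BetaMatrix(
        pd.DataFrame(
            [[0.1, 0.2], [0.3, 0.4]],
            index=pd.Index(["cgA", "cgB"], name="probe_id"),
            columns=["s1", "s2"],
        )
    )


@pytest.fixture
def blood_cohort():
    """Small healthy single-tissue cohort shared across tests."""
    cfg = e.default_config("healthy-blood", seed=11)
    cfg = e.SimulationConfig(**{**cfg.__dict__, "n_samples": 200, "n_probes": 400})
    return e.simulate_cohort(cfg)


@pytest.fixture
def reference5():
    rng = np.random.default_rng(42)
    vals = rng.uniform(0.0, 1.0, size=(200, 5))
    return e.CellTypeReference(
        pd.DataFrame(
            vals,
            index=pd.Index([f"cg{i:04d}" for i in range(200)], name="probe_id"),
            columns=["Bcell", "Tcell", "Mono", "NK", "Gran"],
        )
    )
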