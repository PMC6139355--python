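import numpy as np
import pytest

import shuntsim as ss


@pytest.fixture(scope="session", autouse=True)
def warm_kernels():
    """Compile the integration kernels once so timing-sensitive tests measure
    the algorithm, not the JIT."""
    from shuntsim.oxygen import converge_saturations

    sol = ss.run_to_steady_state(ss.default_parameter_set(),
                                 controllers=False, vol_tol=1e-2)
    converge_saturations(sol, max_cycles=2, tol=np.inf)


@pytest.fixture(scope="session")
def quick_patient():
    """Default reference child converged under homeostatic control only
    (no pulmonary tuning, no structural adaptation) — cheap shared fixture."""
    params = ss.default_parameter_set()
    sol = ss.run_to_steady_state(params)
    return sol


@pytest.fixture(scope="session")
def frozen_patient(quick_patient):
    """The same patient re-converged with controllers frozen."""
    return ss.run_to_steady_state(quick_patient.params, init=quick_patient.state,
                                  controllers=False)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20180910)
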