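import numpy as np
import pytest

from ribokin import KineticParams, builtin_design, generate_velocity_matrix

# reference ground truth used throughout: the reported inhibition constants
# for tRNA (Ki, alpha) with plausible saturation parameters
KI_TRUE = 0.031
ALPHA_TRUE = 18.8
KM_TRUE = 50.0
KITHF_TRUE = 200.0
VMAX_TRUE = 1.0


@pytest.fixture(scope="session")
def truth_params() -> KineticParams:
    return KineticParams(vmax=VMAX_TRUE, km=KM_TRUE, ki_thf=KITHF_TRUE,
                         ki=KI_TRUE, alpha=ALPHA_TRUE)


@pytest.fixture(scope="session")
def noiseless_grid_series(truth_params):
    """Exact hyperbolic-competitive velocities on the THF x tRNA design."""
    design = builtin_design("thf-inhibitor-grid", cv=0.0, replicates=1)
    return generate_velocity_matrix(design, truth_params, seed=0)


@pytest.fixture(scope="session")
def noisy_grid_series(truth_params):
    """One realistic noisy dataset (5% CV, 3 replicates)."""
    design = builtin_design("thf-inhibitor-grid")
    return generate_velocity_matrix(design, truth_params, seed=42)


@pytest.fixture(autouse=True)
def _quiet_numpy():
    with np.errstate(all="ignore"):
        yield
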