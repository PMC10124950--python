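import numpy as np
import pytest

from numtune import HRFParams, build_numerosity_run, build_symbolic_run, inject_task_trials
from numtune.fitting import PredictionGrid, default_fit_config


@pytest.fixture(scope="session")
def hrf():
    return HRFParams()


@pytest.fixture(scope="session")
def symbolic_seq():
    return build_symbolic_run()


@pytest.fixture(scope="session")
def symbolic_task_seq():
    return inject_task_trials(build_symbolic_run(), seed=11)


@pytest.fixture(scope="session")
def localizer_seq():
    return build_numerosity_run()


@pytest.fixture(scope="session")
def linear_grid(symbolic_seq, hrf):
    return PredictionGrid(symbolic_seq, hrf, default_fit_config("linear"), "linear")


@pytest.fixture(scope="session")
def log_grid(localizer_seq, hrf):
    return PredictionGrid(localizer_seq, hrf, default_fit_config("log"), "log")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230419)
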