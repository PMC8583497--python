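import warnings

import pytest
from hypothesis import settings

settings.register_profile("deterministic", deadline=None, derandomize=True)
settings.load_profile("deterministic")

from mockupeval import AnalysisConfig, compute_measures, generate_scenario
from mockupeval.fixtures import recovery_layout, recovery_script

N_RECOVERY_RUNS = 20


@pytest.fixture(scope="session")
def config():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def recovery_runs(config):
    """20 seeded recovery-scenario simulations with their measure reports.

    Shared across the recovery, brute-force and conservation checks so the
    simulations are generated once per session.
    """
    layout = recovery_layout()
    runs = []
    for seed in range(N_RECOVERY_RUNS):
        script = recovery_script(n_interruptions=1 + seed % 3)
        log, truth = generate_scenario(script, layout, config, seed=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = compute_measures(log, layout, config)
        runs.append((seed, log, truth, report))
    return layout, runs
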