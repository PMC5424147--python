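import numpy as np
import pytest

from netresp import synth


@pytest.fixture(scope="session")
def small_scenario():
    return synth.small_scenario()


@pytest.fixture(scope="session")
def default_scenario_fi():
    return synth.default_scenario(include_pn=False)


@pytest.fixture(scope="session")
def small_cohort():
    return synth.make_cohort(synth.CohortSpec(n_subjects=8, seed=0))


@pytest.fixture(scope="session")
def small_sim(small_cohort, small_scenario):
    """Forward-modelled BOLD for 8 subjects on the small scenario."""
    return synth.simulate_task_bold(small_cohort, small_scenario, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(20231115)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full synthetic end-to-end run, shared across tests."""
    import time

    from netresp.pipeline import PipelineConfig, run_pipeline

    out = tmp_path_factory.mktemp("pipeline")
    t0 = time.monotonic()
    result = run_pipeline(PipelineConfig(seed=0, n_boot=300), out)
    elapsed = time.monotonic() - t0
    return {"result": result, "outdir": out, "elapsed_s": elapsed}
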