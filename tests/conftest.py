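import warnings

import pytest

import taumem as tm


@pytest.fixture(scope="session")
def effects_table2():
    return tm.preset_from_table("table2")


@pytest.fixture(scope="session")
def small_config():
    return tm.CohortConfig(n_per_cell=30, seed=42)


@pytest.fixture(scope="session")
def cohort_direct(small_config, effects_table2):
    return tm.generate_cohort(small_config, effects_table2)


@pytest.fixture(scope="session")
def cohort_raw(effects_table2):
    cfg = tm.CohortConfig(n_per_cell=30, seed=42, mode="raw")
    return tm.generate_cohort(cfg, effects_table2)


@pytest.fixture(scope="session")
def reference(small_config):
    return tm.generate_normative_reference(small_config, n=4000)


@pytest.fixture(scope="session")
def norms(reference):
    return tm.fit_norms(reference)


@pytest.fixture(scope="session")
def analysis_raw(cohort_raw, norms):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return tm.run_full_analysis(cohort_raw, norms=norms)
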