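import numpy as np
import pytest

from cnvstrat import phenotype_io as pio
from cnvstrat import synthetic_cohort as sc


@pytest.fixture(scope="session")
def schema():
    return pio.default_schema()


@pytest.fixture(scope="session")
def default_cohort(schema):
    """The default-configuration synthetic cohort (537 patients)."""
    return sc.simulate_cohort(sc.default_config(seed=0), schema)


@pytest.fixture(scope="session")
def small_config(schema):
    """A reduced two-class config (60 + 50 patients) for cheap end-to-end runs."""
    cfg = sc.default_config(seed=7)
    cfg.profiles[0].n = 60
    cfg.profiles[1].n = 50
    return cfg


@pytest.fixture(scope="session")
def clustered_default(schema, default_cohort):
    """Full clustering of the default cohort, shared across tests (slow)."""
    from cnvstrat import cluster_engine as ce

    return ce.cluster_cohort(default_cohort, schema, seed=0)


def make_record(pid="p1", **features):
    return pio.PatientRecord(pid, dict(features))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
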