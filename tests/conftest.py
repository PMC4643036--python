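import pytest

from durumir.preprocess import run_preprocess
from durumir.synthdata import SimulationConfig, simulate_study
from durumir import hairpin_discovery as hd


@pytest.fixture(scope="session")
def config():
    return SimulationConfig()


@pytest.fixture(scope="session")
def study(config):
    """The standard reduced-design synthetic study shared across tests."""
    return simulate_study(config, 42)


@pytest.fixture(scope="session")
def preprocessed(study, config):
    per_lib = {lib: [seq for _rid, seq, _q in recs] for lib, recs in study.reads.items()}
    return run_preprocess(
        per_lib, study.design, config.adapter3, study.contaminants, study.contaminant_classes
    )


@pytest.fixture(scope="session")
def discovered(study, preprocessed):
    return hd.discover(preprocessed.table, study.genome, study.mature_refs)
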