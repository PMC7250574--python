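import pytest

from regcircuit import pipeline, synthetic


@pytest.fixture(scope="session")
def default_config():
    return synthetic.SyntheticConfig(seed=0)


@pytest.fixture(scope="session")
def dataset(tmp_path_factory, default_config):
    """The default synthetic study, generated once per session."""
    out = tmp_path_factory.mktemp("dataset")
    ledger = synthetic.generate_dataset(default_config, out)
    return out, default_config, ledger


@pytest.fixture(scope="session")
def pipeline_result(dataset):
    out, _, _ = dataset
    return pipeline.run_pipeline(out)
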