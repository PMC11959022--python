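import pytest

from faersignal import faers_io
from faersignal.synthetic import example_config, generate_dataset


@pytest.fixture(scope="session")
def dataset(tmp_path_factory):
    """One messy synthetic dataset shared across the suite: duplicates,
    deleted cases, partial and missing dates all switched on."""
    cfg = example_config(n_reports=1500, seed=42)
    cfg.duplicate_fraction = 0.2
    cfg.deleted_fraction = 0.05
    cfg.partial_date_fraction = 0.08
    cfg.missing_rates = {"event_dt": 0.08, "start_dt": 0.05}
    out = tmp_path_factory.mktemp("dataset")
    truth = generate_dataset(cfg, out)
    return cfg, out, truth


@pytest.fixture(scope="session")
def linked(dataset):
    _, out, _ = dataset
    anomalies = faers_io.AnomalyLog()
    cases = faers_io.load_dataset(out, anomalies)
    return cases, anomalies
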