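import warnings

import pytest

from ne_pipeline.datasets import load_reference_tables, wheat_bran_frame
from ne_pipeline.energy_balance import analyze_experiment, load_records
from ne_pipeline.synthetic_data import reference_config, simulate_experiment


@pytest.fixture(scope="session")
def reference_tables():
    return load_reference_tables()


@pytest.fixture(scope="session")
def bran():
    """Chemistry + determined DE/ME/NE for the six wheat brans."""
    return wheat_bran_frame()


@pytest.fixture(scope="session")
def zero_noise_run(tmp_path_factory):
    """Noise-free synthetic herd run through the full CSV -> balance path."""
    config, diets = reference_config(seed=7, noise_cv=0.0)
    chamber, balance, truth = simulate_experiment(config, diets)
    d = tmp_path_factory.mktemp("sim")
    chamber.to_csv(d / "chamber_records.csv", index=False)
    balance.to_csv(d / "balance_records.csv", index=False)
    records = load_records(d / "chamber_records.csv", d / "balance_records.csv")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        per_pig, per_diet = analyze_experiment(records)
    return {
        "config": config,
        "diets": diets,
        "truth": truth,
        "records": records,
        "per_pig": per_pig,
        "per_diet": per_diet,
        "paths": (d / "chamber_records.csv", d / "balance_records.csv"),
    }
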