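import numpy as np
import pandas as pd
import pytest

from qaffp import basemodels, chemdata, synthdata


@pytest.fixture(scope="session")
def small_synth():
    """Two targets x 150 compounds, noise-free, with curation hazards."""
    cfg = synthdata.SynthConfig(
        n_targets=2,
        n_compounds_per_target=150,
        noise_sd=0.0,
        duplicate_rate=0.15,
        bad_relation_rate=0.05,
        salt_rate=0.2,
        n_cell_lines=1,
        seed=11,
    )
    records, molecules, truth = synthdata.generate_target_datasets(cfg)
    return cfg, records, molecules, truth


@pytest.fixture(scope="session")
def curated_small(small_synth):
    cfg, records, molecules, _ = small_synth
    std = chemdata.standardize_table(records)
    return chemdata.curate_all(records, std, chemdata.CurationConfig()), std


@pytest.fixture(scope="session")
def trained_base_model(curated_small):
    """One quickly-trained base model plus its fingerprint matrix."""
    curated, std = curated_small
    ds = curated["T000"]
    mols = [std[c] for c in ds.entries["compound_id"]]
    fps = chemdata.morgan_fingerprints(mols)
    model = basemodels.train_base_model(
        ds, fps, basemodels.ModelConfig(n_trees=30, cv_folds=5, seed=5)
    )
    return model, ds, fps


@pytest.fixture
def benchmark_results_balanced():
    """Hand-built balanced 2 datasets x 2 descriptors x 3 replicates table."""
    rows = []
    values = {
        ("D1", "morgan2"): [0.70, 0.72, 0.74],
        ("D1", "rv_qaffp"): [0.80, 0.82, 0.78],
        ("D2", "morgan2"): [0.60, 0.58, 0.62],
        ("D2", "rv_qaffp"): [0.90, 0.95, 0.85],
    }
    for (ds, desc), vals in values.items():
        for rep, v in enumerate(vals):
            rows.append(
                {"dataset": ds, "descriptor": desc, "replicate": rep, "rmse_test": v}
            )
    return pd.DataFrame(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
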