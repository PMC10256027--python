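import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "repro",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """One-variety 12-sample dataset shared by CV and pipeline tests."""
    from dataclasses import replace

    from mustspec.synthetic import TABLE1_RANGES, VarietyProfile, default_config, generate_dataset

    cfg = replace(
        default_config(seed=99),
        varieties=(VarietyProfile("Riesling", TABLE1_RANGES["Riesling"], 12),),
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_design(small_dataset):
    """Preprocessed design matrix, y per analyte, and groups for the
    small dataset."""
    import numpy as np

    from mustspec.io import ANALYTES
    from mustspec.spectra import preprocess

    processed = [preprocess(s) for s in small_dataset.spectra]
    X = np.vstack([s.values for s in processed])
    groups = np.array([s.sample_id for s in processed])
    ref = small_dataset.primary_reference.set_index("sample_id")
    ys = {a: np.array([ref.loc[g, f"{a}_g_l"] for g in groups]) for a in ANALYTES}
    return X, ys, groups
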