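import numpy as np
import pandas as pd
import pytest

from metafork.io_formats import METABOLITE, OmicsMatrix, SampleDesign
from metafork.preprocess import PreprocessConfig, impute_min, log_transform
from metafork.synthetic_data import GeneratorConfig, generate


@pytest.fixture
def rng():
    return np.random.default_rng(20231108)


@pytest.fixture(scope="session")
def default_dataset():
    """One seeded draw of the default study design (12/11 + nested 8/8)."""
    return generate(GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def log_dataset(default_dataset):
    """The same draw, imputed, log-transformed and concatenated cross-omic."""
    metabolites, transcripts, design, truth = default_dataset
    cfg = PreprocessConfig(keep_all=True)
    m = OmicsMatrix.concat(
        [log_transform(impute_min(metabolites), cfg), log_transform(transcripts, cfg)]
    )
    return m, design, truth


def make_matrix(values: np.ndarray, features=None, samples=None, log_scale=False,
                omic_type=METABOLITE) -> OmicsMatrix:
    """Small helper: wrap a raw array as a single-omic matrix."""
    values = np.asarray(values, dtype=float)
    features = features or [f"f{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    df = pd.DataFrame(values, index=features, columns=samples)
    return OmicsMatrix.build(df, omic_type, log_scale=log_scale)


def make_design(n_control: int, n_treatment: int) -> SampleDesign:
    return SampleDesign(
        tuple(f"s{i}" for i in range(n_control + n_treatment)),
        tuple(["control"] * n_control + ["treatment"] * n_treatment),
    )
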