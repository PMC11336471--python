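import pytest

from paerisk.config import default_config
from paerisk.synthetic import moment_match_exact, study_specs


@pytest.fixture(scope="session")
def cfg():
    return default_config()


@pytest.fixture(scope="session")
def male(cfg):
    return cfg.factors("male")


@pytest.fixture(scope="session")
def female(cfg):
    return cfg.factors("female")


@pytest.fixture(scope="session")
def exact_samples(cfg):
    """Both sections, moments matched exactly to the configured targets."""
    specs = study_specs(
        cfg.concentration_targets, cfg.section_sizes, cfg.rank_correlations, seed=42
    )
    samples = []
    for spec in specs:
        samples.extend(moment_match_exact(spec))
    return samples
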