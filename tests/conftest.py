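import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from iecdeg import ArraySimConfig, generate_array_dataset, \
    generate_qpcr_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """500-gene dataset at the default study conditions, fixed seed."""
    return generate_array_dataset(ArraySimConfig(n_genes=500, seed=42))


@pytest.fixture(scope="session")
def clean_dataset():
    """Noise-free (no background) dataset with uniform f = 0.10."""
    cfg = ArraySimConfig(n_genes=400, contamination_fractions=(0.10,) * 4,
                         background_sd=0.0, cv_within=0.0, seed=7)
    return generate_array_dataset(cfg)


@pytest.fixture(scope="session")
def qpcr_noiseless():
    """Noise-free qPCR dataset with one 4-fold upregulated gene."""
    return generate_qpcr_dataset(
        {"active_cd": 5, "control": 5}, ["IRF1", "SPINK4"],
        efficiency=2.0, ct_noise_sd=0.0, seed=3,
        fold_changes={"IRF1": {"active_cd": 4.0}})
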