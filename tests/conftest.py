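import numpy as np
import pandas as pd
import pytest

from mirlink.config import PipelineConfig
from mirlink.simulate import SimulationConfig, simulate_dataset


@pytest.fixture
def study_config():
    """The default study design: 4 donor pairs, 20 q-miRNAs x ~15 targets."""
    return SimulationConfig(seed=7)


@pytest.fixture
def small_config():
    """A scaled-down design for fast structural tests."""
    return SimulationConfig(
        n_mirna_q=5, n_mirna_a=8, n_genes_q=10, n_genes_a=30, n_genes_bg=10,
        targets_per_q_mirna=6.0, targets_per_a_mirna=1.0, seed=11,
    )


@pytest.fixture
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture
def demo_pipeline_config(small_config):
    return PipelineConfig(simulation=small_config)


@pytest.fixture
def toy_sheet():
    rows = [
        ("qHSC_D1", "HSC", "quiescent", "D1"),
        ("qHSC_D2", "HSC", "quiescent", "D2"),
        ("qHSC_D3", "HSC", "quiescent", "D3"),
        ("aHSC_D1", "HSC", "activated", "D1"),
        ("aHSC_D2", "HSC", "activated", "D2"),
        ("aHSC_D3", "HSC", "activated", "D3"),
        ("HEP_1", "hepatocyte", "n/a", "H1"),
        ("HEP_2", "hepatocyte", "n/a", "H2"),
        ("LSEC_1", "LSEC", "n/a", "L1"),
        ("LSEC_2", "LSEC", "n/a", "L2"),
    ]
    return pd.DataFrame(rows, columns=["sample_id", "cell_type", "state", "donor_id"])
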