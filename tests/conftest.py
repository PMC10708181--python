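import numpy as np
import pandas as pd
import pytest

from protturn import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Small noiseless one-organ dataset: exact exponential decay."""
    cfg = SimulationConfig(
        organs=["lung"],
        oxygen_levels=["21"],
        reference_oxygen="21",
        n_proteins=12,
        peptides_per_protein=(2, 4),
        noise_cv=0.0,
        missing_rate=0.0,
        loading_factor_sigma=0.0,
        seed=11,
    )
    return cfg, simulate_dataset(cfg)


@pytest.fixture(scope="session")
def noisy_dataset():
    """Two-oxygen noisy dataset at the default noise level."""
    cfg = SimulationConfig(
        organs=["lung"],
        oxygen_levels=["8", "21"],
        reference_oxygen="21",
        n_proteins=30,
        peptides_per_protein=(4, 6),
        frac_affected=0.3,
        effect_fc_range=(2.0, 2.0),
        missing_rate=0.05,
        seed=7,
    )
    return cfg, simulate_dataset(cfg)


@pytest.fixture()
def toy_abundance():
    """Hand-sized abundance/sample tables with a 2-peptide panel protein."""
    samples = pd.DataFrame(
        {
            "sample_id": ["s0a", "s0b", "s4a"],
            "organ": "lung",
            "oxygen": "21",
            "time_days": [0.0, 0.0, 4.0],
            "replicate": [1, 2, 1],
        }
    )
    rows = []
    for pep, prot, vals in [
        ("LLp1", "LL1", [100.0, 100.0, 100.0]),
        ("LLp2", "LL1", [50.0, 50.0, 50.0]),
        ("Ap1", "A", [10.0, 10.0, 10.0 * np.exp(-0.8)]),
        ("Ap2", "A", [20.0, 20.0, 20.0 * np.exp(-0.8)]),
    ]:
        for sid, v in zip(samples["sample_id"], vals):
            rows.append(
                {"peptide_id": pep, "protein_id": prot, "sample_id": sid, "abundance": v}
            )
    return pd.DataFrame(rows), samples, ["LL1"]
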