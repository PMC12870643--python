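import numpy as np
import pandas as pd
import pytest

from methewas import SimulationConfig, generate_dataset
from methewas.annotate import ProbeAnnotation


@pytest.fixture(scope="session")
def signal_dataset():
    """Small cohort with strong planted phenotype and smoking effects."""
    cfg = SimulationConfig(
        n_samples=200,
        n_probes=400,
        n_cases=60,
        n_causal=5,
        causal_effect_range=(0.04, 0.06),
        n_smoking_probes=5,
        smoking_effect_range=(0.04, 0.06),
        n_bmi_probes=5,
        n_blocks=4,
        block_size=5,
        block_rho=0.8,
        markers_per_type=5,
        confounding_strength=0.3,
        covariate_missing_rate=0.05,
        seed=7,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def null_dataset():
    """Cohort with no planted effects of any kind."""
    cfg = SimulationConfig(
        n_samples=200,
        n_probes=300,
        n_cases=60,
        n_causal=0,
        n_smoking_probes=0,
        n_bmi_probes=0,
        confounding_strength=0.0,
        markers_per_type=5,
        covariate_missing_rate=0.0,
        seed=13,
    )
    return generate_dataset(cfg)


@pytest.fixture()
def toy_annotation():
    """Three islands on one chromosome plus probes in every context."""
    probes = pd.DataFrame(
        {
            "chrom": ["1"] * 6 + ["2"],
            "pos": [1000, 5000, 5500, 7000, 12000, 50000, 300],
            "gene": ["GA", "GB;GC", "", "GB", "GD", "", "GE"],
        },
        index=[f"p{i}" for i in range(7)],
    )
    islands = {"1": np.array([[5000, 6000], [20000, 21000]])}
    return ProbeAnnotation(probes, islands)
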