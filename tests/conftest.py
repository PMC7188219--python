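import numpy as np
import pandas as pd
import pytest

from mrcost.simulate import (
    SnpPanel,
    StructuralParams,
    default_bmi_panel,
    simulate_unrelated_cohort,
)


@pytest.fixture(scope="session")
def panel():
    """Default 79-SNP BMI-like panel, no pleiotropy."""
    return default_bmi_panel(seed=0)


@pytest.fixture(scope="session")
def small_panel():
    """Hand-built 3-SNP panel with known parameters."""
    return SnpPanel(
        snp_id=np.array(["rs1", "rs2", "rs3"]),
        chrom=np.array([1, 1, 2]),
        pos_bp=np.array([1000, 500_000, 1000]),
        effect_allele=np.array(["A", "C", "G"]),
        other_allele=np.array(["G", "T", "A"]),
        eaf=np.array([0.3, 0.4, 0.25]),
        gamma=np.array([0.15, 0.15, 0.15]),
        alpha=np.zeros(3),
    )


@pytest.fixture(scope="session")
def params():
    return StructuralParams()


@pytest.fixture(scope="session")
def cohort(panel, params):
    """Medium unrelated cohort reused across read-only tests."""
    return simulate_unrelated_cohort(panel, params, 20_000, seed=11)


@pytest.fixture(scope="session")
def tiny_assoc_frame():
    """A 3-SNP association table for harmonization/clumping tests."""
    return pd.DataFrame(
        {
            "snp": ["rs1", "rs2", "rs3"],
            "chr": [1, 1, 2],
            "pos": [1000, 500_000, 1000],
            "effect_allele": ["A", "C", "G"],
            "other_allele": ["G", "T", "A"],
            "eaf": [0.3, 0.4, 0.25],
            "beta": [0.2, -0.1, 0.3],
            "se": [0.02, 0.02, 0.03],
            "pval": [1e-10, 1e-9, 1e-8],
            "n": [10_000, 10_000, 10_000],
        }
    )
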