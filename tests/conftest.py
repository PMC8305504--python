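import numpy as np
import pandas as pd
import pytest

from psipath import SimConfig, simulate_cohort, quantify_cohort, strict_cascade


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared across read-only tests."""
    return simulate_cohort(SimConfig(seed=11))


@pytest.fixture(scope="session")
def default_psi(default_cohort):
    matrix, audit = quantify_cohort(default_cohort)
    return matrix


@pytest.fixture(scope="session")
def filtered_psi(default_psi):
    filtered, reports = strict_cascade(default_psi)
    return filtered


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_meta():
    """A tiny balanced two-tissue, two-ancestry, two-disease design."""
    rows = []
    for i in range(8):
        for tissue in ("ileum", "rectum"):
            for rep in (1, 2):
                rows.append(
                    {
                        "sample_id": f"I{i:02d}_{tissue[0].upper()}{rep}",
                        "individual_id": f"I{i:02d}",
                        "location": tissue,
                        "ancestry": "European" if i % 2 == 0 else "African",
                        "disease": "CD" if i < 4 else "UC",
                        "status": "established",
                        "group_label": "differentiated",
                    }
                )
    return pd.DataFrame(rows).set_index("sample_id")
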