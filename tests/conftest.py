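import numpy as np
import pandas as pd
import pytest

from stressmir import CountMatrix, simulate


@pytest.fixture(scope="session")
def small_config():
    return simulate.DesignConfig(
        n_mirna=60,
        n_replicates=2,
        baseline_mean=100.0,
        dispersion=0.05,
        effect_log2fc=3.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_truth(small_config):
    return simulate.generate_truth(small_config)


@pytest.fixture(scope="session")
def small_counts(small_truth, small_config):
    return simulate.simulate_counts(small_truth, small_config)


@pytest.fixture()
def tiny_cm():
    """Four conditions x two replicates, eight miRNAs, hand-sized counts."""
    rng = np.random.default_rng(3)
    samples = []
    for ci, cond in enumerate(["C0", "C1", "C2", "C3"]):
        for r in (1, 2):
            samples.append((f"s{ci}{r}", cond, r))
    sheet = pd.DataFrame(
        samples, columns=["sample_id", "condition", "replicate"]
    ).set_index("sample_id")
    counts = pd.DataFrame(
        rng.poisson(50, size=(8, 8)) + 1,
        index=[f"mir-{i}" for i in range(8)],
        columns=sheet.index,
    )
    return CountMatrix(counts, sheet)
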