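import numpy as np
import pandas as pd
import pytest

from heatortho.io import CountMatrix, SampleSheet
from heatortho.simulate import SimulationConfig, simulate_experiment


@pytest.fixture(scope="session")
def small_experiment():
    """A 400-pair simulated experiment shared across read-only tests."""
    cfg = SimulationConfig(n_orthologs=400, seed=42)
    return simulate_experiment(cfg)


@pytest.fixture()
def tiny_counts():
    df = pd.DataFrame(
        [[10, 0], [5, 7]], index=["g1", "g2"], columns=["s1", "s2"]
    )
    return CountMatrix(df)


@pytest.fixture(scope="session")
def two_species_sheet():
    rows = []
    conditions = ("CM", "CN", "HW1M", "HW1N", "HW2N", "HW3N", "R1N", "CR2N", "R2N")
    for sp in ("A", "B"):
        for cond in conditions:
            for rep in (1, 2, 3):
                rows.append((f"{sp}_{cond}_{rep}", sp, cond, rep))
    return SampleSheet(
        pd.DataFrame(rows, columns=["sample_id", "species", "condition", "replicate"])
    )


def nb_counts(rng, mean, dispersion, size):
    """Direct NB sampler used as an independent fixture generator."""
    if dispersion == 0:
        return rng.poisson(mean, size=size)
    k = 1.0 / dispersion
    return rng.negative_binomial(k, k / (k + mean), size=size)
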