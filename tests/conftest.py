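import numpy as np
import pytest

from icaflow.io import ExpressionMatrix, SampleInfo
from icaflow.simulate import SimulationConfig, simulate_dataset


def make_samples(m, distances=None, genders=None, paired=False):
    """Small hand-built sample lists for unit tests."""
    samples = []
    for j in range(m):
        if paired:
            subj, tp = f"P{j // 2}", ("pre" if j % 2 == 0 else "post")
        else:
            subj, tp = f"P{j}", "pre"
        d = 0.0 if distances is None else float(distances[j])
        g = ("male" if j % 2 == 0 else "female") if genders is None else genders[j]
        if tp == "pre":
            d = 0.0 if distances is None else d
        samples.append(SampleInfo(f"S{j}", subj, tp, g, d))
    return samples


def make_matrix(values, distances=None, genders=None, paired=False):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    return ExpressionMatrix(
        [f"F{i}" for i in range(n)],
        make_samples(m, distances=distances, genders=genders, paired=paired),
        values,
    )


@pytest.fixture(scope="session")
def default_sim():
    """One default-config synthetic study shared across tests."""
    return simulate_dataset(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def clean_sim():
    """A structure-free study: no modes, no subject effects, planted effects only."""
    cfg = SimulationConfig(seed=42, k_modes=0, subject_sd=0.0)
    return simulate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
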