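import numpy as np
import pandas as pd
import pytest

from mixbench import (
    MixtureDesign,
    make_default_design,
    simulate_mixture_counts,
    simulate_reference_profiles,
)

DESIGN_PROPORTIONS = (1.0, 0.75, 0.5, 0.25, 0.0)


def titration_proportions(n_replicates: int = 3) -> np.ndarray:
    """Proportion vector of the good samples of the default design."""
    return np.repeat(DESIGN_PROPORTIONS, n_replicates).astype(float)


def noise_free_logcpm(X, Y, n_replicates: int = 3) -> tuple[pd.DataFrame, np.ndarray]:
    """Forward-generate log2-CPM from the mixture dose-response mean."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    p = titration_proportions(n_replicates)
    mu = np.log2(p[None, :] * X[:, None] + (1.0 - p)[None, :] * Y[:, None])
    df = pd.DataFrame(
        mu,
        index=[f"g{i}" for i in range(len(X))],
        columns=[f"s{i}" for i in range(len(p))],
    )
    return df, p


def random_reference(rng, n_genes, lfc_sd=1.5, meanlog=4.0, sdlog=1.5):
    """Raw (X, Y) concentration draws for forward-generation in tests."""
    X = rng.lognormal(meanlog * np.log(2), sdlog * np.log(2), n_genes)
    Y = X / np.exp2(rng.normal(0.0, lfc_sd, n_genes))
    return X, Y


@pytest.fixture(scope="session")
def default_design() -> MixtureDesign:
    return make_default_design()


@pytest.fixture(scope="session")
def small_simulation(default_design):
    """A 300-gene simulated experiment shared by cheap tests."""
    ref = simulate_reference_profiles(300, de_fraction=0.2, lfc_sd=2.0, seed=11)
    counts = simulate_mixture_counts(ref, default_design, lib_size_mean=3e5, seed=11)
    return ref, default_design, counts
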