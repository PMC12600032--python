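import numpy as np
import pandas as pd
import pytest

from foreco import synthetic


def dbh_for_basal_area(ba_m2: float) -> float:
    """DBH (cm) of a stem with the given basal area (m^2)."""
    return 200.0 * np.sqrt(ba_m2 / np.pi)


@pytest.fixture
def two_species_plot() -> pd.DataFrame:
    """One plot: spA with 3 stems (total BA 0.6 m^2) in both subplots,
    spB with 1 stem (BA 0.2 m^2) in one subplot."""
    d = dbh_for_basal_area(0.2)
    return pd.DataFrame({
        "plot_id": ["p1"] * 4,
        "subplot_id": [1, 1, 2, 2],
        "species": ["spA", "spA", "spA", "spB"],
        "dbh_cm": [d, d, d, d],
    })


@pytest.fixture(scope="session")
def zero_noise_data():
    cfg = synthetic.zero_noise_config(seed=11)
    trees, plots, truth = synthetic.generate_inventory(cfg)
    return cfg, trees, plots, truth


@pytest.fixture(scope="session")
def moderate_noise_data():
    cfg = synthetic.moderate_noise_config(seed=12)
    trees, plots, truth = synthetic.generate_inventory(cfg)
    return cfg, trees, plots, truth


def random_abundance_matrix(rng, n_sites=6, n_species=10) -> pd.DataFrame:
    """Small random site x species count matrix with positive site totals."""
    X = rng.poisson(2.0, size=(n_sites, n_species))
    for i in range(n_sites):
        if X[i].sum() == 0:
            X[i, rng.integers(n_species)] = 1
    return pd.DataFrame(
        X, index=[f"s{i}" for i in range(n_sites)],
        columns=[f"sp{j}" for j in range(n_species)],
    )
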