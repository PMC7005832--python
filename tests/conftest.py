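import numpy as np
import pandas as pd
import pytest

from paleocomm.occurrences import AbundanceTable, TimeBinScheme
from paleocomm.synthetic import ScenarioConfig, preset, simulate


@pytest.fixture
def tiny_scheme():
    return TimeBinScheme(("bin00", "bin01", "bin02"))


@pytest.fixture
def tiny_table(tiny_scheme):
    """Three samples, four species in three genera, three bins."""
    counts = pd.DataFrame(
        [[30, 20, 10, 0], [25, 0, 15, 60], [0, 5, 0, 45]],
        index=["s1", "s2", "s3"],
        columns=["Ostrea alpha", "Ostrea sp.", "Corbula beta", "Turritella gamma"],
    )
    meta = pd.DataFrame(
        {"time_bin": [0, 1, 2], "locality": ["a", "b", "c"],
         "lithology": ["carbonate", "clastic", "mixed"]},
        index=counts.index,
    )
    taxonomy = pd.DataFrame(
        {"genus": ["Ostrea", "Ostrea", "Corbula", "Turritella"],
         "family": ["Ostreidae", "Ostreidae", "Corbulidae", "Turritellidae"],
         "is_informal": [False, True, False, False]},
        index=counts.columns,
    )
    return AbundanceTable(counts, meta, taxonomy, "species", tiny_scheme)


@pytest.fixture(scope="session")
def stable_run():
    """One stable-preset realisation shared across tests."""
    return simulate(preset("stable", seed=11))


@pytest.fixture(scope="session")
def mass_extinction_run():
    return simulate(preset("mass_extinction", seed=11))


@pytest.fixture(scope="session")
def small_run():
    """A compact scenario for fast end-to-end style tests."""
    cfg = ScenarioConfig(n_bins=6, n_genera=15, samples_per_bin=4,
                         mean_specimens=100.0, max_specimens=200, seed=5)
    return simulate(cfg)


def random_table(rng, n_samples=6, n_genera=5, n_bins=3, max_species=3):
    """Small random species-rank table for property tests."""
    species, genera = [], []
    for g in range(n_genera):
        for s in range(1 + rng.integers(max_species)):
            species.append(f"G{g:02d} s{s}")
            genera.append(f"G{g:02d}")
    counts = rng.integers(0, 20, size=(n_samples, len(species)))
    # keep every sample non-empty
    for i in range(n_samples):
        if counts[i].sum() == 0:
            counts[i, rng.integers(len(species))] = 1
    idx = [f"s{i}" for i in range(n_samples)]
    scheme = TimeBinScheme(tuple(f"b{i}" for i in range(n_bins)))
    meta = pd.DataFrame({
        "time_bin": rng.integers(0, n_bins, size=n_samples),
        "locality": "x", "lithology": "mixed"}, index=idx)
    taxonomy = pd.DataFrame({"genus": genera, "family": "",
                             "is_informal": False}, index=species)
    tab = AbundanceTable(pd.DataFrame(counts, index=idx, columns=species),
                         meta, taxonomy, "species", scheme)
    return tab.drop_empty_taxa()
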