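import pytest

from polym6a import synthetic_data as sd


@pytest.fixture(scope="session")
def small_config() -> sd.SyntheticConfig:
    return sd.SyntheticConfig(seed=3, n_triads=30, n_methylated_triads=15,
                              pop_genes_per_class=20, samples_per_pop=8)


@pytest.fixture(scope="session")
def small_dataset(small_config) -> sd.SyntheticDataset:
    """One shared synthetic dataset (30 triads, 15 methylated, population)."""
    return sd.simulate(small_config)


@pytest.fixture(scope="session")
def called_peaks(small_dataset):
    from polym6a import peak_calling as pc
    cons, per_rep = pc.call_peaks(small_dataset.window_counts)
    return cons, per_rep
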