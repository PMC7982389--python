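import pytest

from potbench.synthetic import FixtureSpec, generate_library, generate_potency_matrix


@pytest.fixture(scope="session")
def small_fixture():
    """Five-series library with a sparse 10-target matrix and its truth."""
    spec = FixtureSpec(n_series=5, n_targets=10, density=0.5, seed=3)
    library, truth = generate_library(spec)
    matrix, truth = generate_potency_matrix(library, truth, spec)
    return spec, library, matrix, truth


@pytest.fixture(scope="session")
def dense_single_target():
    """Noise-free, structure-determined single-target data set."""
    spec = FixtureSpec(
        n_series=10,
        series_size_range=(10, 16),
        n_targets=1,
        density=1.0,
        noise_sd=0.0,
        series_effect_sd=1.2,
        substituent_effect_sd=0.3,
        seed=5,
    )
    library, truth = generate_library(spec)
    matrix, truth = generate_potency_matrix(library, truth, spec)
    return spec, library, matrix, truth
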