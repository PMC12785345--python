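import numpy as np
import pytest

from nirauth import preprocess, sampling, synthetic


@pytest.fixture(scope="session")
def dataset42() -> synthetic.SpectraSet:
    """The default 275-sample dataset at root seed 42."""
    return synthetic.generate(synthetic.SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def sg42(dataset42):
    """Savitzky-Golay smoothed (window 15, order 2) absorbance matrix."""
    pipe = preprocess.get_pipeline("SG")
    return pipe.fit_transform(dataset42.absorbance, delta=dataset42.grid.step)


@pytest.fixture(scope="session")
def split42(dataset42, sg42) -> sampling.SplitResult:
    """Class-stratified 6:2:2 Kennard-Stone split on the SG spectra."""
    strata = np.where(dataset42.is_genuine, "genuine", "adulterated")
    return sampling.split_622(sg42, strata)


@pytest.fixture()
def small_grid() -> synthetic.WavenumberGrid:
    return synthetic.WavenumberGrid.default(n_points=201)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
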