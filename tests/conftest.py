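import numpy as np
import pytest

from ecoloc import PatternConfig, simulate_pattern
from ecoloc.patterns import SlidePattern


@pytest.fixture(scope="session")
def clustered_pattern():
    """A mid-colocalization clustered pattern, ~4-5k cells."""
    return simulate_pattern(PatternConfig(rho=0.5, seed=202))


@pytest.fixture
def small_random_pattern():
    """1000 uniformly scattered cells in a 1000x500 window."""
    rng = np.random.default_rng(17)
    n = 1000
    classes = rng.choice(["cancer", "immune", "stromal_other"], size=n, p=[0.5, 0.3, 0.2])
    return SlidePattern(
        patient_id="P1",
        section_id="S1",
        x=rng.uniform(0, 1000, n),
        y=rng.uniform(0, 500, n),
        cell_class=classes,
        window=(0.0, 0.0, 1000.0, 500.0),
    )
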