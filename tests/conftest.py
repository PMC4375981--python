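import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the _oracles helper module

from gardenqg import synth


@pytest.fixture(scope="session")
def balanced_design():
    """Fully balanced layout the ANOVA oracle can handle: 4 x 20 x 6."""
    return synth.DesignSpec(
        n_blocks=4, n_populations=20, genotypes_per_population=(6,) * 20
    )


@pytest.fixture(scope="session")
def study_design():
    """The default study layout: 4 blocks, 20 populations, 124 genotypes."""
    return synth.DesignSpec()


@pytest.fixture(scope="session")
def standard_trait():
    """Ground truth used throughout recovery tests: Q_ST = 0.5."""
    return synth.TraitGenSpec(
        name="trait", mu=10.0, sigma2_P=0.2, sigma2_G=0.1, sigma2_E=0.7,
        block_effects=(0.0, 0.5, -0.3, 0.1),
    )
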