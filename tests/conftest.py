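import numpy as np
import pytest

from metstab.synthetic import SimulationSpec, generate_met
from metstab.trial_io import records_to_frame


@pytest.fixture
def small_trial():
    """Balanced 6-genotype x 4-harvest x 3-replicate wet trial with truth."""
    spec = SimulationSpec(n_genotypes=6, n_harvests=4, n_replicates=3,
                          sigma2_g=4.0, sigma2_e=1.0, interaction_rank=2,
                          interaction_sd=0.5, seed=11)
    records, truth = generate_met(spec)
    return spec, records, truth


@pytest.fixture
def small_frame(small_trial):
    _, records, _ = small_trial
    return records_to_frame(records)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
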