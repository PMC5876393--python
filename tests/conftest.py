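import numpy as np
import pytest

from fnirsdecode import (build_montage, design_fir, make_schedule,
                         simulate_concentrations, concentrations_to_od,
                         preprocess_block, build_trial_matrix,
                         EffectSpec, NoiseSpec, DEFAULT_FS)
from fnirsdecode.io import RunConfig, simulate_participant


@pytest.fixture(scope="session")
def montage():
    return build_montage()


@pytest.fixture(scope="session")
def filter_spec():
    return design_fir(DEFAULT_FS)


@pytest.fixture(scope="session")
def passive_schedule():
    return make_schedule("passive", 123)


@pytest.fixture(scope="session")
def passive_recording(montage, passive_schedule):
    """One seeded passive block with the default planted effect."""
    conc = simulate_concentrations(passive_schedule, montage,
                                   EffectSpec.default("passive"),
                                   NoiseSpec(), seed=456)
    return concentrations_to_od(conc, seed=456)


@pytest.fixture(scope="session")
def passive_matrix(passive_recording, filter_spec, montage):
    epochs = preprocess_block(passive_recording, filter_spec)
    return build_trial_matrix(epochs, "p000", montage.channel_names())


@pytest.fixture(scope="session")
def participant_matrices(montage):
    """Both blocks of one simulated participant under default conditions."""
    return simulate_participant(RunConfig(seed=11), 0, montage)
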