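"""Shared fixtures: small synthetic tracks and envelopes.

The heavy fixtures are session-scoped; analysis settings are lighter than
the library defaults (20 cochlear channels, 80 Hz-6 kHz at 16 kHz audio)
to keep the suite fast without changing any tested property.
"""

import numpy as np
import pytest

from ammod import coupling, stimgen, synth

# light cochlear-analysis settings shared across tests
LIGHT = dict(n_channels=20, f_range=(80.0, 6000.0))
FS = 16000.0


@pytest.fixture(scope="session")
def music12():
    """12-s music-like track at 120 bpm."""
    return synth.synth_music(duration_s=12.0, sample_rate=FS, seed=11)


@pytest.fixture(scope="session")
def mod12(music12):
    """music12 with 16 Hz half-depth modulation over 200-1000 Hz."""
    return stimgen.apply_modulation(
        music12, stimgen.ModulationParams(rate=16.0, nominal_depth=0.5)
    )


@pytest.fixture(scope="session")
def env60():
    """Broadband envelope (250 Hz) of a 60-s track modulated at 16 Hz."""
    track = synth.synth_music(duration_s=60.0, sample_rate=FS, seed=21)
    proc = stimgen.apply_modulation(
        track, stimgen.ModulationParams(rate=16.0, nominal_depth=0.5)
    )
    return coupling.stimulus_envelope_for_plv(proc, 250.0, **LIGHT)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
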