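"""Shared fixtures: small stimulus sets and simulated populations.

Everything is generated programmatically and seeded; session scope keeps the
rendering and simulation cost paid once.
"""

import numpy as np
import pytest

from orthopop import stimuli as st
from orthopop import synth


@pytest.fixture(scope="session")
def glyph_config():
    return st.GlyphConfig()


@pytest.fixture(scope="session")
def mirror_config():
    return st.GlyphConfig(font=st.MirrorFont())


@pytest.fixture(scope="session")
def base_small():
    """12 words + 12 pseudowords under all six variations (144 images)."""
    return st.build_base_set(n_words=12, n_pseudo=12, seed=0)


@pytest.fixture(scope="session")
def letters_small():
    """26 letters x 4 positions x 2 variations."""
    return st.build_letter_set(variations=2)


@pytest.fixture(scope="session")
def letters_full():
    """26 letters x 4 positions x 6 variations (the full letter set)."""
    return st.build_letter_set(variations=6)


@pytest.fixture(scope="session")
def full_small(base_small, letters_small):
    return base_small.concat(letters_small)


@pytest.fixture(scope="session")
def tensor_small(full_small):
    cfg = synth.SimConfig(n_sites=40, n_reps=8, seed=0)
    return synth.simulate_population(full_small, cfg)


@pytest.fixture(scope="session")
def bigram_table():
    return st.load_bigram_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
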