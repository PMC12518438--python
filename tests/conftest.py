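"""Shared fixtures: small synthetic datasets reused across test modules."""

import numpy as np
import pytest

from cardiokit.synth import (
    MitoPhantomSpec,
    TatsPhantomSpec,
    TransientSimSpec,
    gen_mito_volume,
    gen_tats_volume,
    gen_transient_trace,
)


@pytest.fixture(scope="session")
def short_spec():
    """Two-frequency pacing spec that keeps traces small."""
    return TransientSimSpec(pacing_frequencies=(1.0, 2.0), seed=7)


@pytest.fixture(scope="session")
def short_trace(short_spec):
    return gen_transient_trace(short_spec)


@pytest.fixture(scope="session")
def clean_trace():
    """Noise-free single-ladder trace with every beat captured."""
    spec = TransientSimSpec(
        pacing_frequencies=(1.0, 2.0), noise_sd=0.0, missed_beat_prob=0.0, seed=3
    )
    return spec, gen_transient_trace(spec)


@pytest.fixture(scope="session")
def tats_phantom():
    spec = TatsPhantomSpec(seed=0)
    vol, truth = gen_tats_volume(spec)
    return spec, vol, truth


@pytest.fixture(scope="session")
def mito_phantom():
    spec = MitoPhantomSpec(seed=0)
    mtg, tmrm, truth = gen_mito_volume(spec)
    return spec, mtg, tmrm, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
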