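"""Shared fixtures: canonical synthetic voices and small cohorts.

Synthesis is cheap but not free; voices used by several tests are
session-scoped so each is generated once.
"""

from __future__ import annotations

import numpy as np
import pytest

from voicesym.synth import FormantSpec, GlottalParams, synthesize_voice

RATE = 11025.0

FIVE_FORMANTS = FormantSpec(
    centers=(500.0, 1500.0, 2500.0, 3500.0, 4500.0),
    bandwidths=(80.0, 110.0, 160.0, 220.0, 300.0),
)


def clean_glottal(**overrides) -> GlottalParams:
    """Noiseless, perturbation-free source unless overridden."""
    params = dict(
        f0_mean=120.0, f0_sd=0.0, jitter_pct=0.0, shimmer_pct=0.0,
        noise_snr_db=np.inf, open_quotient=0.6, amplitude=0.5,
    )
    params.update(overrides)
    return GlottalParams(**params)


@pytest.fixture(scope="session")
def clean_voice():
    """1 s noiseless 120 Hz voice through the 5-formant tract."""
    return synthesize_voice(clean_glottal(), FIVE_FORMANTS, 1.0, RATE, seed=1)


@pytest.fixture(scope="session")
def noisy_voice_10db():
    return synthesize_voice(
        clean_glottal(noise_snr_db=10.0), FIVE_FORMANTS, 1.0, RATE, seed=4
    )


@pytest.fixture(scope="session")
def sine_200():
    t = np.arange(int(RATE)) / RATE
    from voicesym.audio import AudioRecording

    return AudioRecording(0.5 * np.sin(2 * np.pi * 200.0 * t), RATE)


@pytest.fixture(scope="session")
def white_noise():
    from voicesym.audio import AudioRecording

    rng = np.random.default_rng(0)
    return AudioRecording(0.3 * rng.standard_normal(int(RATE)), RATE)
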