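import numpy as np
import pytest

from amentrain import (
    TrialTiming,
    analytic_phase,
    compute_envelope,
    extract_am_tiers,
    synth_stimulus,
)
from amentrain.synth import StimulusSpec, make_stimuli

RATE = 1000.0


def cosine_tier(freq: float, duration: float = 10.0, rate: float = RATE):
    """Analytic tier of a pure cosine AM (integer cycles -> exact Hilbert)."""
    t = np.arange(int(duration * rate)) / rate
    return analytic_phase(np.cos(2 * np.pi * freq * t), rate, "syllable")


@pytest.fixture(scope="session")
def syllable_tier_4hz():
    return cosine_tier(4.0)


@pytest.fixture(scope="session")
def default_stimulus():
    return synth_stimulus()


@pytest.fixture(scope="session")
def stimulus_tiers(default_stimulus):
    """AM hierarchy + analytic tiers of the default synthetic sentence."""
    env = compute_envelope(default_stimulus.waveform)
    hier = extract_am_tiers(env)
    tiers = {name: hier.analytic(name) for name in ("stress", "syllable", "phoneme")}
    return env, hier, tiers


def build_sentence_set(spec: StimulusSpec, seed: int = 7):
    """Stimulus set + analytic tiers + timings for pipeline tests."""
    stimuli = make_stimuli(spec, seed=seed)
    tiers = {}
    for name, truth in stimuli.items():
        env = compute_envelope(truth.waveform)
        hier = extract_am_tiers(env)
        tiers[name] = {n: hier.analytic(n) for n in ("stress", "syllable", "phoneme")}
    timing = TrialTiming(sentence_duration=spec.duration, stress_rate=spec.stress_rate)
    timings = {name: timing for name in stimuli}
    return stimuli, tiers, timings


@pytest.fixture(scope="session")
def recovery_stimuli():
    """Leakage-reduced stimulus set for phase-recovery oracles.

    Keeps the stress line small and the phoneme line away from the
    syllable-band edge so the extracted syllable tier is near-sinusoidal.
    """
    return build_sentence_set(StimulusSpec(stress_depth_ratio=1.5, phoneme_rate=16.0))


@pytest.fixture(scope="session")
def four_sentence_stimuli():
    """The standard 2-trochaic + 2-iambic stimulus set with analytic tiers."""
    stimuli = make_stimuli(StimulusSpec(), seed=7)
    tiers = {}
    for name, truth in stimuli.items():
        env = compute_envelope(truth.waveform)
        hier = extract_am_tiers(env)
        tiers[name] = {n: hier.analytic(n) for n in ("stress", "syllable", "phoneme")}
    timing = TrialTiming(sentence_duration=2.0, stress_rate=2.0)
    timings = {name: timing for name in stimuli}
    return stimuli, tiers, timings
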