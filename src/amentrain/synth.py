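"""Synthetic-data generators.

Produce every input the analysis pipelines need with known ground truth:
metrically regular speech-like stimuli (nested stress/syllable/phoneme
amplitude modulation on a noise or tone carrier), tap trains with a
controllable phase offset and von Mises jitter, produced-utterance
analogues with a controllable syllable:phoneme coupling angle, and
two-group cohorts with planted phase offsets and behaviour links.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .am_hierarchy import Waveform
from .circular import wrap_angle
from .errors import ConfigurationError, InvalidInputError
from .perception import EventSeries, TrialTiming

__all__ = [
    "StimulusSpec",
    "ResponseSpec",
    "BehaviourLink",
    "CohortSpec",
    "StimulusTruth",
    "SynthProduction",
    "CohortDataset",
    "synth_stimulus",
    "synth_tap_train",
    "synth_production",
    "synth_cohort",
    "make_stimuli",
    "DEFAULT_SENTENCES",
]

#: sentence label -> metre for the standard four-trial design
DEFAULT_SENTENCES: dict[str, str] = {
    "troch1": "trochaic",
    "troch2": "trochaic",
    "iamb1": "iambic",
    "iamb2": "iambic",
}


@dataclass(frozen=True)
class StimulusSpec:
    """Parameters of one metrically regular synthetic sentence."""

    syllable_rate: float = 4.0
    stress_rate: float = 2.0
    n_syllables: int = 8
    metre: str = "trochaic"
    phoneme_rate: float = 12.0
    carrier: str = "noise"
    sample_rate: float = 16000.0
    stress_depth_ratio: float = 2.0  # stressed:unstressed envelope peak ratio
    syllable_depth: float = 0.4
    phoneme_depth: float = 0.12
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.stress_rate - self.syllable_rate / 2) > 1e-9:
            raise ConfigurationError("stress_rate must equal syllable_rate / 2")
        ratio = self.phoneme_rate / self.syllable_rate
        if abs(ratio - round(ratio)) > 1e-9:
            raise ConfigurationError(
                "phoneme_rate must be an integer multiple of syllable_rate"
            )
        if self.metre not in ("trochaic", "iambic"):
            raise ConfigurationError(f"unknown metre {self.metre!r}")
        if self.carrier not in ("noise", "tone"):
            raise ConfigurationError(f"unknown carrier {self.carrier!r}")
        if self.phoneme_rate >= self.sample_rate / 2:
            raise ConfigurationError("phoneme_rate at or above Nyquist")

    @property
    def duration(self) -> float:
        return self.n_syllables / self.syllable_rate


@dataclass(frozen=True)
class ResponseSpec:
    """Parameters of a synthetic tapping response."""

    tier_target: str = "syllable"
    phase_offset: float = 0.0
    kappa: float = np.inf
    miss_rate: float = 0.0
    extra_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ConfigurationError("kappa must be >= 0")
        for r in (self.miss_rate, self.extra_rate):
            if not 0 <= r < 1:
                raise ConfigurationError("rates must lie in [0, 1)")


@dataclass(frozen=True)
class BehaviourLink:
    """Linear link from tapping phase to a behaviour score.

    score = intercept + slope * cos(phase - ref_angle) + N(0, noise_sd).
    """

    intercept: float = 100.0
    slope: float = 10.0
    ref_angle: float = 0.0
    noise_sd: float = 3.0


@dataclass(frozen=True)
class CohortSpec:
    """Two-group cohort with planted group phase offsets."""

    n_control: int = 22
    n_dyslexic: int = 21
    group_phase_offsets: Mapping[str, float] = field(
        default_factory=lambda: {"control": 0.40 * np.pi, "dyslexic": 0.09 * np.pi}
    )
    participant_kappa: float = 5.0  # between-participant offset concentration
    tap_kappa: float = 10.0         # within-participant tap jitter
    miss_rate: float = 0.0
    behaviour_model: Mapping[str, BehaviourLink] = field(
        default_factory=lambda: {
            "reading": BehaviourLink(),
            "spelling": BehaviourLink(),
            "phonology": BehaviourLink(),
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_control, self.n_dyslexic) < 2:
            raise ConfigurationError("group sizes must be >= 2")


@dataclass
class StimulusTruth:
    """A synthetic stimulus with its exact latent event times."""

    waveform: Waveform
    envelope: np.ndarray       # the modulator itself, at waveform rate
    syllable_onsets: EventSeries
    vowel_onsets: EventSeries  # syllable-pulse peaks (vowel-nucleus analogues)
    stress_beats: EventSeries  # peaks of the stressed syllables
    spec: StimulusSpec


def synth_stimulus(s: StimulusSpec | None = None) -> StimulusTruth:
    """Generate one metrically regular sentence with ground-truth events.

    The envelope is additive — a DC term plus pure cosines at the stress,
    syllable and phoneme rates — so each extracted AM tier is sinusoidal
    and its instantaneous phase advances uniformly (an envelope with
    in-band harmonics would distort tap-phase scoring). The stress
    component's depth sets the stressed:unstressed peak ratio and its
    alignment encodes the metre; the carrier is seeded white noise or a
    1 kHz tone. The envelope modulation spectrum peaks at the stress and
    syllable rates.
    """
    s = s or StimulusSpec()
    t = np.arange(int(round(s.duration * s.sample_rate))) / s.sample_rate
    period = 1.0 / s.syllable_rate
    # syllable peaks at (k + 1/2) * period keep all events off the edges
    peaks = (np.arange(s.n_syllables) + 0.5) * period
    onsets = peaks  # acoustic peak = vowel-nucleus analogue = onset landmark
    stressed_first = s.metre == "trochaic"
    stress_idx = np.arange(0 if stressed_first else 1, s.n_syllables, 2)
    stress_peaks = peaks[stress_idx]
    a = s.syllable_depth
    r = s.stress_depth_ratio
    c = (r - 1) * (1 + a) / (r + 1)  # stress depth giving the peak ratio
    theta_syl = 2 * np.pi * s.syllable_rate * (t - peaks[0])
    theta_str = 2 * np.pi * s.stress_rate * (t - stress_peaks[0])
    env = (
        1.0
        + c * np.cos(theta_str)
        + a * np.cos(theta_syl)
        + s.phoneme_depth * np.cos(2 * np.pi * s.phoneme_rate * t)
    )
    env = np.clip(env, 0.0, None)
    rng = np.random.default_rng(s.seed)
    if s.carrier == "noise":
        carrier = rng.standard_normal(t.size)
    else:
        carrier = np.sin(2 * np.pi * 1000.0 * t)
    wav = Waveform(samples=env * carrier, rate=s.sample_rate,
                   label=f"synthetic[{s.metre}]")
    return StimulusTruth(
        waveform=wav,
        envelope=env,
        syllable_onsets=EventSeries(onsets, kind="syllable_onset", metre=s.metre),
        vowel_onsets=EventSeries(peaks, kind="vowel_onset", metre=s.metre),
        stress_beats=EventSeries(stress_peaks, kind="stress_beat", metre=s.metre),
        spec=s,
    )


def synth_tap_train(
    stimulus_truth: EventSeries,
    t: TrialTiming,
    r: ResponseSpec | None = None,
    tier_rates: Mapping[str, float] | None = None,
    n_repetitions: int = 3,
    **labels,
) -> EventSeries:
    """Tap train: one tap near each stress beat of every presentation.

    Taps are shifted by ``phase_offset / (2*pi*f_tier)`` relative to the
    beats and jittered by a von Mises(kappa) draw on the target tier's
    cycle; misses and extra taps are injected at the configured rates.
    """
    r = r or ResponseSpec()
    rates = {"stress": t.stress_rate, "syllable": 2 * t.stress_rate}
    if tier_rates:
        rates.update(tier_rates)
    f_tier = rates[r.tier_target]
    rng = np.random.default_rng(r.seed)
    taps: list[float] = []
    for rep in range(min(n_repetitions, len(t.repetition_starts))):
        start = t.repetition_starts[rep]
        for beat in stimulus_truth.times:
            if r.miss_rate and rng.random() < r.miss_rate:
                continue
            jitter = 0.0 if np.isinf(r.kappa) else float(rng.vonmises(0.0, r.kappa))
            taps.append(start + beat + (r.phase_offset + jitter) / (2 * np.pi * f_tier))
        if r.extra_rate:
            n_extra = rng.binomial(len(stimulus_truth.times), r.extra_rate)
            taps.extend(start + rng.uniform(0, t.sentence_duration, n_extra))
    times = np.unique(np.asarray(taps))
    times = times[times >= 0]
    return EventSeries(times, kind="tap", **labels)


@dataclass
class SynthProduction:
    """Synthetic production recording with ground truth."""

    waveform: Waveform
    vowel_onsets: list[EventSeries]  # one series per repetition
    metronome: EventSeries
    repetition_starts: np.ndarray
    coupling_angle: float
    syllable_rate: float


def synth_production(
    s: StimulusSpec | None = None,
    voi_ms: float = 250.0,
    coupling_angle: float = np.pi,
    jitter_sd: float = 0.0,
    seed: int = 0,
    n_repetitions: int = 5,
    stress_depth: float = 0.25,
    syllable_depth: float = 0.45,
    phoneme_depth: float = 0.25,
) -> SynthProduction:
    """Five repetitions of an 8-syllable utterance paced at ``voi_ms``.

    Within each utterance the envelope is built additively,
    ``1 + c*cos(theta_str) + a*cos(theta_syl) + b*cos(3*theta_syl -
    coupling_angle)``, so the phoneme-band component's generalized
    3:1 phase difference against the syllable component equals
    ``coupling_angle`` exactly (an additive design avoids intermodulation
    sidebands inside the phoneme band). Reported vowel onsets are the
    nominal grid plus Gaussian jitter of ``jitter_sd`` ms.
    """
    if voi_ms <= 0:
        raise InvalidInputError("voi_ms must be positive")
    s = s or StimulusSpec()
    f_syl = 1000.0 / voi_ms
    n_syl = s.n_syllables
    utt_dur = n_syl / f_syl
    gap = utt_dur
    rate = s.sample_rate
    rng = np.random.default_rng(seed)
    total = n_repetitions * utt_dur + (n_repetitions - 1) * gap
    n_total = int(round(total * rate))
    samples = np.zeros(n_total)
    rep_starts = np.arange(n_repetitions) * (utt_dur + gap)
    onset_series = []
    b = phoneme_depth
    for rep, start in enumerate(rep_starts):
        n_utt = int(round(utt_dur * rate))
        tt = np.arange(n_utt) / rate
        theta = 2 * np.pi * f_syl * (tt - 0.5 / f_syl)
        env = (
            1.0
            + stress_depth * np.cos(theta / 2)
            + syllable_depth * np.cos(theta)
            + b * np.cos(3 * theta - coupling_angle)
        )
        taper = int(round(0.05 * n_utt))
        win = np.ones(n_utt)
        if taper > 0:
            ramp = 0.5 * (1 - np.cos(np.linspace(0, np.pi, taper)))
            win[:taper] = ramp
            win[-taper:] = ramp[::-1]
        carrier = rng.standard_normal(n_utt) if s.carrier == "noise" else np.sin(
            2 * np.pi * 1000.0 * tt
        )
        i0 = int(round(start * rate))
        samples[i0:i0 + n_utt] = np.clip(env, 0, None) * win * carrier
        nominal = start + (np.arange(n_syl) + 0.5) / f_syl
        jitter = rng.normal(0.0, jitter_sd / 1000.0, n_syl) if jitter_sd > 0 else 0.0
        onset_series.append(
            EventSeries(np.sort(nominal + jitter), kind="vowel_onset", repetition=rep + 1)
        )
    beat_interval = 2.0 / f_syl  # two syllables per metronome beat
    metronome = EventSeries(
        np.arange(0.0, total, beat_interval), kind="metronome"
    )
    return SynthProduction(
        waveform=Waveform(samples, rate, label="synthetic-production"),
        vowel_onsets=onset_series,
        metronome=metronome,
        repetition_starts=rep_starts,
        coupling_angle=float(wrap_angle(coupling_angle)),
        syllable_rate=f_syl,
    )


def make_stimuli(
    s: StimulusSpec | None = None,
    sentences: Mapping[str, str] = DEFAULT_SENTENCES,
    seed: int = 0,
) -> dict[str, StimulusTruth]:
    """One synthetic stimulus per sentence label (label -> metre mapping)."""
    s = s or StimulusSpec()
    out = {}
    for i, (name, metre) in enumerate(sentences.items()):
        spec = StimulusSpec(
            syllable_rate=s.syllable_rate,
            stress_rate=s.stress_rate,
            n_syllables=s.n_syllables,
            metre=metre,
            phoneme_rate=s.phoneme_rate,
            carrier=s.carrier,
            sample_rate=s.sample_rate,
            stress_depth_ratio=s.stress_depth_ratio,
            syllable_depth=s.syllable_depth,
            phoneme_depth=s.phoneme_depth,
            seed=seed + i,
        )
        truth = synth_stimulus(spec)
        truth.waveform.label = name
        out[name] = truth
    return out


@dataclass
class CohortDataset:
    """Synthetic two-group dataset: stimuli, taps, behaviour, ground truth."""

    participants: pd.DataFrame  # participant, group, true_offset
    stimuli: dict[str, StimulusTruth]
    timing: TrialTiming
    taps: list[EventSeries]     # trial-clock taps, one series per trial
    behaviour: pd.DataFrame     # participant + measure columns
    spec: CohortSpec


def synth_cohort(
    c: CohortSpec | None = None,
    s: StimulusSpec | None = None,
    t: TrialTiming | None = None,
    stimuli: dict[str, StimulusTruth] | None = None,
) -> CohortDataset:
    """Generate a full two-group cohort with planted ground truth.

    Each participant draws a personal syllable-phase offset from a von
    Mises around their group's planted offset, then taps every trial with
    von Mises(tap_kappa) jitter. Behaviour scores follow the configured
    cosine link from the participant's true offset, so circular-linear
    correlations are recoverable. Pass precomputed ``stimuli`` to skip
    waveform synthesis (the taps/behaviour still resample from ``c.seed``).
    """
    c = c or CohortSpec()
    s = s or StimulusSpec()
    t = t or TrialTiming(sentence_duration=s.duration, stress_rate=s.stress_rate)
    if stimuli is None:
        stimuli = make_stimuli(s, seed=c.seed)
    rng = np.random.default_rng(c.seed)
    rows = []
    for group, n in (("control", c.n_control), ("dyslexic", c.n_dyslexic)):
        mu = float(c.group_phase_offsets[group])
        for i in range(n):
            offset = (
                mu if np.isinf(c.participant_kappa)
                else float(wrap_angle(rng.vonmises(mu, c.participant_kappa)))
            )
            rows.append({"participant": f"{group[0]}{i + 1:02d}", "group": group,
                         "true_offset": offset})
    participants = pd.DataFrame(rows)
    taps = []
    for _, p in participants.iterrows():
        for name, truth in stimuli.items():
            r = ResponseSpec(
                tier_target="syllable",
                phase_offset=p["true_offset"],
                kappa=c.tap_kappa,
                miss_rate=c.miss_rate,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            taps.append(
                synth_tap_train(
                    truth.stress_beats, t, r,
                    participant=p["participant"], group=p["group"],
                    sentence=name, metre=truth.spec.metre,
                )
            )
    beh_rows = []
    for _, p in participants.iterrows():
        row = {"participant": p["participant"], "group": p["group"]}
        for measure, link in c.behaviour_model.items():
            row[measure] = (
                link.intercept
                + link.slope * np.cos(p["true_offset"] - link.ref_angle)
                + rng.normal(0.0, link.noise_sd)
            )
        beh_rows.append(row)
    return CohortDataset(
        participants=participants,
        stimuli=stimuli,
        timing=t,
        taps=taps,
        behaviour=pd.DataFrame(beh_rows),
        spec=c,
    )
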