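"""Amplitude-modulation hierarchy extraction.

Demodulates a speech waveform into its amplitude envelope, computes the
envelope modulation spectrum, band-pass filters the envelope into a
three-tier AM hierarchy (stress / syllable / phoneme rates), and exposes
instantaneous phase of each tier via the analytic signal.

Conventions
-----------
* Phase lives in [-pi, pi]; 0 rad is the peak of the oscillatory cycle and
  +/-pi equivalently mark the trough.
* All filtering of AM tiers is zero-phase (forward-backward Butterworth),
  so tier peaks stay aligned with envelope peaks.
* Time is in seconds everywhere; rates in Hz.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .errors import ConfigurationError, InvalidInputError, UndefinedPhaseError

logger = logging.getLogger(__name__)

__all__ = [
    "Waveform",
    "EnvelopeSignal",
    "AMBandConfig",
    "AMHierarchy",
    "AnalyticTier",
    "ModSpectrum",
    "DEFAULT_ENVELOPE_RATE",
    "DEFAULT_SPECTRAL_EDGES",
    "compute_envelope",
    "modulation_spectrum",
    "extract_am_tiers",
    "analytic_phase",
    "phase_at_times",
    "spectral_band_filter",
]

#: Envelope sampling rate used throughout unless overridden (Hz).
DEFAULT_ENVELOPE_RATE = 1000.0

#: Five log-spaced acoustic bands spanning 100-7250 Hz (six edges).
DEFAULT_SPECTRAL_EDGES = tuple(np.geomspace(100.0, 7250.0, 6))

TIER_NAMES = ("stress", "syllable", "phoneme")


@dataclass
class Waveform:
    """A mono audio signal.

    Parameters
    ----------
    samples : array-like of float
        Signal samples (arbitrary units).
    rate : float
        Sampling rate in samples/s; must be positive.
    label : str
        Free-text identifier (e.g. sentence name).
    """

    samples: np.ndarray
    rate: float
    label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise InvalidInputError("waveform must be one-dimensional (mono)")
        if self.rate <= 0:
            raise InvalidInputError(f"rate must be positive, got {self.rate}")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise InvalidInputError("waveform contains non-finite samples")

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.rate


@dataclass
class EnvelopeSignal:
    """Nonnegative amplitude envelope at its own (lower) sampling rate."""

    values: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.rate <= 0:
            raise InvalidInputError("envelope rate must be positive")
        if self.values.size and np.min(self.values) < 0:
            raise InvalidInputError("envelope values must be nonnegative")

    @property
    def duration(self) -> float:
        return self.values.size / self.rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) / self.rate


@dataclass(frozen=True)
class AMBandConfig:
    """Pass-band edges (Hz) for the three AM tiers plus the filter order.

    Defaults follow the analysis bands: stress 0.8-2.5 Hz (0.9 Hz variant
    selectable), syllable 2.5-12 Hz, phoneme 12-40 Hz.
    """

    stress_band: tuple[float, float] = (0.8, 2.5)
    syllable_band: tuple[float, float] = (2.5, 12.0)
    phoneme_band: tuple[float, float] = (12.0, 40.0)
    filter_order: int = 2

    def __post_init__(self) -> None:
        bands = [self.stress_band, self.syllable_band, self.phoneme_band]
        for lo, hi in bands:
            if not 0 < lo < hi:
                raise ConfigurationError(f"band edges must satisfy 0 < lo < hi, got ({lo}, {hi})")
        centres = [np.sqrt(lo * hi) for lo, hi in bands]
        if not centres[0] < centres[1] < centres[2]:
            raise ConfigurationError("bands must be ordered stress < syllable < phoneme")
        if self.filter_order < 1:
            raise ConfigurationError("filter_order must be >= 1")

    @property
    def bands(self) -> dict[str, tuple[float, float]]:
        return {
            "stress": self.stress_band,
            "syllable": self.syllable_band,
            "phoneme": self.phoneme_band,
        }


@dataclass
class AMHierarchy:
    """Three band-limited AM tiers sharing one sampling rate."""

    stress: np.ndarray
    syllable: np.ndarray
    phoneme: np.ndarray
    rate: float
    band_config: AMBandConfig = field(default_factory=AMBandConfig)
    spectral_band_index: int | str = "broadband"

    def __post_init__(self) -> None:
        if not (len(self.stress) == len(self.syllable) == len(self.phoneme)):
            raise InvalidInputError("all tiers must have the same length")

    def tier(self, name: str) -> np.ndarray:
        try:
            return {"stress": self.stress, "syllable": self.syllable, "phoneme": self.phoneme}[name]
        except KeyError:
            raise InvalidInputError(f"unknown tier {name!r}") from None

    def analytic(self, name: str) -> "AnalyticTier":
        return analytic_phase(self.tier(name), self.rate, name)


@dataclass
class AnalyticTier:
    """Instantaneous phase and magnitude of one AM tier.

    Phase is in [-pi, pi] with 0 at the oscillatory peak. The complex
    analytic signal is recoverable as ``magnitude * exp(1j*phase)``, which
    is what :func:`phase_at_times` interpolates.
    """

    phase: np.ndarray
    magnitude: np.ndarray
    rate: float
    tier: str = ""

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=float)
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        if self.phase.shape != self.magnitude.shape:
            raise InvalidInputError("phase and magnitude must have equal shape")

    @property
    def duration(self) -> float:
        return self.phase.size / self.rate

    @property
    def analytic_signal(self) -> np.ndarray:
        return self.magnitude * np.exp(1j * self.phase)


@dataclass
class ModSpectrum:
    """One-sided power spectrum of a (mean-removed) envelope."""

    freqs: np.ndarray
    power: np.ndarray

    def peak_freq(self) -> float:
        """Frequency of the highest power bin."""
        return float(self.freqs[int(np.argmax(self.power))])

    def peak_freqs(self, k: int = 2, min_separation: float = 0.5) -> list[float]:
        """Top-``k`` local-maximum frequencies separated by ``min_separation`` Hz."""
        idx, _ = sps.find_peaks(self.power)
        order = idx[np.argsort(self.power[idx])[::-1]]
        chosen: list[float] = []
        for i in order:
            f = float(self.freqs[i])
            if all(abs(f - g) >= min_separation for g in chosen):
                chosen.append(f)
            if len(chosen) == k:
                break
        return chosen


def _as_fraction(x: float, limit: int = 1000) -> Fraction:
    return Fraction(x).limit_denominator(limit)


def compute_envelope(w: Waveform, env_rate: float = DEFAULT_ENVELOPE_RATE) -> EnvelopeSignal:
    """Hilbert envelope of ``w`` resampled to ``env_rate``.

    The magnitude of the analytic signal is taken at the native rate and
    then polyphase-resampled to ``env_rate`` (the resampler's FIR acts as
    the anti-alias low-pass below ``env_rate/2``). Negative ripple from
    the resampling filter is clipped at zero.
    """
    if w.samples.size == 0:
        raise InvalidInputError("cannot compute the envelope of an empty waveform")
    if env_rate <= 0:
        raise ConfigurationError("env_rate must be positive")
    if env_rate > w.rate:
        raise ConfigurationError(f"env_rate {env_rate} exceeds waveform rate {w.rate}")
    if env_rate < 80.0:
        raise ConfigurationError(
            f"env_rate {env_rate} Hz is below 2x the phoneme-band upper edge (80 Hz)"
        )
    env = np.abs(sps.hilbert(w.samples))
    if env_rate != w.rate:
        ratio = _as_fraction(env_rate / w.rate)
        env = sps.resample_poly(env, ratio.numerator, ratio.denominator)
    return EnvelopeSignal(values=np.clip(env, 0.0, None), rate=env_rate)


def modulation_spectrum(e: EnvelopeSignal, fmax: float = 25.0) -> ModSpectrum:
    """Power spectrum of the mean-removed envelope, truncated at ``fmax`` Hz."""
    if e.values.size == 0:
        raise InvalidInputError("empty envelope")
    nyq = e.rate / 2.0
    if not 0 < fmax <= nyq:
        raise ConfigurationError(f"fmax must lie in (0, {nyq}], got {fmax}")
    x = e.values - np.mean(e.values)
    n = x.size
    spec = np.fft.rfft(x)
    power = (np.abs(spec) ** 2) / n
    freqs = np.fft.rfftfreq(n, d=1.0 / e.rate)
    keep = freqs <= fmax
    return ModSpectrum(freqs=freqs[keep], power=power[keep])


def _bandpass_sos(lo: float, hi: float, rate: float, order: int) -> np.ndarray:
    nyq = rate / 2.0
    if hi >= nyq:
        raise ConfigurationError(f"band edge {hi} Hz at or above Nyquist {nyq} Hz")
    return sps.butter(order, [lo, hi], btype="bandpass", fs=rate, output="sos")


def extract_am_tiers(e: EnvelopeSignal, cfg: AMBandConfig | None = None) -> AMHierarchy:
    """Zero-phase band-pass filter the envelope into the three AM tiers."""
    cfg = cfg or AMBandConfig()
    if e.rate < 2 * cfg.phoneme_band[1]:
        raise ConfigurationError(
            f"envelope rate {e.rate} Hz below 2x phoneme band edge {cfg.phoneme_band[1]} Hz"
        )
    x = e.values - np.mean(e.values)
    # reflect-pad by 1.5 cycles of the slowest band so short utterances are
    # not dominated by filter start-up transients
    n_pad = min(x.size - 1, int(round(1.5 / cfg.stress_band[0] * e.rate)))
    xp = np.pad(x, n_pad, mode="reflect") if n_pad > 0 else x
    tiers = {}
    for name, (lo, hi) in cfg.bands.items():
        sos = _bandpass_sos(lo, hi, e.rate, cfg.filter_order)
        y = sps.sosfiltfilt(sos, xp)
        tiers[name] = y[n_pad:n_pad + x.size] if n_pad > 0 else y
    return AMHierarchy(rate=e.rate, band_config=cfg, **tiers)


def analytic_phase(tier_values: Sequence[float], rate: float, tier: str = "") -> AnalyticTier:
    """Instantaneous phase/magnitude of a band-limited tier via the Hilbert transform.

    Raises
    ------
    UndefinedPhaseError
        If the input is identically zero.
    """
    x = np.asarray(tier_values, dtype=float)
    if x.size == 0 or not np.any(x):
        raise UndefinedPhaseError("phase is undefined for an all-zero signal")
    x = x - np.mean(x)
    # reflect-pad so the Hilbert transform's circular wrap-around does not
    # contaminate the edges of short tiers
    n_pad = min(x.size - 1, int(round(2.0 * rate)))
    xp = np.pad(x, n_pad, mode="reflect") if n_pad > 0 else x
    z = sps.hilbert(xp)
    if n_pad > 0:
        z = z[n_pad:n_pad + x.size]
    return AnalyticTier(phase=np.angle(z), magnitude=np.abs(z), rate=rate, tier=tier)


def phase_at_times(a: AnalyticTier, times: Sequence[float]) -> np.ndarray:
    """Instantaneous phase at arbitrary times by interpolating the analytic signal.

    The complex analytic signal (not the wrapped phase) is linearly
    interpolated and the angle taken, avoiding wrap-around artefacts.
    Out-of-range times yield NaN and are logged; valid outputs lie in
    [-pi, pi].
    """
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        return np.empty(0)
    dur = (a.phase.size - 1) / a.rate
    valid = (t >= 0) & (t <= dur)
    if not np.all(valid):
        logger.warning(
            "%d/%d event times outside [0, %.3f s] excluded from phase lookup",
            int(np.sum(~valid)), t.size, dur,
        )
    z = a.analytic_signal
    grid = np.arange(a.phase.size) / a.rate
    out = np.full(t.shape, np.nan)
    tv = t[valid]
    out[valid] = np.angle(np.interp(tv, grid, z.real) + 1j * np.interp(tv, grid, z.imag))
    return out


def spectral_band_filter(
    w: Waveform,
    edges: Sequence[float] | None = None,
    order: int = 2,
) -> list[Waveform]:
    """Split a waveform into acoustic-frequency bands before demodulation.

    ``edges=None`` selects the default five log-spaced bands spanning
    100-7250 Hz. Pass ``edges="broadband"`` to bypass the decomposition.
    """
    if isinstance(edges, str):
        if edges == "broadband":
            return [w]
        raise ConfigurationError(f"unknown edges mode {edges!r}")
    if edges is None:
        edges = DEFAULT_SPECTRAL_EDGES
    edges = np.asarray(edges, dtype=float)
    if edges.size < 2:
        raise ConfigurationError("need at least two band edges")
    if np.any(np.diff(edges) <= 0):
        raise ConfigurationError("edges must be strictly ascending")
    if edges[0] <= 0 or edges[-1] >= w.rate / 2:
        raise ConfigurationError("edges must lie strictly inside (0, Nyquist)")
    out = []
    for i, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
        sos = sps.butter(order, [lo, hi], btype="bandpass", fs=w.rate, output="sos")
        y = sps.sosfiltfilt(sos, w.samples)
        out.append(Waveform(samples=y, rate=w.rate, label=f"{w.label}[band{i + 1}]"))
    return out


def edge_confidence_mask(n_samples: int, rate: float, slowest_lo: float = 0.8,
                         n_cycles: float = 1.5) -> np.ndarray:
    """Boolean mask, False within ``n_cycles`` of the slowest band at each end.

    Events falling in the False region are still scored but should be
    flagged low-confidence by callers.
    """
    margin = int(round(n_cycles / slowest_lo * rate))
    mask = np.ones(n_samples, dtype=bool)
    if margin > 0:
        mask[:margin] = False
        mask[n_samples - margin:] = False
    return mask


def write_tiers(path, hierarchy: AMHierarchy) -> None:
    """Write tiers as delimited text: time_s, stress, syllable, phoneme."""
    t = np.arange(len(hierarchy.stress)) / hierarchy.rate
    data = np.column_stack([t, hierarchy.stress, hierarchy.syllable, hierarchy.phoneme])
    header = "time_s,stress,syllable,phoneme"
    np.savetxt(path, data, delimiter=",", header=header, comments="", fmt="%.12g")


def write_modspectrum(path, spec: ModSpectrum) -> None:
    """Write a modulation spectrum as delimited text: freq_hz, power."""
    np.savetxt(
        path,
        np.column_stack([spec.freqs, spec.power]),
        delimiter=",",
        header="freq_hz,power",
        comments="",
        fmt="%.12g",
    )
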