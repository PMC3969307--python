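"""Speech-production pipeline.

Vowel-onset intervals measure external synchronisation to the pacing
beat; n:m cross-frequency phase synchronisation between AM tiers
(strength = PSI, timing = generalized phase-difference angle) measures
internal synchronisation across timescales.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .am_hierarchy import (
    AMBandConfig,
    EnvelopeSignal,
    Waveform,
    analytic_phase,
    compute_envelope,
    extract_am_tiers,
    modulation_spectrum,
)
from .circular import circ_mean_resultant, rayleigh_test, watson_williams, wrap_angle
from .errors import ConfigurationError, InvalidInputError
from .perception import EventSeries

logger = logging.getLogger(__name__)

__all__ = [
    "PSIResult",
    "PhaseHeatmap",
    "Utterance",
    "UtteranceSet",
    "DEFAULT_PAIRS",
    "vowel_onset_intervals",
    "psi",
    "select_nm",
    "phase_heatmap",
    "segment_utterances",
    "crossband_phase_analysis",
]

#: AM tier pairs and their a-priori n:m ratios: (slow tier, fast tier, n, m).
DEFAULT_PAIRS = (("stress", "syllable", 2, 1), ("syllable", "phoneme", 3, 1))


@dataclass(frozen=True)
class PSIResult:
    """n:m phase synchronisation index with its circular summary.

    ``psi`` is the resultant length of the wrapped generalized phase
    difference n*theta1 - m*theta2, so ``psi == diff_resultant`` always.
    """

    n: int
    m: int
    psi: float
    mean_diff_angle: float
    diff_resultant: float
    n_samples: int


@dataclass
class PhaseHeatmap:
    """Joint binned distribution of two phase streams (percentages)."""

    x_edges: np.ndarray  # slow-tier phase, [0, 2*pi]
    y_edges: np.ndarray  # fast-tier phase, [-pi, pi]
    freq: np.ndarray     # (ny, nx) percentages
    n: int = 3
    m: int = 1
    normalisation: str = "column"

    @property
    def bin_width(self) -> float:
        return float(self.x_edges[1] - self.x_edges[0])


@dataclass
class Utterance:
    """One segmented repetition of a produced sentence."""

    waveform: Waveform
    repetition_index: int  # 1-based
    start: float
    end: float
    timing_mode: str = "two_syllables_per_beat"
    included: bool = True
    exclusion_reason: str | None = None


@dataclass
class UtteranceSet:
    """All repetitions segmented from one production recording."""

    utterances: list[Utterance]
    participant: str | None = None
    group: str | None = None
    sentence: str | None = None
    metre: str | None = None

    @property
    def included(self) -> list[Utterance]:
        return [u for u in self.utterances if u.included]


def vowel_onset_intervals(
    onsets: EventSeries | Iterable[EventSeries],
    expected_onsets: int = 8,
) -> pd.DataFrame:
    """Successive vowel-onset intervals in ms, one row per interval.

    Each utterance with k onsets yields k-1 intervals (7 for the expected
    8). Utterances with an unexpected onset count are flagged via a
    warning but still contribute their available intervals. Mean VOI per
    participant x sentence is a groupby over the tidy table.
    """
    series = [onsets] if isinstance(onsets, EventSeries) else list(onsets)
    rows = []
    for s in series:
        if len(s) != expected_onsets:
            logger.warning(
                "participant %s sentence %s rep %s: %d onsets (expected %d)",
                s.participant, s.sentence, s.repetition, len(s), expected_onsets,
            )
        if len(s) < 2:
            continue
        vois = np.diff(s.times) * 1000.0
        for i, v in enumerate(vois):
            rows.append(
                {
                    "participant": s.participant,
                    "group": s.group,
                    "sentence": s.sentence,
                    "metre": s.metre,
                    "repetition": s.repetition,
                    "interval_index": i,
                    "voi_ms": v,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["participant", "group", "sentence", "metre", "repetition",
                 "interval_index", "voi_ms"],
    )


def psi(phi1, phi2, n: int, m: int) -> PSIResult:
    """n:m phase synchronisation index |<exp(i(n*phi1 - m*phi2))>|.

    phi1 is the slower oscillation's phase, phi2 the faster one's; the
    generalized difference n*phi1 - m*phi2 is wrapped to [-pi, pi] and its
    mean unit vector taken. PSI is the vector's modulus (0 = none,
    1 = perfect locking) and ``mean_diff_angle`` its angle.
    """
    p1 = np.asarray(phi1, dtype=float).ravel()
    p2 = np.asarray(phi2, dtype=float).ravel()
    if p1.size != p2.size:
        raise InvalidInputError(f"phase streams differ in length ({p1.size} vs {p2.size})")
    if p1.size == 0:
        raise InvalidInputError("empty phase streams")
    if p1.size < 100:
        warnings.warn(f"only {p1.size} samples; PSI estimate will be noisy", stacklevel=2)
    diff = wrap_angle(n * p1 - m * p2)
    summary = circ_mean_resultant(diff)
    return PSIResult(
        n=int(n),
        m=int(m),
        psi=summary.resultant_length,
        mean_diff_angle=summary.mean_angle,
        diff_resultant=summary.resultant_length,
        n_samples=p1.size,
    )


def select_nm(
    phi1,
    phi2,
    candidates: Sequence[tuple[int, int]] = ((2, 1), (3, 1), (4, 1), (5, 1)),
    tie_tolerance: float = 0.01,
) -> tuple[tuple[int, int], pd.DataFrame]:
    """Pick the n:m ratio maximising PSI over a candidate set.

    Returns the winning ratio and the full PSI table. Near-ties (top two
    PSIs within ``tie_tolerance``) resolve toward the smaller n with a
    logged warning.
    """
    if len(candidates) < 2:
        raise ConfigurationError("need at least two candidate ratios")
    rows = []
    for n, m in candidates:
        res = psi(phi1, phi2, n, m)
        rows.append({"n": n, "m": m, "psi": res.psi,
                     "mean_diff_angle": res.mean_diff_angle})
    table = pd.DataFrame(rows)
    ranked = table.sort_values(["psi", "n"], ascending=[False, True]).reset_index(drop=True)
    if len(ranked) > 1 and ranked.loc[0, "psi"] - ranked.loc[1, "psi"] < tie_tolerance:
        warnings.warn(
            f"near-tied PSI across ratios (top two within {tie_tolerance}); "
            "selecting the smaller n",
            stacklevel=2,
        )
    best = (int(ranked.loc[0, "n"]), int(ranked.loc[0, "m"]))
    return best, table


def phase_heatmap(
    phi_syll,
    phi_phon,
    n: int = 3,
    m: int = 1,
    nbins: int = 24,
    normalisation: str = "column",
) -> PhaseHeatmap:
    """Joint histogram of concurrent slow/fast tier phases, as percentages.

    The slow (x) phase is mapped to [0, 2*pi), the fast (y) phase stays in
    [-pi, pi]. ``normalisation='column'`` (default) makes every x-column
    sum to 100%; ``'global'`` makes the whole grid sum to 100%.
    """
    p1 = np.mod(np.asarray(phi_syll, dtype=float).ravel(), 2 * np.pi)
    p2 = wrap_angle(phi_phon)
    if p1.size != p2.size:
        raise InvalidInputError("phase streams differ in length")
    x_edges = np.linspace(0.0, 2 * np.pi, nbins + 1)
    y_edges = np.linspace(-np.pi, np.pi, nbins + 1)
    counts, _, _ = np.histogram2d(p2, p1, bins=[y_edges, x_edges])
    if normalisation == "column":
        col = counts.sum(axis=0, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(col > 0, counts / col * 100.0, 0.0)
    elif normalisation == "global":
        total = counts.sum()
        freq = counts / total * 100.0 if total else counts
    else:
        raise ConfigurationError(f"unknown normalisation {normalisation!r}")
    return PhaseHeatmap(x_edges=x_edges, y_edges=y_edges, freq=freq,
                        n=n, m=m, normalisation=normalisation)


def _active_mask(env: np.ndarray, threshold_db: float, hangover: int) -> np.ndarray:
    thresh = np.max(env) * 10 ** (threshold_db / 20.0)
    active = env > thresh
    if hangover > 0 and active.any():
        # dilate: keep activity alive for `hangover` samples after it drops
        kernel = np.ones(hangover)
        active = np.convolve(active.astype(float), kernel, mode="same") > 0
    return active


def segment_utterances(
    recording: Waveform,
    metronome: EventSeries,
    n_repetitions: int = 5,
    threshold_db: float = -40.0,
    hangover_s: float = 0.05,
    env_rate: float = 200.0,
    syllable_search_band: tuple[float, float] = (1.0, 12.0),
) -> UtteranceSet:
    """Segment a multi-repetition production recording into utterances.

    Boundaries come from an energy gate (``threshold_db`` re max, with a
    ``hangover_s`` hold), repetitions are indexed in order, and each
    utterance's timing mode is classified by comparing its produced
    syllable rate (dominant envelope modulation frequency inside
    ``syllable_search_band``) against the metronome rate: a ratio >= 1.5
    means two syllables per beat. Repetitions 1-2 and one-syllable-per-beat
    utterances are marked ``included=False``.
    """
    env = compute_envelope(recording, env_rate=min(env_rate, recording.rate))
    active = _active_mask(env.values, threshold_db, int(round(hangover_s * env.rate)))
    # contiguous active runs -> candidate segments
    padded = np.concatenate([[0], active.astype(int), [0]])
    edges = np.flatnonzero(np.diff(padded))
    runs = [(edges[i] / env.rate, edges[i + 1] / env.rate) for i in range(0, edges.size, 2)]
    if len(runs) > n_repetitions:
        runs = sorted(sorted(runs, key=lambda r: r[1] - r[0])[-n_repetitions:])
    if len(runs) < n_repetitions:
        logger.warning(
            "detected %d utterances (expected %d); best-effort indexing", len(runs), n_repetitions
        )
    if len(metronome) >= 2:
        beat_rate = 1.0 / float(np.median(np.diff(metronome.times)))
    else:
        beat_rate = 2.0
    utterances = []
    for i, (t0, t1) in enumerate(runs):
        i0, i1 = int(t0 * recording.rate), int(t1 * recording.rate)
        seg = Waveform(recording.samples[i0:i1], recording.rate,
                       label=f"{recording.label}[rep{i + 1}]")
        j0, j1 = int(t0 * env.rate), int(t1 * env.rate)
        seg_env = EnvelopeSignal(env.values[j0:j1], env.rate)
        spec = modulation_spectrum(seg_env, fmax=syllable_search_band[1])
        in_band = spec.freqs >= syllable_search_band[0]
        if np.any(in_band) and np.any(spec.power[in_band] > 0):
            syl_rate = float(spec.freqs[in_band][np.argmax(spec.power[in_band])])
        else:
            syl_rate = 0.0
        mode = ("two_syllables_per_beat" if syl_rate / beat_rate >= 1.5
                else "one_syllable_per_beat")
        included, reason = True, None
        if i < n_repetitions - 3:
            included, reason = False, "early_repetition"
        if mode == "one_syllable_per_beat":
            included, reason = False, "syllable_timed"
        utterances.append(
            Utterance(waveform=seg, repetition_index=i + 1, start=t0, end=t1,
                      timing_mode=mode, included=included, exclusion_reason=reason)
        )
    return UtteranceSet(utterances=utterances, participant=metronome.participant,
                        group=metronome.group, sentence=metronome.sentence,
                        metre=metronome.metre)


def _utterance_pair_psi(
    w: Waveform,
    pair: tuple[str, str, int, int],
    cfg: AMBandConfig,
    env_rate: float,
    threshold_db: float | None,
) -> PSIResult:
    env = compute_envelope(w, env_rate=min(env_rate, w.rate))
    hier = extract_am_tiers(env, cfg)
    slow, fast, n, m = pair
    a1 = analytic_phase(hier.tier(slow), env.rate, slow)
    a2 = analytic_phase(hier.tier(fast), env.rate, fast)
    if threshold_db is None:
        mask = np.ones(env.values.size, dtype=bool)
    else:
        mask = _active_mask(env.values, threshold_db, int(round(0.05 * env.rate)))
    return psi(a1.phase[mask], a2.phase[mask], n, m)


def crossband_phase_analysis(
    utterance_sets: Sequence[UtteranceSet],
    pairs: Sequence[tuple[str, str, int, int]] = DEFAULT_PAIRS,
    band_config: AMBandConfig | None = None,
    env_rate: float = 1000.0,
    threshold_db: float | None = -40.0,
    alpha: float = 0.05,
    concatenate: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-frequency phase-locking per participant plus group comparisons.

    For every included utterance and tier pair, the PSI and generalized
    phase-difference angle are computed over within-utterance samples
    above the energy threshold (``threshold_db=None`` uses all samples).
    Per participant x sentence, repetition PSIs are averaged (or phases
    concatenated with ``concatenate=True``). Group comparisons per pair x
    metre: a two-sample t-test on PSI strength, and a Rayleigh-gated
    Watson-Williams test on per-participant mean difference angles.

    Returns ``(per_utterance_table, group_table)``.
    """
    cfg = band_config or AMBandConfig()
    rows = []
    for uset in utterance_sets:
        for utt in uset.utterances:
            if not utt.included:
                logger.info(
                    "excluded %s/%s rep %d: %s",
                    uset.participant, uset.sentence, utt.repetition_index,
                    utt.exclusion_reason,
                )
                continue
            for pair in pairs:
                res = _utterance_pair_psi(utt.waveform, pair, cfg, env_rate, threshold_db)
                rows.append(
                    {
                        "participant": uset.participant,
                        "group": uset.group,
                        "sentence": uset.sentence,
                        "metre": uset.metre,
                        "repetition": utt.repetition_index,
                        "pair": f"{pair[0]}:{pair[1]}",
                        "n": pair[2],
                        "m": pair[3],
                        "psi": res.psi,
                        "mean_diff_angle": res.mean_diff_angle,
                        "n_samples": res.n_samples,
                    }
                )
    per_utt = pd.DataFrame(rows)
    if per_utt.empty:
        return per_utt, pd.DataFrame()

    # participant-level summaries per pair x metre
    summaries = []
    for (pair, metre, participant), cell in per_utt.groupby(
        ["pair", "metre", "participant"], sort=False
    ):
        angles = cell["mean_diff_angle"].to_numpy()
        summaries.append(
            {
                "pair": pair,
                "metre": metre,
                "participant": participant,
                "group": cell["group"].iloc[0],
                "psi": float(cell["psi"].mean()),
                "mean_diff_angle": circ_mean_resultant(angles).mean_angle,
                "diff_resultant": circ_mean_resultant(angles).resultant_length,
            }
        )
    per_participant = pd.DataFrame(summaries)

    group_rows = []
    for (pair, metre), cell in per_participant.groupby(["pair", "metre"], sort=False):
        row: dict = {"pair": pair, "metre": metre}
        groups_present = sorted(cell["group"].unique())
        if len(groups_present) < 2:
            row["reason"] = "one group absent"
            group_rows.append(row)
            continue
        g1, g2 = groups_present[:2]
        s1 = cell[cell["group"] == g1]
        s2 = cell[cell["group"] == g2]
        t_res = stats.ttest_ind(s1["psi"], s2["psi"])
        row.update(
            {
                f"{g1}_psi_mean": float(s1["psi"].mean()),
                f"{g2}_psi_mean": float(s2["psi"].mean()),
                "strength_t": float(t_res.statistic),
                "strength_p": float(t_res.pvalue),
            }
        )
        gate_open = True
        angle_groups = []
        for g, sub in ((g1, s1), (g2, s2)):
            ang = sub["mean_diff_angle"].to_numpy()
            angle_groups.append(ang)
            row[f"{g}_mean_angle"] = circ_mean_resultant(ang).mean_angle
            if ang.size >= 4:
                ray = rayleigh_test(ang)
                row[f"{g}_rayleigh_p"] = ray.p
                gate_open &= ray.p < alpha
            else:
                gate_open = False
        if gate_open:
            ww = watson_williams(angle_groups)
            row.update(angle_F=ww.F, angle_df1=ww.df1, angle_df2=ww.df2,
                       angle_p=ww.p, angle_warning=ww.warning or "")
        else:
            row["reason"] = "failed phase-locking gate"
        group_rows.append(row)
    return per_utt, pd.DataFrame(group_rows)
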