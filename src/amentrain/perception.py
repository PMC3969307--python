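"""Tapping (rhythm-perception) pipeline.

Selects the analysable taps from each trial, computes inter-tap intervals,
tap distances to stressed-vowel onsets (P-centre proxies), per-participant
AM phase-of-tapping scores, group phase-locking tests with the
Rayleigh-gated Watson-Williams comparison, phase-literacy circular-linear
correlations, and the 14-bin compass histogram of phase scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .am_hierarchy import AnalyticTier, phase_at_times
from .circular import (
    circ_linear_corr,
    circ_mean_resultant,
    circ_median,
    rayleigh_test,
    watson_williams,
    wrap_angle,
)
from .errors import InsufficientDataError, InvalidInputError

logger = logging.getLogger(__name__)

__all__ = [
    "EventSeries",
    "TrialTiming",
    "PhaseScore",
    "CompassHistogram",
    "select_analysis_taps",
    "times_in_repetition",
    "inter_tap_intervals",
    "pcentre_distances",
    "participant_phase_scores",
    "group_entrainment_tests",
    "phase_literacy_correlations",
    "compass_histogram",
]

TIERS = ("stress", "syllable", "phoneme")
METRES = ("trochaic", "iambic")
GROUPS = ("control", "dyslexic")
BEHAVIOUR_MEASURES = ("reading", "spelling", "phonology")


@dataclass
class EventSeries:
    """Timestamped point events (taps, vowel onsets, metronome beats)."""

    times: np.ndarray
    kind: str = "tap"
    participant: str | None = None
    group: str | None = None
    sentence: str | None = None
    metre: str | None = None
    repetition: int | None = None
    excluded: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float).ravel()
        if self.times.size:
            if np.any(self.times < 0):
                raise InvalidInputError("event times must be nonnegative")
            if np.any(np.diff(self.times) <= 0):
                raise InvalidInputError("event times must be strictly ascending")

    def __len__(self) -> int:
        return self.times.size

    def with_times(self, times: np.ndarray, **kw) -> "EventSeries":
        out = replace(self, **kw)
        out.times = np.asarray(times, dtype=float)
        return out


@dataclass(frozen=True)
class TrialTiming:
    """Timing of one trial: a sentence repeated with silent gaps.

    ``repetition_starts`` are the onsets of each presentation; the gap
    between presentations equals the sentence duration by design.
    """

    sentence_duration: float
    repetition_starts: tuple[float, ...] = ()
    gap_duration: float | None = None
    stress_rate: float = 2.0

    def __post_init__(self) -> None:
        if self.sentence_duration <= 0:
            raise InvalidInputError("sentence_duration must be positive")
        gap = self.gap_duration if self.gap_duration is not None else self.sentence_duration
        object.__setattr__(self, "gap_duration", gap)
        if not self.repetition_starts:
            period = self.sentence_duration + gap
            object.__setattr__(self, "repetition_starts", tuple(i * period for i in range(3)))
        starts = np.asarray(self.repetition_starts, float)
        if starts.size and np.any(np.diff(starts) <= 0):
            raise InvalidInputError("repetition_starts must ascend")

    @property
    def n_beats_per_repetition(self) -> int:
        return int(round(self.sentence_duration * self.stress_rate))

    def beat_times(self, repetition: int) -> np.ndarray:
        """Expected stress-beat times within one repetition (0-indexed)."""
        start = self.repetition_starts[repetition]
        return start + np.arange(self.n_beats_per_repetition) / self.stress_rate


@dataclass
class PhaseScore:
    """One participant's phase-of-tapping score for one tier and metre."""

    participant: str
    group: str
    metre: str
    tier: str
    phase: float
    n_taps: int
    locked: bool
    sentence: str | None = None  # set for per-sentence (unaveraged) scores
    flags: tuple[str, ...] = ()


@dataclass
class CompassHistogram:
    """Equal-width circular histogram of phase scores over [-pi, pi]."""

    bin_edges: np.ndarray
    counts: np.ndarray

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


def select_analysis_taps(taps: EventSeries, t: TrialTiming) -> EventSeries:
    """Keep only taps from the 2nd and 3rd presentations of the sentence.

    Taps during the first presentation and the silent gaps are discarded.
    If a repetition window holds more taps than expected stress beats,
    each beat keeps its single nearest tap (greedy by distance, one tap
    per beat), capping the total at 2 x beats-per-repetition.
    """
    kept: list[float] = []
    n_beats = t.n_beats_per_repetition
    for rep in (1, 2):
        if rep >= len(t.repetition_starts):
            continue
        start = t.repetition_starts[rep]
        end = start + t.sentence_duration
        in_win = taps.times[(taps.times >= start) & (taps.times <= end)]
        if in_win.size > n_beats:
            beats = t.beat_times(rep)
            pairs = sorted(
                (abs(tap - b), bi, tap)
                for bi, b in enumerate(beats)
                for tap in in_win
            )
            used_beats: set[int] = set()
            used_taps: set[float] = set()
            chosen = []
            for _, bi, tap in pairs:
                if bi in used_beats or tap in used_taps:
                    continue
                used_beats.add(bi)
                used_taps.add(tap)
                chosen.append(tap)
            in_win = np.sort(chosen)
        kept.extend(in_win.tolist())
    out = taps.with_times(np.asarray(sorted(kept)))
    if len(out) == 0:
        out.excluded = True
        logger.warning(
            "participant %s sentence %s: no analysable taps; trial excluded",
            taps.participant, taps.sentence,
        )
    return out


def times_in_repetition(events: EventSeries, t: TrialTiming) -> np.ndarray:
    """Map trial-clock event times into sentence-recording time.

    Each event is referred to the start of the latest repetition at or
    before it, yielding times in [0, sentence_duration] suitable for
    phase lookup against the sentence's AM tiers.
    """
    starts = np.asarray(t.repetition_starts)
    idx = np.searchsorted(starts, events.times, side="right") - 1
    idx = np.clip(idx, 0, starts.size - 1)
    return events.times - starts[idx]


def inter_tap_intervals(taps: EventSeries | Iterable[EventSeries]) -> pd.DataFrame:
    """Successive inter-tap intervals in ms, one row per interval.

    Accepts a single series or an iterable; per-participant/sentence means
    are obtained by grouping the returned tidy table.
    """
    series = [taps] if isinstance(taps, EventSeries) else list(taps)
    rows = []
    for s in series:
        if len(s) < 2:
            logger.warning(
                "participant %s sentence %s: <2 taps, no ITIs", s.participant, s.sentence
            )
            continue
        itis = np.diff(s.times) * 1000.0
        for i, v in enumerate(itis):
            rows.append(
                {
                    "participant": s.participant,
                    "group": s.group,
                    "sentence": s.sentence,
                    "metre": s.metre,
                    "interval_index": i,
                    "iti_ms": v,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["participant", "group", "sentence", "metre", "interval_index", "iti_ms"],
    )


def pcentre_distances(taps: EventSeries, vowel_onsets: EventSeries) -> pd.DataFrame:
    """Signed distance (ms) from each tap to its nearest stressed-vowel onset.

    Positive = tap after the onset. Both series must share a clock.
    """
    if len(vowel_onsets) == 0:
        raise InvalidInputError("no vowel onsets provided")
    rows = []
    onsets = vowel_onsets.times
    for tap in taps.times:
        j = int(np.argmin(np.abs(onsets - tap)))
        rows.append(
            {
                "participant": taps.participant,
                "group": taps.group,
                "sentence": taps.sentence,
                "metre": taps.metre,
                "tap_s": tap,
                "onset_s": onsets[j],
                "distance_ms": (tap - onsets[j]) * 1000.0,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["participant", "group", "sentence", "metre", "tap_s", "onset_s", "distance_ms"],
    )


def _sentence_tap_phases(
    taps: EventSeries,
    timing: TrialTiming,
    tier: AnalyticTier,
) -> np.ndarray:
    rel = times_in_repetition(taps, timing)
    phases = phase_at_times(tier, rel)
    return phases[np.isfinite(phases)]


def participant_phase_scores(
    selected_taps: Sequence[EventSeries],
    tiers: Mapping[str, Mapping[str, AnalyticTier]],
    timings: Mapping[str, TrialTiming],
    alpha: float = 0.05,
) -> list[PhaseScore]:
    """Phase-of-tapping scores for one participant.

    For each sentence and tier, the circular median of that sentence's tap
    phases is taken; per metre and tier, the circular mean of the two
    same-metre sentence medians gives the participant's score. ``locked``
    is an individual-level Rayleigh test (alpha) on the pooled tap phases
    of that metre and tier.

    Parameters
    ----------
    selected_taps : one EventSeries per sentence trial (already through
        :func:`select_analysis_taps`), carrying sentence/metre labels.
    tiers : sentence -> tier name -> AnalyticTier of that sentence.
    timings : sentence -> TrialTiming of that trial.
    """
    if not selected_taps:
        raise InvalidInputError("no tap series given")
    participant = selected_taps[0].participant
    group = selected_taps[0].group
    scores: list[PhaseScore] = []
    by_metre: dict[str, list[EventSeries]] = {}
    for s in selected_taps:
        if s.excluded or len(s) == 0:
            continue
        by_metre.setdefault(s.metre, []).append(s)
    for metre, series in by_metre.items():
        for tier_name in TIERS:
            medians = []
            pooled = []
            n_taps = 0
            flags: list[str] = []
            for s in series:
                if s.sentence not in tiers:
                    raise InvalidInputError(f"missing tiers for sentence {s.sentence!r}")
                tier = tiers[s.sentence][tier_name]
                ph = _sentence_tap_phases(s, timings[s.sentence], tier)
                if ph.size == 0:
                    flags.append(f"no_valid_phases:{s.sentence}")
                    continue
                medians.append(circ_median(ph))
                pooled.extend(ph.tolist())
                n_taps += ph.size
            if not medians:
                continue
            if len(medians) == 1 and len(series) > 1:
                flags.append("single_sentence_fallback")
            elif len(series) == 1:
                flags.append("single_sentence_available")
            score = circ_mean_resultant(medians).mean_angle
            locked = False
            if len(pooled) >= 4:
                locked = rayleigh_test(pooled).p < alpha
            scores.append(
                PhaseScore(
                    participant=participant,
                    group=group,
                    metre=metre,
                    tier=tier_name,
                    phase=float(score),
                    n_taps=n_taps,
                    locked=locked,
                    flags=tuple(flags),
                )
            )
    return scores


def group_entrainment_tests(
    scores: Sequence[PhaseScore],
    alpha: float = 0.05,
    locked_only: bool = False,
) -> pd.DataFrame:
    """Rayleigh per group and gated Watson-Williams, per tier x metre.

    The Watson-Williams comparison of group mean phases runs only when
    *both* groups' Rayleigh tests reject uniformity at ``alpha`` for that
    tier x metre; otherwise the row records the suppression reason.
    """
    rows = []
    df = pd.DataFrame(
        [
            {
                "participant": s.participant,
                "group": s.group,
                "metre": s.metre,
                "tier": s.tier,
                "phase": s.phase,
                "locked": s.locked,
            }
            for s in scores
        ]
    )
    if locked_only and not df.empty:
        df = df[df["locked"]]
    for (tier, metre), cell in df.groupby(["tier", "metre"], sort=False):
        row: dict = {"tier": tier, "metre": metre}
        gate_open = True
        present = sorted(cell["group"].unique())
        if len(present) < 2:
            row["ww_reason"] = f"group absent ({present})"
            rows.append(row)
            continue
        group_phases = {}
        for g in present:
            ph = cell.loc[cell["group"] == g, "phase"].to_numpy()
            group_phases[g] = ph
            summary = circ_mean_resultant(ph)
            row[f"{g}_n"] = ph.size
            row[f"{g}_mean_phase"] = summary.mean_angle
            row[f"{g}_resultant"] = summary.resultant_length
            try:
                ray = rayleigh_test(ph)
                row[f"{g}_rayleigh_z"] = ray.z
                row[f"{g}_rayleigh_p"] = ray.p
                if ray.p >= alpha:
                    gate_open = False
            except InsufficientDataError:
                row[f"{g}_rayleigh_p"] = np.nan
                gate_open = False
        if gate_open:
            ww = watson_williams([group_phases[g] for g in present])
            row.update(
                ww_F=ww.F, ww_df1=ww.df1, ww_df2=ww.df2, ww_p=ww.p,
                ww_warning=ww.warning or "",
            )
        else:
            row["ww_reason"] = "failed phase-locking gate"
        rows.append(row)
    return pd.DataFrame(rows)


def phase_literacy_correlations(
    scores: Sequence[PhaseScore],
    behaviour: pd.DataFrame,
    measures: Sequence[str] = BEHAVIOUR_MEASURES,
    n_permutations: int = 0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Circular-linear correlations of phase scores with behaviour measures.

    One row per tier x metre x measure x stratum (all / control / dyslexic);
    p-values are uncorrected for multiple comparisons and flagged as such.
    """
    if "participant" not in behaviour.columns:
        raise InvalidInputError("behaviour table needs a 'participant' column")
    sdf = pd.DataFrame(
        [
            {"participant": s.participant, "group": s.group, "metre": s.metre,
             "tier": s.tier, "phase": s.phase}
            for s in scores
        ]
    )
    beh = behaviour.drop(columns=[c for c in ("group", "metre", "tier") if c in behaviour])
    merged = sdf.merge(beh, on="participant", how="inner")
    dropped = set(sdf["participant"]) - set(merged["participant"])
    if dropped:
        logger.warning("dropped %d participants lacking behaviour rows: %s",
                       len(dropped), sorted(dropped))
    rows = []
    for (tier, metre), cell in merged.groupby(["tier", "metre"], sort=False):
        for measure in measures:
            for stratum in ("all",) + tuple(GROUPS):
                sub = cell if stratum == "all" else cell[cell["group"] == stratum]
                row = {
                    "tier": tier, "metre": metre, "measure": measure,
                    "stratum": stratum, "n": len(sub),
                    "p_correction": "uncorrected",
                }
                try:
                    res = circ_linear_corr(
                        sub["phase"].to_numpy(), sub[measure].to_numpy(),
                        n_permutations=n_permutations, seed=seed,
                    )
                    row.update(r=res.r, p=res.p, p_permutation=res.p_permutation)
                except (InsufficientDataError, InvalidInputError) as exc:
                    row.update(r=np.nan, p=np.nan, error=str(exc))
                rows.append(row)
    return pd.DataFrame(rows)


def compass_histogram(scores: Sequence[PhaseScore] | np.ndarray, nbins: int = 14) -> CompassHistogram:
    """Bin phase scores into ``nbins`` equal bins spanning [-pi, pi].

    Bins are left-closed/right-open except the last, which is closed, so
    +pi falls in the final bin.
    """
    if len(scores) and isinstance(scores[0], PhaseScore):
        angles = np.array([s.phase for s in scores])
    else:
        angles = np.asarray(scores, dtype=float)
    edges = np.linspace(-np.pi, np.pi, nbins + 1)
    counts, _ = np.histogram(wrap_angle(angles), bins=edges)
    return CompassHistogram(bin_edges=edges, counts=counts)
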