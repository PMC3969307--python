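import numpy as np
import pandas as pd
import pytest

from amentrain import (
    EventSeries,
    TrialTiming,
    circ_median,
    compass_histogram,
    group_entrainment_tests,
    inter_tap_intervals,
    participant_phase_scores,
    pcentre_distances,
    phase_literacy_correlations,
    select_analysis_taps,
)
from amentrain.errors import InvalidInputError
from amentrain.perception import PhaseScore, times_in_repetition

from conftest import cosine_tier

TIMING = TrialTiming(sentence_duration=2.0, stress_rate=2.0)  # reps at 0, 4, 8 s


def make_scores(phases, group="control", metre="trochaic", tier="syllable", locked=True):
    return [
        PhaseScore(participant=f"p{i}", group=group, metre=metre, tier=tier,
                   phase=float(p), n_taps=16, locked=locked)
        for i, p in enumerate(phases)
    ]


class TestSelectAnalysisTaps:
    def test_ideal_metronomic_taps_keep_exactly_eight(self):
        taps = EventSeries(np.arange(20) * 0.5, kind="tap")  # every 500 ms, whole trial
        sel = select_analysis_taps(taps, TIMING)
        assert len(sel) == 8
        in_windows = ((sel.times >= 4) & (sel.times <= 6)) | (
            (sel.times >= 8) & (sel.times <= 10)
        )
        assert np.all(in_windows)

    def test_taps_only_in_gaps_excluded(self):
        taps = EventSeries([2.5, 3.0, 6.5, 7.0], kind="tap")  # silent gaps only
        sel = select_analysis_taps(taps, TIMING)
        assert len(sel) == 0
        assert sel.excluded

    def test_double_tap_keeps_nearer(self):
        beats = TIMING.beat_times(1)  # 4.0, 4.5, 5.0, 5.5
        times = np.sort(np.concatenate([beats + 0.02, [beats[1] + 0.1]]))
        sel = select_analysis_taps(EventSeries(times), TIMING)
        assert len(sel) == 4
        assert beats[1] + 0.02 in sel.times
        assert beats[1] + 0.1 not in sel.times

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        taps = EventSeries(np.sort(rng.uniform(0, 12, 25)))
        once = select_analysis_taps(taps, TIMING)
        twice = select_analysis_taps(once, TIMING)
        assert np.array_equal(once.times, twice.times)

    def test_sparse_in_window_taps_all_kept(self):
        taps = EventSeries([4.1, 5.3, 9.0])
        sel = select_analysis_taps(taps, TIMING)
        assert np.array_equal(sel.times, [4.1, 5.3, 9.0])


class TestInterTapIntervals:
    def test_ideal_500ms_intervals(self):
        df = inter_tap_intervals(EventSeries([0, 0.5, 1.0, 1.5], participant="p1"))
        assert list(df["iti_ms"]) == [500.0, 500.0, 500.0]
        assert df["iti_ms"].mean() == 500.0

    def test_control_like_mean(self):
        # 525 ms mean ITI, the control-group scale
        df = inter_tap_intervals(EventSeries([0, 0.525, 1.050]))
        assert df["iti_ms"].mean() == pytest.approx(525.0)

    def test_unsorted_input_rejected_by_invariant(self):
        with pytest.raises(InvalidInputError):
            EventSeries([0.5, 0.2, 1.0])

    def test_single_tap_yields_empty(self):
        assert inter_tap_intervals(EventSeries([1.0])).empty


class TestPcentreDistances:
    ONSETS = EventSeries(np.array([0.25, 0.75, 1.25, 1.75]), kind="vowel_onset")

    def test_taps_on_onsets_zero_distance(self):
        df = pcentre_distances(EventSeries(self.ONSETS.times), self.ONSETS)
        assert np.allclose(df["distance_ms"], 0.0)

    def test_late_taps_positive_distance(self):
        # positive = tap after the vowel onset
        df = pcentre_distances(EventSeries(self.ONSETS.times + 0.03), self.ONSETS)
        assert np.allclose(df["distance_ms"], 30.0)
        assert df["distance_ms"].mean() == pytest.approx(30.0)

    def test_symmetric_errors_cancel(self):
        taps = EventSeries([0.25 - 0.04, 0.75 + 0.04])
        df = pcentre_distances(taps, self.ONSETS)
        assert df["distance_ms"].mean() == pytest.approx(0.0)


class TwoSentenceSetup:
    """Two same-metre 'sentences' whose tiers are pure 4 Hz cosines."""

    @pytest.fixture()
    def setup(self):
        tier = cosine_tier(4.0, duration=2.0)
        tiers = {s: {"stress": cosine_tier(2.0, 2.0), "syllable": tier,
                     "phoneme": cosine_tier(12.0, 2.0)} for s in ("s1", "s2")}
        timings = {s: TIMING for s in ("s1", "s2")}
        return tiers, timings


class TestParticipantPhaseScores(TwoSentenceSetup):
    def taps_at_phase(self, phase, sentence):
        # taps in repetition windows 2-3, offset from 4 Hz cosine peaks
        base = np.concatenate([TIMING.beat_times(1), TIMING.beat_times(2)])
        return EventSeries(base + phase / (2 * np.pi * 4.0), kind="tap",
                           participant="p1", group="control",
                           sentence=sentence, metre="trochaic")

    def test_constant_phase_recovered(self, setup):
        tiers, timings = setup
        taps = [self.taps_at_phase(0.40 * np.pi, s) for s in ("s1", "s2")]
        scores = participant_phase_scores(taps, tiers, timings)
        syl = next(s for s in scores if s.tier == "syllable")
        assert syl.phase == pytest.approx(0.40 * np.pi, abs=0.03)
        assert syl.metre == "trochaic"
        assert syl.n_taps == 16
        assert syl.locked

    def test_uniform_taps_not_locked(self, setup):
        tiers, timings = setup
        # 8 taps spread evenly over one 250 ms cycle -> uniform phases
        spread = np.linspace(0, 0.25, 9)[:-1]
        times = np.sort(np.concatenate([4.0 + spread, 8.0 + spread + 0.03]))
        taps = [EventSeries(times, participant="p1", group="control",
                            sentence="s1", metre="trochaic")]
        scores = participant_phase_scores(taps, {"s1": tiers["s1"]},
                                          {"s1": timings["s1"]})
        syl = next(s for s in scores if s.tier == "syllable")
        assert not syl.locked

    def test_metre_score_is_circular_mean_of_sentence_medians(self, setup):
        tiers, timings = setup
        taps = [self.taps_at_phase(0.0, "s1"), self.taps_at_phase(np.pi / 2, "s2")]
        scores = participant_phase_scores(taps, tiers, timings)
        syl = next(s for s in scores if s.tier == "syllable")
        assert syl.phase == pytest.approx(np.pi / 4, abs=0.03)

    def test_missing_tier_errors(self, setup):
        _, timings = setup
        taps = [self.taps_at_phase(0.0, "s1")]
        with pytest.raises((InvalidInputError, KeyError)):
            participant_phase_scores(taps, {"s1": {}}, timings)

    def test_single_sentence_fallback_flagged(self, setup):
        tiers, timings = setup
        taps = [self.taps_at_phase(0.1, "s1"),
                EventSeries([2.5], participant="p1", sentence="s2", metre="trochaic")]
        scores = participant_phase_scores(taps, tiers, timings)
        syl = next(s for s in scores if s.tier == "syllable")
        assert any("no_valid_phases" in f or "fallback" in f for f in syl.flags) or syl.n_taps == 8

    def test_rotation_property(self, setup):
        # delaying every tap by dt shifts the 4 Hz tier score by 2*pi*f*dt
        tiers, timings = setup
        dt = 0.02
        base = [self.taps_at_phase(0.2, s) for s in ("s1", "s2")]
        shifted = [t.with_times(t.times + dt) for t in base]
        s0 = participant_phase_scores(base, tiers, timings)
        s1 = participant_phase_scores(shifted, tiers, timings)
        syl0 = next(s for s in s0 if s.tier == "syllable")
        syl1 = next(s for s in s1 if s.tier == "syllable")
        expected = syl0.phase + 2 * np.pi * 4.0 * dt
        assert np.angle(np.exp(1j * (syl1.phase - expected))) == pytest.approx(0.0, abs=0.03)
        # ITIs unchanged
        assert np.allclose(
            inter_tap_intervals(base[0])["iti_ms"],
            inter_tap_intervals(shifted[0])["iti_ms"],
        )

    def test_pcentre_phase_consistency(self, setup):
        # taps 30 ms after 4 Hz onsets: distance +30 ms and phase ~ +0.24*pi
        tiers, timings = setup
        onset_base = np.concatenate([TIMING.beat_times(1), TIMING.beat_times(2)])
        taps = [EventSeries(onset_base + 0.030, participant="p1", group="control",
                            sentence="s1", metre="trochaic")]
        rel = taps[0].with_times(times_in_repetition(taps[0], TIMING))
        onsets = EventSeries(np.unique(times_in_repetition(
            EventSeries(onset_base), TIMING)), kind="vowel_onset")
        dist = pcentre_distances(rel, onsets)
        assert dist["distance_ms"].mean() == pytest.approx(30.0, abs=1e-6)
        scores = participant_phase_scores(taps, {"s1": tiers["s1"]}, {"s1": TIMING})
        syl = next(s for s in scores if s.tier == "syllable")
        assert syl.phase == pytest.approx(30 / 250 * 2 * np.pi, abs=0.03)


class TestGroupEntrainmentTests:
    def test_gate_open_when_both_groups_concentrated(self):
        rng = np.random.default_rng(0)
        scores = make_scores(rng.vonmises(0.4 * np.pi, 8, 20), "control") + make_scores(
            rng.vonmises(0.09 * np.pi, 8, 20), "dyslexic"
        )
        df = group_entrainment_tests(scores)
        row = df.iloc[0]
        assert row["control_rayleigh_p"] < 0.05
        assert row["dyslexic_rayleigh_p"] < 0.05
        assert np.isfinite(row["ww_F"])

    def test_gate_closed_when_one_group_uniform(self):
        rng = np.random.default_rng(1)
        scores = make_scores(rng.vonmises(0.4 * np.pi, 8, 20), "control") + make_scores(
            rng.uniform(-np.pi, np.pi, 20), "dyslexic"
        )
        df = group_entrainment_tests(scores)
        assert df.iloc[0]["ww_reason"] == "failed phase-locking gate"
        assert "ww_F" not in df.columns or pd.isna(df.iloc[0].get("ww_F"))

    def test_absent_group_skipped_with_reason(self):
        scores = make_scores(np.full(10, 0.3))
        df = group_entrainment_tests(scores)
        assert "absent" in df.iloc[0]["ww_reason"]

    def test_true_offset_detected(self):
        rng = np.random.default_rng(2)
        detected = 0
        for _ in range(30):
            scores = make_scores(rng.vonmises(0.40 * np.pi, 5, 22), "control") + make_scores(
                rng.vonmises(0.09 * np.pi, 5, 21), "dyslexic"
            )
            row = group_entrainment_tests(scores).iloc[0]
            if "ww_p" in row and pd.notna(row.get("ww_p")) and row["ww_p"] < 0.05:
                detected += 1
        assert detected >= 24  # >= 80%


class TestPhaseLiteracyCorrelations:
    def make_full_scores(self, rng):
        scores = []
        for group, n in (("control", 22), ("dyslexic", 21)):
            for metre in ("trochaic", "iambic"):
                for tier in ("stress", "syllable", "phoneme"):
                    phases = rng.uniform(-np.pi, np.pi, n)
                    for i, p in enumerate(phases):
                        scores.append(PhaseScore(f"{group[0]}{i}", group, metre, tier,
                                                 float(p), 16, True))
        return scores

    def test_planted_dependence_recovered(self):
        rng = np.random.default_rng(0)
        scores = make_scores(rng.uniform(-np.pi, np.pi, 40))
        behaviour = pd.DataFrame(
            {
                "participant": [s.participant for s in scores],
                "reading": [np.cos(s.phase) + 0.05 * rng.standard_normal() for s in scores],
                "spelling": rng.standard_normal(40),
                "phonology": rng.standard_normal(40),
            }
        )
        df = phase_literacy_correlations(scores, behaviour)
        cell = df[(df["measure"] == "reading") & (df["stratum"] == "all")].iloc[0]
        assert cell["r"] > 0.9
        assert (df["p_correction"] == "uncorrected").all()

    def test_54_cells(self):
        rng = np.random.default_rng(1)
        scores = self.make_full_scores(rng)
        participants = sorted({s.participant for s in scores})
        behaviour = pd.DataFrame(
            {
                "participant": participants,
                "reading": rng.standard_normal(len(participants)),
                "spelling": rng.standard_normal(len(participants)),
                "phonology": rng.standard_normal(len(participants)),
            }
        )
        df = phase_literacy_correlations(scores, behaviour)
        assert len(df) == 54  # 3 tiers x 2 metres x 3 measures x 3 strata

    def test_independent_behaviour_small_r(self):
        rng = np.random.default_rng(3)
        scores = make_scores(rng.uniform(-np.pi, np.pi, 500))
        behaviour = pd.DataFrame(
            {
                "participant": [s.participant for s in scores],
                "reading": rng.standard_normal(500),
                "spelling": rng.standard_normal(500),
                "phonology": rng.standard_normal(500),
            }
        )
        df = phase_literacy_correlations(scores, behaviour)
        cell = df[(df["measure"] == "reading") & (df["stratum"] == "all")].iloc[0]
        assert cell["r"] < 0.15


class TestCompassHistogram:
    def test_scores_at_bin_centres(self):
        edges = np.linspace(-np.pi, np.pi, 15)
        centres = (edges[:-1] + edges[1:]) / 2
        hist = compass_histogram(make_scores(centres))
        assert np.array_equal(hist.counts, np.ones(14, dtype=int))

    def test_identical_scores_single_bin(self):
        hist = compass_histogram(make_scores(np.full(9, 0.7)))
        assert hist.counts.max() == 9
        assert hist.counts.sum() == 9

    def test_bin_width(self):
        hist = compass_histogram(make_scores([0.0]))
        assert hist.bin_width == pytest.approx(2 * np.pi / 14)
        assert hist.bin_edges.size == 15

    def test_plus_pi_lands_in_last_bin(self):
        hist = compass_histogram(np.array([np.pi]))
        assert hist.counts[-1] == 1


class TestEndToEndRecovery:
    def test_parameter_recovery_kappa10(self, recovery_stimuli):
        # planted syllable-phase offset recovered within 0.05*pi (median over seeds)
        from amentrain.synth import ResponseSpec, synth_tap_train

        stimuli, tiers, timings = recovery_stimuli
        timing = timings["troch1"]
        delta = 0.3 * np.pi
        errors = []
        for seed in range(60):  # scaled from 200; see ledger
            taps = []
            for name, truth in stimuli.items():
                r = ResponseSpec(tier_target="syllable", phase_offset=delta,
                                 kappa=10.0, seed=seed * 10 + hash(name) % 10)
                taps.append(
                    synth_tap_train(truth.stress_beats, timing, r,
                                    participant="p", group="control",
                                    sentence=name, metre=truth.spec.metre)
                )
            selected = [taps_sel for taps_sel in
                        (select_analysis_taps(t, timing) for t in taps) if len(taps_sel)]
            scores = participant_phase_scores(selected, tiers, timings)
            for s in scores:
                if s.tier == "syllable":
                    errors.append(abs(np.angle(np.exp(1j * (s.phase - delta)))))
        assert np.median(errors) < 0.05 * np.pi
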