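"""Pipeline orchestration: ties the stages into the two experiments.

Each mode reads its inputs per the run configuration, executes the
analysis stages, and writes tidy tables plus a machine-readable manifest
(inputs, package versions, config hash, status). On failure, partial
results stay on disk and the failure reason lands in the manifest.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy

from . import __version__
from .am_hierarchy import (
    AMBandConfig,
    analytic_phase,
    compute_envelope,
    extract_am_tiers,
    modulation_spectrum,
    spectral_band_filter,
    write_modspectrum,
)
from .config import RunConfig
from .errors import AmentrainError, InvalidInputError
from .perception import (
    EventSeries,
    TrialTiming,
    compass_histogram,
    group_entrainment_tests,
    inter_tap_intervals,
    pcentre_distances,
    participant_phase_scores,
    phase_literacy_correlations,
    select_analysis_taps,
    times_in_repetition,
)
from .production import (
    crossband_phase_analysis,
    phase_heatmap,
    segment_utterances,
    vowel_onset_intervals,
)
from .synth import (
    BehaviourLink,
    CohortSpec,
    StimulusSpec,
    synth_cohort,
)
from . import io as amio

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline"]


def _band_config(cfg: RunConfig) -> AMBandConfig:
    b = cfg.bands
    return AMBandConfig(
        stress_band=tuple(b.stress_band),
        syllable_band=tuple(b.syllable_band),
        phoneme_band=tuple(b.phoneme_band),
        filter_order=b.filter_order,
    )


def _sentence_tiers(cfg: RunConfig, wav):
    """Envelope -> AM hierarchy -> analytic tiers for one sentence recording."""
    if cfg.spectral_band != "broadband":
        bands = spectral_band_filter(wav)
        idx = int(cfg.spectral_band) - 1
        if not 0 <= idx < len(bands):
            raise InvalidInputError(f"spectral_band {cfg.spectral_band} out of range")
        wav = bands[idx]
    env = compute_envelope(wav, env_rate=min(cfg.envelope_rate, wav.rate))
    hier = extract_am_tiers(env, _band_config(cfg))
    tiers = {name: analytic_phase(hier.tier(name), env.rate, name)
             for name in ("stress", "syllable", "phoneme")}
    return env, hier, tiers


def _write_manifest(out: Path, cfg: RunConfig, mode: str, inputs: dict,
                    status: str, reason: str | None = None) -> None:
    manifest = {
        "mode": mode,
        "status": status,
        "failure_reason": reason,
        "config_hash": cfg.config_hash(),
        "config": cfg.model_dump(mode="json"),
        "inputs": inputs,
        "versions": {
            "amentrain": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def run_pipeline(cfg: RunConfig, mode: str, out_dir: str | Path | None = None) -> Path:
    """Run one pipeline mode; returns the output directory.

    Raises on failure after writing a 'failed' manifest alongside any
    partial results.
    """
    out = Path(out_dir or cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    runners = {"simulate": _run_simulate, "perception": _run_perception,
               "production": _run_production}
    if mode not in runners:
        raise InvalidInputError(f"unknown mode {mode!r}")
    inputs: dict = {}
    try:
        runners[mode](cfg, out, inputs)
    except Exception as exc:
        _write_manifest(out, cfg, mode, inputs, "failed", repr(exc))
        raise
    _write_manifest(out, cfg, mode, inputs, "ok")
    return out


# ---------------------------------------------------------------- simulate


def _run_simulate(cfg: RunConfig, out: Path, inputs: dict) -> None:
    sim = cfg.simulate
    stim_spec = StimulusSpec(
        syllable_rate=sim.syllable_rate,
        stress_rate=sim.syllable_rate / 2,
        n_syllables=sim.n_syllables,
        sample_rate=sim.sample_rate,
        seed=cfg.seed,
    )
    cohort_spec = CohortSpec(
        n_control=sim.n_control,
        n_dyslexic=sim.n_dyslexic,
        group_phase_offsets={
            "control": sim.control_offset_pi * np.pi,
            "dyslexic": sim.dyslexic_offset_pi * np.pi,
        },
        participant_kappa=sim.participant_kappa,
        tap_kappa=sim.tap_kappa,
        behaviour_model={
            "reading": BehaviourLink(),
            "spelling": BehaviourLink(),
            "phonology": BehaviourLink(),
        },
        seed=cfg.seed,
    )
    cohort = synth_cohort(cohort_spec, stim_spec)
    audio_dir = out / "audio"
    audio_dir.mkdir(exist_ok=True)
    onset_series = []
    for name, truth in cohort.stimuli.items():
        amio.write_wav(audio_dir / f"{name}.wav", truth.waveform)
        onset_series.append(
            truth.stress_beats.with_times(truth.stress_beats.times, sentence=name)
        )
        spec = modulation_spectrum(
            compute_envelope(truth.waveform, env_rate=min(cfg.envelope_rate, truth.waveform.rate)),
            fmax=20.0,
        )
        write_modspectrum(out / f"modspectrum_{name}.csv", spec)
    amio.write_events(out / "taps.csv", cohort.taps)
    amio.write_events(out / "onsets.csv", onset_series)
    amio.write_table(out / "behaviour.csv", cohort.behaviour)
    truth_doc = {
        "group_phase_offsets": {k: float(v) for k, v in
                                cohort.spec.group_phase_offsets.items()},
        "participants": cohort.participants.to_dict(orient="records"),
        "sentence_duration": cohort.timing.sentence_duration,
        "repetition_starts": list(cohort.timing.repetition_starts),
        "stress_rate": cohort.timing.stress_rate,
        "syllable_rate": stim_spec.syllable_rate,
        "seed": cfg.seed,
    }
    (out / "truth.json").write_text(json.dumps(truth_doc, indent=2, sort_keys=True))
    inputs["generated"] = sorted(p.name for p in out.iterdir())


# -------------------------------------------------------------- perception


def _load_trial(cfg: RunConfig, duration: float) -> TrialTiming:
    dur = cfg.trial.sentence_duration or duration
    period = 2 * dur  # silent gap equal to the sentence length
    starts = tuple(i * period for i in range(cfg.trial.n_repetitions))
    return TrialTiming(sentence_duration=dur, repetition_starts=starts,
                       stress_rate=cfg.trial.stress_rate)


def _run_perception(cfg: RunConfig, out: Path, inputs: dict) -> None:
    if not cfg.audio_dir or not cfg.taps_file:
        raise InvalidInputError("perception mode needs audio_dir and taps_file")
    audio_dir = Path(cfg.audio_dir)
    inputs["audio_dir"] = str(audio_dir)
    inputs["taps_file"] = str(cfg.taps_file)

    tiers, timings = {}, {}
    for sentence, metre in cfg.sentences.items():
        wav_path = audio_dir / f"{sentence}.wav"
        if not wav_path.exists():
            raise InvalidInputError(f"missing audio file: {wav_path}")
        wav = amio.read_wav(wav_path)
        _, _, tiers[sentence] = _sentence_tiers(cfg, wav)
        timings[sentence] = _load_trial(cfg, wav.duration)

    taps_df = amio.read_event_table(cfg.taps_file)
    onsets_by_sentence = {}
    if cfg.onsets_file:
        inputs["onsets_file"] = str(cfg.onsets_file)
        odf = amio.read_event_table(cfg.onsets_file)
        for sentence, sub in odf.groupby("sentence"):
            onsets_by_sentence[sentence] = EventSeries(
                np.unique(sub["time_s"].to_numpy()), kind="vowel_onset", sentence=sentence
            )

    selected, all_scores, iti_frames, dist_frames = [], [], [], []
    for (participant, sentence), sub in taps_df.groupby(["participant", "sentence"]):
        if sentence not in cfg.sentences:
            logger.warning("skipping unknown sentence %r", sentence)
            continue
        series = EventSeries(
            np.unique(sub["time_s"].to_numpy()) + cfg.trial.clock_offset,
            kind="tap",
            participant=str(participant),
            group=str(sub["group"].iloc[0]) if "group" in sub else None,
            sentence=sentence,
            metre=cfg.sentences[sentence],
        )
        sel = select_analysis_taps(series, timings[sentence])
        selected.append(sel)
        if len(sel) >= 2:
            iti_frames.append(inter_tap_intervals(sel))
        if sentence in onsets_by_sentence and len(sel):
            rel = sel.with_times(np.unique(times_in_repetition(sel, timings[sentence])))
            dist_frames.append(pcentre_distances(rel, onsets_by_sentence[sentence]))

    for participant, group_series in _group_by_participant(selected).items():
        usable = [s for s in group_series if not s.excluded and len(s)]
        if not usable:
            continue
        all_scores.extend(participant_phase_scores(usable, tiers, timings,
                                                   alpha=cfg.rayleigh_alpha))

    amio.write_table(out / "iti.csv",
                     pd.concat(iti_frames, ignore_index=True) if iti_frames else pd.DataFrame())
    if dist_frames:
        amio.write_table(out / "pcentre_distances.csv",
                         pd.concat(dist_frames, ignore_index=True))
    scores_df = pd.DataFrame(
        [
            {"participant": s.participant, "group": s.group, "metre": s.metre,
             "tier": s.tier, "phase_rad": s.phase, "n_taps": s.n_taps,
             "locked": s.locked, "flags": ";".join(s.flags)}
            for s in all_scores
        ]
    )
    amio.write_table(out / "phase_scores.csv", scores_df)
    amio.write_table(out / "group_tests.csv",
                     group_entrainment_tests(all_scores, alpha=cfg.rayleigh_alpha))

    hist_rows = []
    for (tier, metre, group), cell in scores_df.groupby(["tier", "metre", "group"]):
        hist = compass_histogram(cell["phase_rad"].to_numpy())
        for i, count in enumerate(hist.counts):
            hist_rows.append({"tier": tier, "metre": metre, "group": group,
                              "bin_lo_rad": hist.bin_edges[i],
                              "bin_hi_rad": hist.bin_edges[i + 1],
                              "count": int(count)})
    amio.write_table(out / "compass_histograms.csv", pd.DataFrame(hist_rows))

    if cfg.behaviour_file:
        inputs["behaviour_file"] = str(cfg.behaviour_file)
        behaviour = pd.read_csv(cfg.behaviour_file)
        amio.write_table(out / "phase_literacy_correlations.csv",
                         phase_literacy_correlations(all_scores, behaviour))


def _group_by_participant(series: list[EventSeries]) -> dict[str, list[EventSeries]]:
    out: dict[str, list[EventSeries]] = {}
    for s in series:
        out.setdefault(s.participant, []).append(s)
    return out


# -------------------------------------------------------------- production


def _run_production(cfg: RunConfig, out: Path, inputs: dict) -> None:
    if not cfg.recordings_manifest:
        raise InvalidInputError("production mode needs recordings_manifest")
    inputs["recordings_manifest"] = str(cfg.recordings_manifest)
    manifest = pd.read_csv(cfg.recordings_manifest)
    required = {"participant", "group", "sentence", "metre", "path"}
    if not required <= set(manifest.columns):
        raise InvalidInputError(f"recordings manifest needs columns {sorted(required)}")

    sets = []
    exclusion_rows = []
    for _, row in manifest.iterrows():
        wav = amio.read_wav(row["path"])
        beats = EventSeries(
            np.arange(0.0, wav.duration, 1.0 / cfg.metronome_rate),
            kind="metronome", participant=str(row["participant"]),
            group=str(row["group"]), sentence=str(row["sentence"]),
            metre=str(row["metre"]),
        )
        uset = segment_utterances(wav, beats, threshold_db=cfg.energy_threshold_db)
        sets.append(uset)
        for utt in uset.utterances:
            if not utt.included:
                exclusion_rows.append(
                    {"participant": uset.participant, "sentence": uset.sentence,
                     "repetition": utt.repetition_index,
                     "reason": utt.exclusion_reason}
                )
    amio.write_table(out / "exclusions.csv", pd.DataFrame(exclusion_rows))

    per_utt, group_table = crossband_phase_analysis(
        sets, band_config=_band_config(cfg), env_rate=cfg.envelope_rate,
        threshold_db=cfg.energy_threshold_db, alpha=cfg.rayleigh_alpha,
    )
    amio.write_table(out / "psi_per_utterance.csv", per_utt)
    amio.write_table(out / "psi_group.csv", group_table)

    if cfg.onsets_file:
        inputs["onsets_file"] = str(cfg.onsets_file)
        odf = amio.read_event_table(cfg.onsets_file)
        series = []
        keys = [k for k in ("participant", "group", "sentence", "metre", "repetition")
                if k in odf.columns]
        for key_vals, sub in odf.groupby(keys):
            labels = dict(zip(keys, key_vals if isinstance(key_vals, tuple) else (key_vals,)))
            if "repetition" in labels:
                labels["repetition"] = int(labels["repetition"])
            series.append(EventSeries(np.unique(sub["time_s"].to_numpy()),
                                      kind="vowel_onset", **labels))
        amio.write_table(out / "voi.csv", vowel_onset_intervals(series))

    _write_heatmaps(cfg, out, sets)


def _write_heatmaps(cfg: RunConfig, out: Path, sets) -> None:
    """Pooled syllable:phoneme joint phase heatmap per group."""
    phases: dict[str, list[np.ndarray]] = {}
    for uset in sets:
        for utt in uset.included:
            env = compute_envelope(utt.waveform,
                                   env_rate=min(cfg.envelope_rate, utt.waveform.rate))
            hier = extract_am_tiers(env, _band_config(cfg))
            a1 = analytic_phase(hier.syllable, env.rate, "syllable")
            a2 = analytic_phase(hier.phoneme, env.rate, "phoneme")
            phases.setdefault(uset.group, []).append(np.vstack([a1.phase, a2.phase]))
    for group, chunks in phases.items():
        stacked = np.hstack(chunks)
        hm = phase_heatmap(stacked[0], stacked[1])
        np.savetxt(out / f"heatmap_{group}.csv", hm.freq, delimiter=",", fmt="%.6f")
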