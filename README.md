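# amentrain

Multi-timescale amplitude-modulation (AM) entrainment analysis for rhythmic
speech and sensorimotor synchronisation experiments.

The package demodulates speech into a three-tier AM hierarchy — stress
(0.8–2.5 Hz), syllable (2.5–12 Hz) and phoneme (12–40 Hz) rates — and provides
two analysis pipelines plus a fully seeded synthetic-data generator:

* **Perception (tapping)** — select analysable taps from repeated-sentence
  trials, compute inter-tap intervals, tap distances to stressed-vowel onsets
  (P-centre proxies), per-participant phase-of-tapping scores (circular median
  of instantaneous AM phases), Rayleigh-gated Watson–Williams group
  comparisons, circular–linear phase/behaviour correlations, and 14-bin
  compass histograms.
* **Production (paced speech)** — vowel-onset intervals for external
  synchronisation; n:m cross-frequency phase synchronisation (PSI strength,
  generalized phase-difference angle, 24×24 joint phase heatmaps) for internal
  synchronisation, with energy-based utterance segmentation, repetition and
  timing-mode exclusion rules, and group comparisons.
* **Synthesis** — metrically regular stimuli with exact ground-truth event
  times, tap trains with controllable phase offset and von Mises jitter,
  produced-utterance analogues with a controllable 3:1 syllable:phoneme
  coupling angle, and two-group cohorts with planted phase offsets and
  behaviour links.

## Library quick start

```python
import numpy as np
import amentrain as am

# AM hierarchy of a waveform (read real audio with amentrain.io.read_wav)
truth = am.synth_stimulus()                       # synthetic sentence + ground truth
env = am.compute_envelope(truth.waveform, env_rate=1000.0)
hier = am.extract_am_tiers(env)                   # stress/syllable/phoneme tiers
syl = am.analytic_phase(hier.syllable, env.rate)  # instantaneous phase, 0 = peak
phases = am.phase_at_times(syl, truth.stress_beats.times)

# circular statistics
am.phase_to_time(0.31 * np.pi, 4.0)               # -> 38.75 ms
am.rayleigh_test(phases)

# n:m phase synchronisation between two tiers' phase streams
pho = am.analytic_phase(hier.phoneme, env.rate)
res = am.psi(syl.phase, pho.phase, n=3, m=1)      # PSI + mean difference angle
```

## Command line

Three pipelines share a JSON config (validated before any data is read;
`--seed` and `--out` override the config):

```bash
# generate a synthetic cohort (audio, taps, onsets, behaviour, ground truth)
simulate --seed 1 --out sim/

# tapping experiment
analyze-perception --config cfg.json --audio-dir sim/audio \
    --taps sim/taps.csv --behaviour sim/behaviour.csv --out results/

# production experiment
analyze-production --config cfg.json --recordings recordings.csv \
    --onsets onsets.csv --out results/
```

All three are also subcommands of the umbrella `amentrain` command. Outputs
are tidy delimited-text tables plus a `manifest.json` recording inputs,
package versions and the config hash; reruns with the same config are
byte-identical.

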