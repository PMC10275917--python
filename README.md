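# bluetitsong

Tools for a question in birdsong research: do songbirds gain from *repeating*
themselves, and what does it cost them?  Many species, the blue tit
(*Cyanistes caeruleus*) among them, sing trilled songs — a few introductory
notes followed by a trill in which one note is repeated in rapid succession —
and repeat the whole song many times (a *song-type bout*) before switching to
another song type.  Precise repetition within the trill (**vocal
consistency**) advertises neuromotor skill; repetition of the whole song,
however, makes the audience habituate.  This package implements the
measurement and modelling pipeline for that trade-off, end to end:

* **Vocal consistency by spectrogram cross-correlation (SPCC).**  Each trill
  note becomes a magnitude spectrogram (512-sample Hann window, 90% overlap);
  a note pair's similarity is the maximum Pearson correlation over temporal
  offsets up to ±20 ms at ~1 ms resolution; a song's consistency is the mean
  over all unordered trill-note pairs — a score in [−1, 1], near 1 for
  precise singers.
* **Bout structure and the warm-up effect.**  Continuous dawn song is
  segmented into song-type bouts (≥3 repetitions; a silent pause >1 min or a
  type switch starts a new bout).  Within a bout, consistency standardised by
  the first song is modelled as `std_consistency ~ repetition + (1 | male)`
  to estimate the warm-up slope (consistency units per repetition).
* **Playback-stimulus construction.**  The female-choice trial stimulus: two
  75 s song-type bouts (one exemplar song repeated at its measured song rate)
  per 150 s song section, 12 five-minute rounds of song + silence in seeded
  random order after ≥5 min lead silence — 24 song-type bouts per 1 h trial.
* **Female response models.**  Binary per-bout / per-position response
  scoring from classified calls (copulation-solicitation classes only), the
  paired signed-rank song-vs-silence comparison, a binomial GLMM of response
  on acoustic song predictors (preference), and the habituation model
  `logit P(response) = β₀ + β₁·switch + β₂·log(position) + β₃·switch·log(position) + b_female`,
  fitted by adaptive Gauss–Hermite maximum likelihood, plus AICc model
  averaging, Akaike weights, relative importance and VIF screening.
* **Synthetic birdsong.**  A generator of trilled songs with controlled
  frequency/duration/amplitude jitter and noise, dawn sessions with known
  bout structure, and simulated female responses — so the whole pipeline is
  testable without field recordings.

## Worked example

```python
import numpy as np
from bluetitsong import (SynthSongConfig, synth_song,
                         song_consistency_from_annotations)

rng = np.random.default_rng(0)
precise = synth_song(SynthSongConfig(freq_jitter_sd=0.0, duration_jitter_sd=0.0,
                                     amp_jitter_sd=0.0, noise_level=0.0), rng)
sloppy  = synth_song(SynthSongConfig(freq_jitter_sd=200.0), rng)
print(song_consistency_from_annotations(precise).song_score)  # 1.0
print(song_consistency_from_annotations(sloppy).song_score)   # 0.9957...
```

A jitter-free trill scores exactly 1.0; 200 Hz of note-to-note frequency
jitter drops the score to ≈0.996 — small numbers, but on the scale real
birds occupy (scores cluster near 1, and differences of a few thousandths
separate individuals).

The numbered scripts under `analysis/` run the full narrative on synthetic
data and write their tables under `results/`:

```sh
python analysis/01_simulate_dawn_sessions.py   # 81 songs, 3 males -> WAV/labels
python analysis/02_vocal_consistency.py        # per-song SPCC scores
python analysis/03_bout_warmup.py              # bout segmentation + warm-up LMM
python analysis/04_playback_stimulus.py        # 1 h stimulus + schedule/cues
python analysis/05_female_response_models.py   # GLMMs, signed-rank, AICc
```

Script 03, for instance, recovers every generated bout boundary and prints

```
warm-up slope: 0.00228 consistency units/repetition (95% CI 0.00104 to 0.00353; truth 0.002)
```

— the warm-up effect injected into the simulation (0.002 per repetition, the
published estimate) is recovered with its CI covering the truth.  Script 05
refits the habituation model on responses simulated from the published
coefficients and shows the signature pattern: response probability 0.53 at
the first song after silence, falling to 0.06 by repetition 15, with partial
recovery (0.33) after a song-type switch — habituation with dishabituation.

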